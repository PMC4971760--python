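import pytest

from peakprior import (
    cluster_tss_groups,
    effective_lengths,
    parse_annotation,
    read_peaks,
)
from peakprior.fixtures import make_fixtures
from peakprior.quantify import read_alignments_sam

FIXTURE_SEED = 0
FRAGMENT_LENGTH = 100


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    return make_fixtures(str(outdir), seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_data(fixture_paths):
    transcripts = parse_annotation(fixture_paths["gtf"])
    groups = cluster_tss_groups(transcripts)
    peaks = read_peaks(fixture_paths["peaks"])
    ell = effective_lengths(transcripts, FRAGMENT_LENGTH)
    compat = read_alignments_sam(fixture_paths["sam"])
    return {
        "transcripts": transcripts,
        "groups": groups,
        "peaks": peaks,
        "eff_lengths": ell,
        "compat": compat,
        "paths": fixture_paths,
    }
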