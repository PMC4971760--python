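"""Synthetic annotation / peak / read fixtures.

Generates a small, fully deterministic test genome exhibiting the structures
the method cares about: genes with alternatively spliced isoforms sharing
exons (including a fully indistinguishable isoform), TSSs separated by more
and less than the grouping distance, a gene with mixed peak status, a pair
of genes with overlapping exonic spans, a cross-locus homology group, and
peak placement correlated with expression.  Fragment counts are driven by a
theta drawn from the with-peak/no-peak Dirichlet, so expression correlates
with peak presence by construction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Transcript
from .chip import Peak, PriorSpec
from .simulate import SimulationTruth, draw_theta, generate_fragments
from .annotation import effective_lengths
from .quantify import write_alignments_sam

__all__ = ["FixtureDesign", "build_fixture_transcripts", "make_fixtures"]

# Pseudocounts used to draw the fixture's ground-truth theta: the with-peak
# and no-peak Dirichlet parameters of the default two-partition prior.
TRUTH_ALPHA_WITH_PEAK = 0.60
TRUTH_ALPHA_NO_PEAK = 0.04


@dataclass
class FixtureDesign:
    transcripts: list[Transcript]
    peaks: list[Peak]
    with_peak: set[str]  # transcript ids whose TSS group carries a peak
    homology_groups: list[set[str]]


def build_fixture_transcripts(scale: int = 1) -> FixtureDesign:
    """Deterministic fixture annotation; ``scale`` multiplies the number of
    background single-isoform genes."""
    T = Transcript
    transcripts: list[Transcript] = []
    with_peak: set[str] = set()

    # geneA: A1 spliced, A2 single-exon contained in A1's first exon
    # (indistinguishable at fragment lengths <= 600); shared TSS group, peak.
    transcripts += [
        T("A1", "geneA", "chrS", "+", ((1000, 1600), (2600, 3200))),
        T("A2", "geneA", "chrS", "+", ((1000, 1600),)),
    ]
    with_peak.update({"A1", "A2"})

    # geneB: mixed peak status; two TSS groups > 500 nt apart sharing the
    # downstream exon, so their fragments multimap.
    transcripts += [
        T("B1", "geneB", "chrS", "+", ((20000, 20800), (22000, 22800))),
        T("B2", "geneB", "chrS", "+", ((21200, 21600), (22000, 22800))),
    ]
    with_peak.add("B1")

    # geneC/geneD: overlapping exonic spans (excluded from any training set)
    transcripts += [
        T("C1", "geneC", "chrS", "+", ((40000, 41500),)),
        T("D1", "geneD", "chrS", "+", ((41000, 42500),)),
    ]
    with_peak.add("C1")

    # geneE/geneF: homologous loci on different chromosomes
    transcripts += [
        T("E1", "geneE", "chrS", "+", ((60000, 61000),)),
        T("F1", "geneF", "chrT", "+", ((5000, 6000),)),
    ]
    with_peak.add("E1")
    homology_groups = [{"E1", "F1"}]

    # background single-isoform genes, alternating peak status; one
    # minus-strand gene for strand coverage
    n_bg = 10 * max(scale, 1)
    pos = 100_000
    for i in range(n_bg):
        tid = f"BG{i:03d}"
        strand = "-" if i % 5 == 4 else "+"
        transcripts.append(
            T(tid, f"geneBG{i:03d}", "chrS", strand, ((pos, pos + 1000),))
        )
        if i % 2 == 0:
            with_peak.add(tid)
        pos += 3000

    peaks = []
    for t in transcripts:
        if t.transcript_id in with_peak:
            # one peak per with-peak TSS suffices; members of a shared TSS
            # group share it
            peaks.append(
                Peak(chrom=t.chrom, start=t.tss - 50, end=t.tss + 50, signal=10.0)
            )
    # deduplicate peaks from shared TSSs
    peaks = sorted(set(peaks), key=lambda p: (p.chrom, p.start))
    return FixtureDesign(
        transcripts=transcripts,
        peaks=peaks,
        with_peak=with_peak,
        homology_groups=homology_groups,
    )


def fixture_truth_prior(design: FixtureDesign) -> PriorSpec:
    """Two-partition truth prior over the fixture: with-peak isoforms get the
    large pseudocount, no-peak the small one."""
    assignment = {
        t.transcript_id: (1 if t.transcript_id in design.with_peak else 2)
        for t in design.transcripts
    }
    return PriorSpec(
        partition_model="two_partition_peak",
        alphas={1: TRUTH_ALPHA_WITH_PEAK, 2: TRUTH_ALPHA_NO_PEAK},
        assignment=assignment,
    )


def write_gtf(path: str, transcripts) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            for start, end in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                )
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            "fixture",
                            "exon",
                            str(start + 1),  # GTF is 1-based closed
                            str(end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def write_narrowpeak(path: str, peaks) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        f"peak{i}",
                        "0",
                        ".",
                        f"{p.signal}",
                        "-1",
                        "-1",
                        str((p.end - p.start) // 2),
                    ]
                )
                + "\n"
            )


def make_fixtures(
    outdir: str,
    seed: int = 0,
    scale: int = 1,
    n_fragments: int = 20000,
    fragment_length: int = 100,
    noise_fraction: float = 0.05,
) -> dict[str, str]:
    """Write fixture.gtf, peaks.narrowPeak, reads.sam, truth.tsv and
    homology.tsv under ``outdir``; returns the path map.  Identical seeds
    yield identical files."""
    os.makedirs(outdir, exist_ok=True)
    design = build_fixture_transcripts(scale=scale)
    prior = fixture_truth_prior(design)
    ell = effective_lengths(design.transcripts, fragment_length)
    truth = draw_theta(
        prior,
        design.transcripts,
        ell,
        n_fragments=n_fragments,
        seed=seed,
        noise_fraction=noise_fraction,
    )
    compat = generate_fragments(
        truth,
        design.transcripts,
        fragment_length,
        homology_groups=design.homology_groups,
        seed=seed + 1,
    )
    paths = {
        "gtf": os.path.join(outdir, "fixture.gtf"),
        "peaks": os.path.join(outdir, "peaks.narrowPeak"),
        "sam": os.path.join(outdir, "reads.sam"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "homology": os.path.join(outdir, "homology.tsv"),
    }
    write_gtf(paths["gtf"], design.transcripts)
    write_narrowpeak(paths["peaks"], design.peaks)
    lengths = {t.transcript_id: t.length for t in design.transcripts}
    write_alignments_sam(paths["sam"], compat, lengths, read_length=fragment_length)
    origin_counts = pd.Series(
        [rid.split("|", 1)[1] for rid in compat.read_ids]
    ).value_counts()
    truth_df = pd.DataFrame(
        {
            "transcript_id": truth.theta.index,
            "theta": truth.theta.to_numpy(),
            "true_tpm": truth.true_tpm.to_numpy(),
            "origin_count": [
                int(origin_counts.get(t, 0)) for t in truth.theta.index
            ],
        }
    )
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["homology"], "w") as fh:
        fh.write("group_id\ttranscript_id\n")
        for i, grp in enumerate(design.homology_groups):
            for tid in sorted(grp):
                fh.write(f"hg{i}\t{tid}\n")
    return paths
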