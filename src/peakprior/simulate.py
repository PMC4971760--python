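"""Data-driven simulation and estimator evaluation.

Draws fragment-generating probabilities from a partitioned Dirichlet, emits
structurally multimapping fragments from the annotation (plus optional
cross-locus homology groups), subsamples reads, and scores estimators by
false-positive / false-negative rates at a TPM cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import Transcript, effective_lengths, fragment_compatible
from .chip import PriorSpec
from .quantify import (
    CompatibilityMatrix,
    em_quantify,
    gibbs_quantify,
    uniform_prior_variant,
    aggregate_genes,
)

__all__ = [
    "SimulationTruth",
    "ClassificationResult",
    "draw_theta",
    "generate_fragments",
    "subsample_reads",
    "classify_fpr_fnr",
    "fold_change",
    "benchmark_estimators",
]


@dataclass
class SimulationTruth:
    """Ground-truth fragment-generating probabilities and abundances."""

    theta: pd.Series
    true_tpm: pd.Series
    n_fragments: int
    noise_fraction: float
    seed: int


@dataclass
class ClassificationResult:
    fpr: float  # percent of truly unexpressed units called expressed
    fnr: float  # percent of truly expressed units called unexpressed
    n_fp: int
    n_fn: int
    n_true_expressed: int
    n_true_unexpressed: int
    cutoff_tpm: float


def draw_theta(
    prior: PriorSpec,
    transcripts: Sequence[Transcript],
    eff_lengths: Mapping[str, float],
    n_fragments: int,
    seed: int,
    noise_fraction: float = 0.05,
    zero_alphas: Mapping[str, float] | None = None,
) -> SimulationTruth:
    """Draw theta ~ Dirichlet(alpha) with per-transcript alphas from the
    prior's partition assignment.

    ``zero_alphas`` may override individual transcripts with an alpha of 0,
    pinning their theta (and true TPM) exactly to zero — the simulated
    truly-unexpressed units.
    """
    tids = [t.transcript_id for t in transcripts]
    alphas = np.array(
        [
            0.0
            if zero_alphas is not None and zero_alphas.get(tid, 1) == 0
            else prior.alpha_for(tid)
            for tid in tids
        ]
    )
    rng = np.random.default_rng(seed)
    theta = np.zeros(len(tids))
    pos = alphas > 0
    if not pos.any():
        raise ValueError("all alphas are zero; nothing to simulate")
    theta[pos] = rng.dirichlet(alphas[pos])
    ell = np.array([eff_lengths[t] for t in tids])
    dens = theta / ell
    tpm = 1e6 * dens / dens.sum()
    return SimulationTruth(
        theta=pd.Series(theta, index=tids, name="theta"),
        true_tpm=pd.Series(tpm, index=tids, name="true_tpm"),
        n_fragments=int(n_fragments),
        noise_fraction=float(noise_fraction),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Fragment generation

_compat_cache: dict = {}


def _compatibility_map(
    transcripts: tuple[Transcript, ...],
    fragment_length: int,
    homology_groups: tuple[frozenset, ...] = (),
) -> dict[str, list[list[tuple[str, int]]]]:
    """For every transcript and start position, the full alignment set.

    Same-gene compatibility is structural (exon-chain footprint containment);
    homology groups declare transcripts at other loci mutually alignable at
    the same transcript coordinate when the fragment fits (idealised
    homologs with matching internal structure).
    """
    key = (transcripts, fragment_length, homology_groups)
    if key in _compat_cache:
        return _compat_cache[key]
    by_gene: dict[str, list[Transcript]] = {}
    by_id = {t.transcript_id: t for t in transcripts}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    homologs: dict[str, set[str]] = {}
    for grp in homology_groups:
        for tid in grp:
            homologs.setdefault(tid, set()).update(grp - {tid})
    out: dict[str, list[list[tuple[str, int]]]] = {}
    for t in transcripts:
        n_starts = t.length - fragment_length + 1
        per_start: list[list[tuple[str, int]]] = []
        mates = [o for o in by_gene[t.gene_id] if o.transcript_id != t.transcript_id]
        for p in range(max(n_starts, 0)):
            aln = [(t.transcript_id, p)]
            for o in mates:
                q = fragment_compatible(t, p, fragment_length, o)
                if q is not None:
                    aln.append((o.transcript_id, q))
            for hid in homologs.get(t.transcript_id, ()):
                h = by_id[hid]
                if p + fragment_length <= h.length:
                    aln.append((hid, p))
            per_start.append(aln)
        out[t.transcript_id] = per_start
    _compat_cache[key] = out
    return out


def generate_fragments(
    truth: SimulationTruth,
    transcripts: Sequence[Transcript],
    fragment_length: int,
    homology_groups: Iterable[Iterable[str]] | None = None,
    seed: int | None = None,
) -> CompatibilityMatrix:
    """Simulate ``truth.n_fragments`` fragments.

    Each fragment is noise with probability ``noise_fraction`` (counted in
    sequencing depth, never aligned, hence absent from the returned matrix);
    otherwise its transcript follows theta and its start is uniform over the
    transcript's valid positions.  The alignment set of a fragment is every
    transcript structurally compatible with its exonic footprint plus
    declared homologs.
    """
    if truth.n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    transcripts = tuple(transcripts)
    tids = [t.transcript_id for t in transcripts]
    lengths = {t.transcript_id: t.length for t in transcripts}
    if all(lengths[t] < fragment_length for t in tids):
        raise ValueError("fragment length exceeds every transcript length")
    theta = truth.theta.reindex(tids).to_numpy()
    for tid, th in zip(tids, theta):
        if th > 0 and lengths[tid] < fragment_length:
            raise ValueError(
                f"transcript {tid} shorter than the fragment length but has "
                "positive generating probability"
            )
    hg = tuple(frozenset(g) for g in (homology_groups or ()))
    compat_map = _compatibility_map(transcripts, fragment_length, hg)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    is_noise = rng.random(truth.n_fragments) < truth.noise_fraction
    n_real = int((~is_noise).sum())
    origins = rng.choice(len(tids), size=n_real, p=theta / theta.sum())
    read_ids, alignments = [], []
    for i, oi in enumerate(origins):
        tid = tids[oi]
        n_starts = lengths[tid] - fragment_length + 1
        p = int(rng.integers(0, n_starts))
        read_ids.append(f"frag{i:07d}|{tid}")
        alignments.append(compat_map[tid][p])
    return CompatibilityMatrix(read_ids=read_ids, alignments=alignments)


def subsample_reads(
    compat: CompatibilityMatrix, fraction: float, seed: int
) -> CompatibilityMatrix:
    """Draw floor(fraction * N) reads without replacement (seeded)."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n_keep = math.floor(fraction * compat.N)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(compat.N, size=n_keep, replace=False))
    return compat.subset(keep)


# ---------------------------------------------------------------------------
# Scoring


def classify_fpr_fnr(
    true_tpm: pd.Series, est_tpm: pd.Series, cutoff_tpm: float = 1.0
) -> ClassificationResult:
    """FPR/FNR of expressed calls at a TPM cutoff (inclusive >= cutoff).

    A false positive is a unit with true TPM < cutoff but estimated TPM >=
    cutoff; a false negative the reverse.  Rates are percentages of the
    truly-unexpressed and truly-expressed unit counts, 0 when the
    denominator is empty.
    """
    if set(true_tpm.index) != set(est_tpm.index):
        raise ValueError("true and estimated TPM cover different units")
    est = est_tpm.reindex(true_tpm.index)
    true_exp = true_tpm >= cutoff_tpm
    est_exp = est >= cutoff_tpm
    n_fp = int((~true_exp & est_exp).sum())
    n_fn = int((true_exp & ~est_exp).sum())
    n_unexp = int((~true_exp).sum())
    n_exp = int(true_exp.sum())
    return ClassificationResult(
        fpr=100.0 * n_fp / n_unexp if n_unexp else 0.0,
        fnr=100.0 * n_fn / n_exp if n_exp else 0.0,
        n_fp=n_fp,
        n_fn=n_fn,
        n_true_expressed=n_exp,
        n_true_unexpressed=n_unexp,
        cutoff_tpm=cutoff_tpm,
    )


def fold_change(est_a: float, est_b: float, pseudocount_tpm: float = 0.0) -> float:
    """log2((a + pseudo) / (b + pseudo))."""
    a = est_a + pseudocount_tpm
    b = est_b + pseudocount_tpm
    if b <= 0 or a <= 0:
        raise ValueError("fold change undefined without a positive pseudocount")
    return float(np.log2(a / b))


# ---------------------------------------------------------------------------
# Benchmark harness


def benchmark_estimators(
    transcripts: Sequence[Transcript],
    truth_prior: PriorSpec,
    estimators: Mapping[str, dict],
    n_replicates: int,
    n_fragments: int,
    fragment_length: int,
    cutoff_tpm: float,
    seed: int,
    noise_fraction: float = 0.05,
    zero_alphas: Mapping[str, float] | None = None,
    homology_groups: Iterable[Iterable[str]] | None = None,
    gibbs_samples: int = 150,
    gibbs_burn_in: int = 100,
) -> pd.DataFrame:
    """End-to-end seeded benchmark: draw theta, simulate fragments, quantify
    with each estimator config, and classify expressed calls at isoform and
    gene level.

    Estimator configs: ``{"kind": "ml"}``, ``{"kind": "gibbs", "prior": spec}``
    or ``{"kind": "gibbs", "pseudocount": x}``.  Returns a tidy table with
    one row per (replicate, estimator, level).
    """
    transcripts = tuple(transcripts)
    tids = [t.transcript_id for t in transcripts]
    tx2gene = {t.transcript_id: t.gene_id for t in transcripts}
    ell = effective_lengths(transcripts, fragment_length)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=(n_replicates, 3))
    rows = []
    for rep in range(n_replicates):
        truth = draw_theta(
            truth_prior,
            transcripts,
            ell,
            n_fragments=n_fragments,
            seed=int(rep_seeds[rep, 0]),
            noise_fraction=noise_fraction,
            zero_alphas=zero_alphas,
        )
        compat = generate_fragments(
            truth,
            transcripts,
            fragment_length,
            homology_groups=homology_groups,
            seed=int(rep_seeds[rep, 1]),
        )
        true_gene_tpm = (
            truth.true_tpm.groupby(pd.Series(tx2gene)).sum()
            if tx2gene
            else pd.Series(dtype=float)
        )
        for name in sorted(estimators):
            cfg = estimators[name]
            if cfg["kind"] == "ml":
                _, est = em_quantify(compat, ell)
            elif cfg["kind"] == "gibbs" and "prior" in cfg:
                est = gibbs_quantify(
                    compat,
                    ell,
                    cfg["prior"],
                    n_samples=gibbs_samples,
                    burn_in=gibbs_burn_in,
                    seed=int(rep_seeds[rep, 2]),
                )
            elif cfg["kind"] == "gibbs":
                est = uniform_prior_variant(
                    compat,
                    ell,
                    pseudocount=cfg.get("pseudocount", 1.0),
                    n_samples=gibbs_samples,
                    burn_in=gibbs_burn_in,
                    seed=int(rep_seeds[rep, 2]),
                )
            else:
                raise ValueError(f"unknown estimator kind {cfg['kind']!r}")
            est_tpm = est["tpm"].reindex(tids)
            for level, truth_s, est_s in (
                ("isoform", truth.true_tpm, est_tpm),
                (
                    "gene",
                    true_gene_tpm,
                    est_tpm.groupby(pd.Series(tx2gene)).sum(),
                ),
            ):
                res = classify_fpr_fnr(truth_s, est_s, cutoff_tpm=cutoff_tpm)
                rows.append(
                    {
                        "replicate": rep,
                        "estimator": name,
                        "level": level,
                        "cutoff": cutoff_tpm,
                        "fpr": res.fpr,
                        "fnr": res.fnr,
                        "n_fp": res.n_fp,
                        "n_fn": res.n_fn,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "replicate",
            "estimator",
            "level",
            "cutoff",
            "fpr",
            "fnr",
            "n_fp",
            "n_fn",
        ],
    )
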