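"""Abundance estimation from read-compatibility evidence.

Two estimators over the same simplified generative model: a read originates
from transcript i with probability theta_i and from a start position uniform
over the transcript's effective length.  ``em_quantify`` gives the maximum
likelihood solution; ``gibbs_quantify`` gives posterior means under a
partitioned Dirichlet prior on theta via a collapsed Gibbs sampler in which
the per-partition pseudocounts act as prior fragment counts.

The read model deliberately omits quality scores, sequencing error, and
positional/orientation bias: the compatibility matrix (which transcripts and
positions each read can come from) is the sole evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from numba import njit

from .chip import PriorSpec

__all__ = [
    "CompatibilityMatrix",
    "em_quantify",
    "gibbs_quantify",
    "uniform_prior_variant",
    "aggregate_genes",
    "call_expressed",
    "read_alignments_sam",
    "read_alignments_tsv",
    "write_alignments_sam",
    "write_quantification",
]

EM_TOL = 1e-8
EM_MAX_ITER = 10_000


@dataclass
class CompatibilityMatrix:
    """Per-read alignment sets: the sole evidence used by EM/Gibbs.

    ``alignments[r]`` is a non-empty list of ``(transcript_id, start)`` pairs
    with the start position expressed in transcript coordinates.
    """

    read_ids: list[str]
    alignments: list[list[tuple[str, int]]]

    def __post_init__(self) -> None:
        if len(self.read_ids) != len(self.alignments):
            raise ValueError("read_ids and alignments must align")
        for rid, aln in zip(self.read_ids, self.alignments):
            if not aln:
                raise ValueError(f"read {rid} has no alignments")
            if len(set(aln)) != len(aln):
                raise ValueError(f"read {rid} has duplicate alignments")

    @property
    def N(self) -> int:
        return len(self.read_ids)

    def transcript_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for aln in self.alignments:
            for tid, _ in aln:
                seen.setdefault(tid)
        return list(seen)

    def subset(self, indices: Sequence[int]) -> "CompatibilityMatrix":
        return CompatibilityMatrix(
            read_ids=[self.read_ids[i] for i in indices],
            alignments=[self.alignments[i] for i in indices],
        )


# ---------------------------------------------------------------------------
# Flattened views


def _index(
    compat: CompatibilityMatrix, eff_lengths: Mapping[str, float]
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """(tids, offsets, tx_slot, w_slot): per-read alignment slots flattened,
    with w = 1/efflen.  Raises if a read names an unknown transcript."""
    tids = sorted(eff_lengths)
    tidx = {t: i for i, t in enumerate(tids)}
    offsets = np.zeros(compat.N + 1, dtype=np.int64)
    tx, w = [], []
    for r, aln in enumerate(compat.alignments):
        for tid, pos in aln:
            if tid not in tidx:
                raise ValueError(f"read aligned to unknown transcript {tid!r}")
            ell = eff_lengths[tid]
            if pos < 0 or pos >= max(ell, 1):
                # positions beyond the effective length carry no extra
                # information in this model; still reject negatives
                if pos < 0:
                    raise ValueError(f"negative alignment position for {tid}")
            tx.append(tidx[tid])
            w.append(1.0 / ell)
        offsets[r + 1] = len(tx)
    return tids, offsets, np.array(tx, dtype=np.int64), np.array(w, dtype=np.float64)


def _tpm_from_theta(theta: np.ndarray, ell: np.ndarray) -> np.ndarray:
    dens = theta / ell
    return 1e6 * dens / dens.sum()


# ---------------------------------------------------------------------------
# EM


def em_quantify(
    compat: CompatibilityMatrix,
    eff_lengths: Mapping[str, float],
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> tuple[pd.Series, pd.DataFrame]:
    """Maximum-likelihood theta via EM on collapsed equivalence classes.

    Reads with identical alignment transcript multisets are interchangeable
    for the likelihood L(theta) = prod_r sum_(i,p) theta_i / efflen_i, so they
    are collapsed into weighted classes before iterating.  The log-likelihood
    is checked to be non-decreasing at every step.
    """
    if compat.N < 1:
        raise ValueError("no reads to quantify")
    tids, offsets, tx, w = _index(compat, eff_lengths)
    M = len(tids)
    # collapse reads into equivalence classes by transcript multiset
    classes: dict[tuple[int, ...], int] = {}
    class_slots: list[np.ndarray] = []
    class_n: list[float] = []
    for r in range(compat.N):
        key = tuple(sorted(tx[offsets[r] : offsets[r + 1]]))
        if key in classes:
            class_n[classes[key]] += 1.0
        else:
            classes[key] = len(class_slots)
            class_slots.append(np.arange(offsets[r], offsets[r + 1]))
            class_n.append(1.0)
    n_c = np.array(class_n)
    N = float(compat.N)

    theta = np.full(M, 1.0 / M)
    ll_prev = -np.inf
    for _ in range(max_iter):
        counts = np.zeros(M)
        ll = 0.0
        for slots, n in zip(class_slots, n_c):
            contrib = theta[tx[slots]] * w[slots]
            denom = contrib.sum()
            ll += n * np.log(denom)
            np.add.at(counts, tx[slots], n * contrib / denom)
        if ll < ll_prev - 1e-9 * max(abs(ll_prev), 1.0):
            raise AssertionError("EM log-likelihood decreased")
        theta = counts / N
        if np.isfinite(ll_prev) and (ll - ll_prev) < tol * abs(ll_prev):
            ll_prev = ll
            break
        ll_prev = ll

    ell = np.array([eff_lengths[t] for t in tids])
    tpm = _tpm_from_theta(theta, ell)
    est = pd.DataFrame(
        {
            "transcript_id": tids,
            "expected_count": counts,
            "theta": theta,
            "tpm": tpm,
            "estimator": "ML",
        }
    ).set_index("transcript_id")
    return pd.Series(theta, index=tids, name="theta"), est


# ---------------------------------------------------------------------------
# Collapsed Gibbs


@njit(cache=True)
def _gibbs_kernel(offsets, tx, w, alpha, z0, n_samples, burn_in, seed):  # pragma: no cover
    np.random.seed(seed)
    M = alpha.shape[0]
    R = offsets.shape[0] - 1
    counts = np.zeros(M)
    z = z0.copy()
    for r in range(R):
        counts[tx[z[r]]] += 1.0
    cum = np.zeros(tx.shape[0])
    mean_counts = np.zeros(M)
    n_iter = burn_in + n_samples
    for it in range(n_iter):
        for r in range(R):
            s, e = offsets[r], offsets[r + 1]
            counts[tx[z[r]]] -= 1.0
            tot = 0.0
            for k in range(s, e):
                tot += (alpha[tx[k]] + counts[tx[k]]) * w[k]
                cum[k] = tot
            u = np.random.random() * tot
            pick = e - 1
            for k in range(s, e):
                if u <= cum[k]:
                    pick = k
                    break
            z[r] = pick
            counts[tx[pick]] += 1.0
        if it >= burn_in:
            for m in range(M):
                mean_counts[m] += counts[m]
    return mean_counts / n_samples


def gibbs_quantify(
    compat: CompatibilityMatrix,
    eff_lengths: Mapping[str, float],
    prior: PriorSpec,
    n_samples: int = 1000,
    burn_in: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior-mean abundances under a Dirichlet prior by collapsed Gibbs.

    Read assignments z_r are resampled with
    ``P(z_r = (i,p) | z_-r)  propto  (alpha_i + n_i^{-r}) / efflen_i`` over
    the read's alignment set.  After burn-in, the posterior-mean count is the
    average occupancy n_i and the posterior-mean theta_i is the average of
    ``(alpha_i + n_i) / (A + N)`` (which, being linear in n_i, follows from
    the averaged counts).  TPM is computed from posterior-mean theta with the
    same length adjustment as the ML estimator.  Bit-reproducible for a seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    tids, offsets, tx, w = _index(compat, eff_lengths)
    missing = [t for t in tids if t not in prior.assignment]
    if missing:
        raise ValueError(f"prior has no pseudocount for transcripts {missing[:5]}")
    alpha = prior.alpha_vector(tids)
    # initialise assignments by sampling once from the EM responsibilities
    theta_ml, _ = em_quantify(compat, eff_lengths)
    rng = np.random.default_rng(seed)
    p_slot = theta_ml.to_numpy()[tx] * w
    # degenerate reads (all-zero ML weight): fall back to uniform slots
    sums = np.add.reduceat(p_slot, offsets[:-1])
    zero = np.repeat(sums == 0, np.diff(offsets))
    p_slot[zero] = 1.0
    cs = np.cumsum(p_slot)
    base = cs[offsets[:-1]] - p_slot[offsets[:-1]]
    tot = cs[offsets[1:] - 1] - base
    target = base + rng.random(compat.N) * tot
    z0 = np.searchsorted(cs, target, side="left")
    z0 = np.minimum(np.maximum(z0, offsets[:-1]), offsets[1:] - 1).astype(np.int64)
    mean_counts = _gibbs_kernel(
        offsets, tx, w, alpha, z0, int(n_samples), int(burn_in), int(seed) & 0x7FFFFFFF
    )
    A = alpha.sum()
    N = float(compat.N)
    theta = (alpha + mean_counts) / (A + N)
    ell = np.array([eff_lengths[t] for t in tids])
    tpm = _tpm_from_theta(theta, ell)
    return pd.DataFrame(
        {
            "transcript_id": tids,
            "posterior_mean_count": mean_counts,
            "theta": theta,
            "tpm": tpm,
            "alpha": alpha,
            "estimator": "posterior_mean",
        }
    ).set_index("transcript_id")


def uniform_prior_variant(
    compat: CompatibilityMatrix,
    eff_lengths: Mapping[str, float],
    pseudocount: float = 1.0,
    n_samples: int = 1000,
    burn_in: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Gibbs posterior means under a flat prior alpha_i = pseudocount.

    ``pseudocount=1`` is the conventional uninformative baseline; a small
    single-partition maximum-likelihood pseudocount gives the unpartitioned
    learned-prior variant.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    prior = PriorSpec.uniform(sorted(eff_lengths), pseudocount=pseudocount)
    return gibbs_quantify(
        compat, eff_lengths, prior, n_samples=n_samples, burn_in=burn_in, seed=seed
    )


# ---------------------------------------------------------------------------
# Aggregation and calls


def aggregate_genes(
    estimates: pd.DataFrame, tx2gene: Mapping[str, str]
) -> pd.DataFrame:
    """Sum per-isoform counts and TPM to the gene level."""
    unmapped = [t for t in estimates.index if t not in tx2gene]
    if unmapped:
        raise ValueError(f"transcripts not mapped to genes: {unmapped[:5]}")
    df = estimates.copy()
    df["gene_id"] = [tx2gene[t] for t in df.index]
    value_cols = [
        c
        for c in ("expected_count", "posterior_mean_count", "tpm")
        if c in df.columns
    ]
    out = df.groupby("gene_id")[value_cols].sum().sort_index()
    return out


def call_expressed(tpm: pd.Series | pd.DataFrame, cutoff_tpm: float = 1.0) -> pd.Series:
    """Expressed iff TPM >= cutoff (inclusive)."""
    if cutoff_tpm <= 0:
        raise ValueError("cutoff_tpm must be positive")
    if isinstance(tpm, pd.DataFrame):
        tpm = tpm["tpm"]
    return tpm >= cutoff_tpm


# ---------------------------------------------------------------------------
# Alignment I/O


def read_alignments_sam(path: str) -> CompatibilityMatrix:
    """Read a transcriptome-coordinate SAM file: RNAME = transcript id,
    1-based POS; multiple records per QNAME encode multimapping."""
    reads: dict[str, list[tuple[str, int]]] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            reads.setdefault(rec.query_name, []).append(
                (rec.reference_name, rec.reference_start)
            )
    read_ids = list(reads)
    return CompatibilityMatrix(
        read_ids=read_ids, alignments=[reads[r] for r in read_ids]
    )


def read_alignments_tsv(path: str) -> CompatibilityMatrix:
    """Read a compatibility TSV with columns read_id, transcript_id, pos."""
    df = pd.read_csv(path, sep="\t")
    reads: dict[str, list[tuple[str, int]]] = {}
    for r in df.itertuples():
        reads.setdefault(str(r.read_id), []).append((str(r.transcript_id), int(r.pos)))
    read_ids = list(reads)
    return CompatibilityMatrix(
        read_ids=read_ids, alignments=[reads[r] for r in read_ids]
    )


def write_alignments_sam(
    path: str,
    compat: CompatibilityMatrix,
    transcript_lengths: Mapping[str, int],
    read_length: int = 100,
) -> None:
    tids = sorted(transcript_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": t, "LN": int(transcript_lengths[t])} for t in tids],
    }
    ref_idx = {t: i for i, t in enumerate(tids)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rid, aln in zip(compat.read_ids, compat.alignments):
            for j, (tid, pos) in enumerate(aln):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = rid
                rec.reference_id = ref_idx[tid]
                rec.reference_start = pos
                rec.mapping_quality = 255
                rec.cigarstring = f"{read_length}M"
                rec.flag = 0 if j == 0 else 256  # secondary for extra hits
                out.write(rec)


def write_quantification(
    path: str,
    transcripts,
    eff_lengths: Mapping[str, float],
    ml_estimates: pd.DataFrame,
    posterior_estimates: pd.DataFrame,
    prior: PriorSpec | None = None,
) -> pd.DataFrame:
    """Write the fixed-column quantification TSV combining ML and posterior
    estimates."""
    rows = []
    for t in transcripts:
        tid = t.transcript_id
        rows.append(
            {
                "transcript_id": tid,
                "gene_id": t.gene_id,
                "length": t.length,
                "effective_length": eff_lengths[tid],
                "expected_count": float(ml_estimates.at[tid, "expected_count"]),
                "TPM": float(ml_estimates.at[tid, "tpm"]),
                "posterior_mean_count": float(
                    posterior_estimates.at[tid, "posterior_mean_count"]
                ),
                "posterior_mean_TPM": float(posterior_estimates.at[tid, "tpm"]),
                "partition_id": prior.assignment[tid] if prior else 1,
                "alpha": prior.alpha_for(tid) if prior else 1.0,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "gene_id",
            "length",
            "effective_length",
            "expected_count",
            "TPM",
            "posterior_mean_count",
            "posterior_mean_TPM",
            "partition_id",
            "alpha",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    return df
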