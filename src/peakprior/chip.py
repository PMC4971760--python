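"""ChIP-seq-derived Dirichlet priors.

Assigns peaks and TSS-proximal signal to isoform TSS windows, builds the
training set of isoforms with uniquely assignable ChIP evidence, partitions
it, and learns one Dirichlet pseudocount per partition by maximising a
Dirichlet-multinomial (DM) likelihood over the training isoforms' fragment
counts.  Also ranks candidate prior sources by training-set log-likelihood
and offers a permutation test of whether a partitioning is informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.optimize import minimize
from scipy.special import gammaln

from .annotation import Transcript, TssGroup

__all__ = [
    "Peak",
    "TssFeature",
    "TrainingSet",
    "PriorSpec",
    "ALPHA_MIN",
    "ALPHA_MAX",
    "read_peaks",
    "tss_peak_status",
    "tss_signal_rpm",
    "build_training_set",
    "dm_log_likelihood",
    "fit_prior",
    "partition_units",
    "compare_prior_sources",
    "informativeness_test",
    "gene_peak_status",
    "write_prior",
    "read_prior",
]

# Bounds for the learned pseudocounts; optimisation runs on ln(alpha).
ALPHA_MIN = 1e-4
ALPHA_MAX = 1e4


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    signal: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty peak interval [{self.start},{self.end})")


@dataclass(frozen=True)
class TssFeature:
    """Peak presence and aggregate signal in a unit's TSS window(s)."""

    unit_id: str
    chrom: str
    window: tuple[int, int]
    has_peak: bool
    signal: float


@dataclass
class TrainingSet:
    """Isoforms with uniquely assignable ChIP evidence plus their ML
    fragment counts and partition labels (1..G)."""

    unit_ids: list[str]
    counts: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.unit_ids) == len(self.counts) == len(self.labels)):
            raise ValueError("unit_ids, counts and labels must align")
        if np.any(self.counts < 0):
            raise ValueError("fragment counts must be non-negative")
        G = self.n_partitions
        present = set(np.unique(self.labels))
        if present != set(range(1, G + 1)):
            raise ValueError("partition labels must cover 1..G")

    @property
    def N(self) -> float:
        return float(self.counts.sum())

    @property
    def n_partitions(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0


@dataclass
class PriorSpec:
    """Partition assignment plus one Dirichlet pseudocount per partition."""

    partition_model: str
    alphas: dict[int, float]
    assignment: dict[str, int]
    log_likelihood: float | None = None

    def __post_init__(self) -> None:
        for g, a in self.alphas.items():
            if not (a > 0):
                raise ValueError(f"alpha for partition {g} must be positive")
        for unit, g in self.assignment.items():
            if g not in self.alphas:
                raise ValueError(f"unit {unit} assigned to unknown partition {g}")

    def alpha_for(self, unit_id: str) -> float:
        return self.alphas[self.assignment[unit_id]]

    def alpha_vector(self, unit_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.alpha_for(u) for u in unit_ids])

    @classmethod
    def uniform(cls, unit_ids: Iterable[str], pseudocount: float = 1.0) -> "PriorSpec":
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        return cls(
            partition_model="no_partition",
            alphas={1: float(pseudocount)},
            assignment={u: 1 for u in unit_ids},
        )


# ---------------------------------------------------------------------------
# Peak I/O and window assignment


def read_peaks(path: str, format: str = "narrowPeak") -> list[Peak]:
    """Read narrowPeak (signalValue column) or BED6 (score column) peaks,
    sorted by (chrom, start, end)."""
    if format == "narrowPeak":
        ncols, signal_col = 10, 6
    elif format == "bed6":
        ncols, signal_col = 6, 4
    else:
        raise ValueError(f"unknown peak format {format!r}")
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    peaks = []
    for idx, row in df.iterrows():
        lineno = idx + 1
        vals = [v for v in row.tolist() if v is not None and v == v]
        if len(vals) < ncols:
            raise ValueError(f"{path}:{lineno}: expected {ncols} columns")
        try:
            start, end = int(vals[1]), int(vals[2])
            signal = float(vals[signal_col])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
        if end <= start:
            raise ValueError(f"{path}:{lineno}: start >= end")
        if signal < 0:
            raise ValueError(f"{path}:{lineno}: negative signal")
        peaks.append(Peak(chrom=vals[0], start=start, end=end, signal=signal))
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return peaks


def _unit_windows(
    unit: Transcript | TssGroup, flank: int
) -> tuple[str, str, list[tuple[int, int]]]:
    """(unit_id, chrom, TSS windows).  A window covers [tss - flank,
    tss + flank] inclusive, i.e. the half-open [tss - flank, tss + flank + 1).
    For a TSS group the windows of all members are used."""
    if isinstance(unit, TssGroup):
        windows = [(t - flank, t + flank + 1) for t in unit.member_tsss]
        return unit.group_id, unit.chrom, windows
    return unit.transcript_id, unit.chrom, [(unit.tss - flank, unit.tss + flank + 1)]


def tss_peak_status(
    units: Sequence[Transcript | TssGroup],
    peaks: Iterable[Peak],
    flank: int = 500,
) -> list[TssFeature]:
    """Peak presence and summed peak signal within each unit's TSS window."""
    if flank < 0:
        raise ValueError("flank must be non-negative")
    trees: dict[str, IntervalTree] = {}
    for i, p in enumerate(peaks):
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, (i, p.signal))
    features = []
    for unit in units:
        unit_id, chrom, windows = _unit_windows(unit, flank)
        tree = trees.get(chrom)
        hits: dict[int, float] = {}
        if tree is not None:
            for ws, we in windows:
                for iv in tree.overlap(ws, we):
                    hits[iv.data[0]] = iv.data[1]
        features.append(
            TssFeature(
                unit_id=unit_id,
                chrom=chrom,
                window=(min(w[0] for w in windows), max(w[1] for w in windows)),
                has_peak=bool(hits),
                signal=float(sum(hits.values())),
            )
        )
    return features


def tss_signal_rpm(
    read_5prime_positions: pd.DataFrame,
    units: Sequence[Transcript | TssGroup],
    flank: int = 100,
    library_depth: int | None = None,
) -> dict[str, float]:
    """Reads-per-million of 5' read ends within a unit's TSS windows.

    ``read_5prime_positions`` is BED-like with columns chrom/start/end and an
    optional strand column; the 5' end is ``start`` on ``+`` and ``end - 1``
    on ``-``.  A read is counted at most once per unit even when it falls in
    several member windows.
    """
    if library_depth is None or library_depth <= 0:
        raise ValueError("library_depth must be a positive count")
    df = read_5prime_positions
    if "strand" in df.columns:
        five = np.where(df["strand"] == "-", df["end"] - 1, df["start"])
    else:
        five = df["start"].to_numpy()
    chroms = df["chrom"].to_numpy()
    order = {}
    for c in np.unique(chroms):
        mask = chroms == c
        order[c] = np.sort(np.asarray(five)[mask])
    out = {}
    for unit in units:
        unit_id, chrom, windows = _unit_windows(unit, flank)
        pos = order.get(chrom)
        count = 0
        if pos is not None:
            seen = np.zeros(len(pos), dtype=bool)
            for ws, we in windows:
                lo = np.searchsorted(pos, ws, side="left")
                hi = np.searchsorted(pos, we, side="left")
                seen[lo:hi] = True
            count = int(seen.sum())
        out[unit_id] = 1e6 * count / library_depth
    return out


# ---------------------------------------------------------------------------
# Training set


def build_training_set(
    transcripts: Sequence[Transcript],
    tss_groups: Sequence[TssGroup],
    peaks: Iterable[Peak],
    quantified_counts: Mapping[str, float],
    flank: int = 500,
    model: str = "two_partition_peak",
    **model_kwargs,
) -> TrainingSet:
    """Select isoforms with uniquely assignable ChIP evidence and label them.

    An isoform is eligible when (a) its TSS group's window overlaps no other
    TSS group's window (unique peak assignment) and (b) its gene's exonic
    span overlaps no other gene's span (unique ChIP read assignment).
    Fragment counts come from a maximum-likelihood quantification.
    """
    features = tss_peak_status(tss_groups, peaks, flank=flank)
    feat_by_group = {f.unit_id: f for f in features}

    # rule (a): group windows pairwise disjoint
    bad_groups: set[str] = set()
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append((f.window[0], f.window[1], f.unit_id))
    for ivs in by_chrom.values():
        ivs.sort()
        for (s1, e1, g1), (s2, e2, g2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                bad_groups.update((g1, g2))

    # rule (b): gene exonic spans pairwise disjoint
    gene_span: dict[str, tuple[str, int, int]] = {}
    for t in transcripts:
        s, e = t.span
        if t.gene_id in gene_span:
            c, s0, e0 = gene_span[t.gene_id]
            gene_span[t.gene_id] = (c, min(s0, s), max(e0, e))
        else:
            gene_span[t.gene_id] = (t.chrom, s, e)
    bad_genes: set[str] = set()
    spans_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gid, (c, s, e) in gene_span.items():
        spans_by_chrom.setdefault(c, []).append((s, e, gid))
    for ivs in spans_by_chrom.values():
        ivs.sort()
        max_end, max_gene = -1, None
        for s, e, gid in ivs:
            if s < max_end:
                bad_genes.update((gid, max_gene))
            if e > max_end:
                max_end, max_gene = e, gid

    group_of = {tid: g for g in tss_groups for tid in g.member_transcript_ids}
    eligible = [
        t
        for t in transcripts
        if group_of[t.transcript_id].group_id not in bad_groups
        and t.gene_id not in bad_genes
    ]
    if not eligible:
        raise ValueError(
            "training set is empty: no isoform has uniquely assignable ChIP "
            "evidence; provide a larger or less overlapping annotation"
        )
    unit_ids = [t.transcript_id for t in eligible]
    counts = np.array([float(quantified_counts[u]) for u in unit_ids])
    table = pd.DataFrame(
        {
            "has_peak": [
                feat_by_group[group_of[u].group_id].has_peak for u in unit_ids
            ],
            "signal": [feat_by_group[group_of[u].group_id].signal for u in unit_ids],
        },
        index=unit_ids,
    )
    assignment = partition_units(table, model=model, **model_kwargs)
    labels = np.array([assignment[u] for u in unit_ids])
    return TrainingSet(unit_ids=unit_ids, counts=counts, labels=labels)


# ---------------------------------------------------------------------------
# Dirichlet-multinomial likelihood and fitting


def dm_log_likelihood(
    counts: np.ndarray | TrainingSet,
    labels: np.ndarray | None = None,
    alphas: Sequence[float] | None = None,
) -> float:
    """Log-probability of the training counts under a partitioned DM model.

    ln[ Gamma(N+1)/prod Gamma(n_i+1) * Gamma(A)/Gamma(N+A)
        * prod Gamma(n_i + a_g(i))/Gamma(a_g(i)) ],  A = sum_i a_g(i).

    Counts may be fractional (ML expected counts); everything goes through
    log-Gamma.  The multinomial coefficient is constant in alpha but kept so
    the value is a true log-probability for integer counts.
    """
    if isinstance(counts, TrainingSet):
        ts = counts
        counts, labels = ts.counts, ts.labels
    n = np.asarray(counts, dtype=float)
    g = np.asarray(labels, dtype=int)
    a = np.asarray(alphas, dtype=float)
    if np.any(a <= 0):
        raise ValueError("all alphas must be positive")
    if np.any(n < 0):
        raise ValueError("counts must be non-negative")
    alpha_i = a[g - 1]
    N = n.sum()
    A = alpha_i.sum()
    return float(
        gammaln(N + 1)
        - gammaln(n + 1).sum()
        + gammaln(A)
        - gammaln(N + A)
        + (gammaln(n + alpha_i) - gammaln(alpha_i)).sum()
    )


def fit_prior(
    training: TrainingSet,
    model: str = "two_partition_peak",
    alpha_min: float = ALPHA_MIN,
    alpha_max: float = ALPHA_MAX,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> PriorSpec:
    """Maximum-likelihood Dirichlet pseudocounts, one per partition.

    Optimises the DM log-likelihood over ln(alpha) with L-BFGS-B inside
    [alpha_min, alpha_max], starting from alpha = 1.
    """
    G = training.n_partitions
    import warnings

    for g in range(1, G + 1):
        if (training.labels == g).sum() < 2:
            warnings.warn(f"partition {g} has fewer than 2 training units")

    def neg_ll(x: np.ndarray) -> float:
        return -dm_log_likelihood(training.counts, training.labels, np.exp(x))

    bounds = [(np.log(alpha_min), np.log(alpha_max))] * G
    res = minimize(
        neg_ll,
        x0=np.zeros(G),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol * 1e-4, "gtol": 1e-8},
    )
    if not res.success:
        # line-search failures on flat likelihoods: polish with the
        # derivative-free simplex from the last iterate
        res2 = minimize(
            neg_ll,
            x0=res.x,
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxiter": 10 * max_iter, "fatol": tol, "xatol": 1e-8},
        )
        if res2.fun <= res.fun:
            res = res2
        if not res.success:
            raise RuntimeError(
                f"prior fit did not converge: {res.message}; last alphas "
                f"{np.exp(res.x)}"
            )
    # coordinate-wise bounded polish: quasi-Newton steps stall on the flat
    # plateaus that arise when a partition's MLE sits at a bound
    from scipy.optimize import minimize_scalar

    x = res.x.copy()
    fx = res.fun
    for _ in range(2):
        for g in range(G):

            def f1(v, g=g):
                xv = x.copy()
                xv[g] = v
                return neg_ll(xv)

            r1 = minimize_scalar(
                f1,
                bounds=bounds[g],
                method="bounded",
                options={"xatol": 1e-10},
            )
            if r1.fun < fx:
                x[g] = r1.x
                fx = r1.fun
    alphas = {g + 1: float(np.exp(x[g])) for g in range(G)}
    assignment = {u: int(l) for u, l in zip(training.unit_ids, training.labels)}
    return PriorSpec(
        partition_model=model,
        alphas=alphas,
        assignment=assignment,
        log_likelihood=float(-fx),
    )


# ---------------------------------------------------------------------------
# Partition models


def partition_units(
    feature_table: pd.DataFrame,
    model: str = "two_partition_peak",
    k: int | None = None,
    responses: pd.Series | None = None,
) -> dict[str, int]:
    """Map units to partitions 1..G.

    ``feature_table`` is indexed by unit id with a boolean ``has_peak``
    column and one or more numeric signal columns.  Models:

    - ``two_partition_peak``: partition 1 = has a TSS peak, 2 = no peak.
    - ``no_partition``: a single partition.
    - ``signal_quantile``: ``k`` equal-frequency groups of ``signal``.
    - ``peak_plus_signal``: no-peak units in partition 1; with-peak units
      split at their median signal into partitions 2 (low) and 3 (high).
    - ``logistic_combined``: logistic regression of a boolean expressed
      response on log1p of every signal column, thresholded at fitted
      probability 0.5 (partition 1 = predicted expressed).
    """
    units = list(feature_table.index)
    if model == "two_partition_peak":
        return {
            u: (1 if bool(feature_table.at[u, "has_peak"]) else 2) for u in units
        }
    if model == "no_partition":
        return {u: 1 for u in units}
    if model == "signal_quantile":
        if k is None or k < 2:
            raise ValueError("signal_quantile requires k >= 2")
        signal = feature_table["signal"].astype(float)
        try:
            codes = pd.qcut(signal, q=k, labels=False, duplicates="raise")
        except ValueError as exc:
            raise ValueError(
                f"cannot split signals into {k} quantile groups: {exc}"
            ) from exc
        return {u: int(c) + 1 for u, c in codes.items()}
    if model == "peak_plus_signal":
        has_peak = feature_table["has_peak"].astype(bool)
        signal = feature_table["signal"].astype(float)
        out: dict[str, int] = {}
        with_peak = [u for u in units if has_peak[u]]
        if len(with_peak) < 2 or signal[with_peak].nunique() < 2:
            raise ValueError("cannot split with-peak units by signal")
        med = float(signal[with_peak].median())
        for u in units:
            if not has_peak[u]:
                out[u] = 1
            elif signal[u] <= med:
                out[u] = 2
            else:
                out[u] = 3
        if len({v for v in out.values()}) < 3:
            raise ValueError("degenerate peak_plus_signal split")
        return out
    if model == "logistic_combined":
        if responses is None:
            raise ValueError("logistic_combined requires training responses")
        from sklearn.linear_model import LogisticRegression

        signal_cols = [
            c
            for c in feature_table.columns
            if c != "has_peak" and pd.api.types.is_numeric_dtype(feature_table[c])
        ]
        X = np.log1p(feature_table[signal_cols].astype(float).to_numpy())
        y = responses.reindex(feature_table.index).astype(bool).to_numpy()
        if y.all() or (~y).all():
            raise ValueError("responses are constant; cannot fit")
        clf = LogisticRegression(solver="lbfgs", max_iter=1000)
        clf.fit(X, y)
        prob = clf.predict_proba(X)[:, list(clf.classes_).index(True)]
        return {u: (1 if p >= 0.5 else 2) for u, p in zip(units, prob)}
    raise ValueError(f"unknown partition model {model!r}")


# ---------------------------------------------------------------------------
# Source comparison and informativeness


def compare_prior_sources(
    counts: np.ndarray,
    candidates: Mapping[str, np.ndarray],
) -> list[dict]:
    """Fit the DM model under each candidate partitioning of the same counts
    and rank sources by maximised training log-likelihood (descending; ties
    broken lexicographically by name)."""
    records = []
    for name in sorted(candidates):
        labels = np.asarray(candidates[name], dtype=int)
        ts = TrainingSet(
            unit_ids=[f"u{i}" for i in range(len(labels))],
            counts=np.asarray(counts, dtype=float),
            labels=labels,
        )
        spec = fit_prior(ts, model=name)
        records.append(
            {
                "source": name,
                "log_likelihood": spec.log_likelihood,
                "alphas": spec.alphas,
            }
        )
    records.sort(key=lambda r: (-r["log_likelihood"], r["source"]))
    return records


def informativeness_test(
    counts: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 199,
    seed: int = 0,
) -> dict:
    """Permutation test of whether a two-way partitioning is informative.

    Statistic: maximised two-partition DM log-likelihood minus the maximised
    single-partition log-likelihood (always >= 0 by nesting).  The null
    distribution permutes the partition labels over units.
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("informativeness test requires exactly 2 partitions")
    unit_ids = [f"u{i}" for i in range(len(counts))]

    def two_part_ll(lab: np.ndarray) -> float:
        lab01 = np.where(lab == uniq[0], 1, 2)
        ts = TrainingSet(unit_ids=unit_ids, counts=counts, labels=lab01)
        return fit_prior(ts).log_likelihood

    ll_null = fit_prior(
        TrainingSet(unit_ids=unit_ids, counts=counts, labels=np.ones(len(counts), int)),
        model="no_partition",
    ).log_likelihood
    observed = two_part_ll(labels) - ll_null
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        stat = two_part_ll(perm) - ll_null
        if stat >= observed - 1e-9:
            n_ge += 1
    p = (1 + n_ge) / (n_permutations + 1)
    return {"statistic": float(observed), "p_value": float(p)}


def gene_peak_status(
    tss_groups: Sequence[TssGroup],
    features: Sequence[TssFeature],
) -> dict[str, str]:
    """Classify genes as 'all' / 'mixed' / 'none' by whether all, some, or no
    isoform TSS groups carry a peak."""
    has = {f.unit_id: f.has_peak for f in features}
    by_gene: dict[str, list[bool]] = {}
    for g in tss_groups:
        by_gene.setdefault(g.gene_id, []).append(has[g.group_id])
    out = {}
    for gene, flags in by_gene.items():
        if all(flags):
            out[gene] = "all"
        elif any(flags):
            out[gene] = "mixed"
        else:
            out[gene] = "none"
    return out


# ---------------------------------------------------------------------------
# Prior file I/O (fixed column orders)


def write_prior(prefix: str, prior: PriorSpec) -> None:
    """Write ``<prefix>.prior.tsv`` (partition_id, alpha, n_training_units)
    and ``<prefix>.assignment.tsv`` (unit_id, partition_id)."""
    n_units = {g: 0 for g in prior.alphas}
    for g in prior.assignment.values():
        n_units[g] += 1
    pd.DataFrame(
        {
            "partition_id": list(prior.alphas),
            "alpha": [prior.alphas[g] for g in prior.alphas],
            "n_training_units": [n_units[g] for g in prior.alphas],
        }
    ).to_csv(f"{prefix}.prior.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "unit_id": list(prior.assignment),
            "partition_id": [prior.assignment[u] for u in prior.assignment],
        }
    ).to_csv(f"{prefix}.assignment.tsv", sep="\t", index=False)


def read_prior(prefix: str, partition_model: str = "two_partition_peak") -> PriorSpec:
    ptab = pd.read_csv(f"{prefix}.prior.tsv", sep="\t")
    atab = pd.read_csv(f"{prefix}.assignment.tsv", sep="\t")
    return PriorSpec(
        partition_model=partition_model,
        alphas={int(r.partition_id): float(r.alpha) for r in ptab.itertuples()},
        assignment={str(r.unit_id): int(r.partition_id) for r in atab.itertuples()},
    )
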