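"""Transcript annotation model.

Parses GTF transcript structures, derives strand-aware transcription start
sites (TSSs), clusters isoforms of a gene into TSS groups, computes effective
lengths under a fragment-length model, and decides structural isoform
distinguishability.

Coordinate conventions
----------------------
All genomic intervals are 0-based, half-open internally.  GTF input (1-based,
closed) is converted on read.  The TSS is the 5'-most transcribed base of an
isoform: the start of the first exon on the ``+`` strand and ``end - 1`` of
the last exon on the ``-`` strand.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

__all__ = [
    "Transcript",
    "TssGroup",
    "DistinguishabilityReport",
    "parse_annotation",
    "cluster_tss_groups",
    "effective_lengths",
    "distinguishability",
    "write_transcript_table",
]


@dataclass(frozen=True)
class Transcript:
    """One isoform: an ordered chain of disjoint exons on a strand.

    ``exons`` are 0-based half-open genomic intervals sorted by genomic
    coordinate and pairwise disjoint.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty exon [{start},{end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or unsorted"
                )
            prev_end = end

    @property
    def length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1] - 1

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent [first exon start, last exon end)."""
        return self.exons[0][0], self.exons[-1][1]

    # -- coordinate mapping ------------------------------------------------

    def _chain(self) -> tuple[tuple[int, int], ...]:
        """Exons in transcript (5'->3') order."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def genomic_to_transcript(self, g: int) -> int | None:
        """Transcript coordinate of genomic base ``g``, or None if intronic."""
        starts = [s for s, _ in self.exons]
        k = bisect.bisect_right(starts, g) - 1
        if k < 0:
            return None
        s, e = self.exons[k]
        if not (s <= g < e):
            return None
        if self.strand == "+":
            before = sum(e2 - s2 for s2, e2 in self.exons[:k])
            return before + (g - s)
        after = sum(e2 - s2 for s2, e2 in self.exons[k + 1 :])
        return after + (e - 1 - g)

    def footprint(self, p: int, length: int) -> tuple[tuple[int, int], ...]:
        """Genomic intervals covered by a fragment of ``length`` starting at
        transcript coordinate ``p``; intervals in genomic order."""
        if p < 0 or p + length > self.length:
            raise ValueError("fragment outside transcript")
        pieces = []
        remaining = length
        offset = p
        for s, e in self._chain():
            exon_len = e - s
            if offset >= exon_len:
                offset -= exon_len
                continue
            take = min(exon_len - offset, remaining)
            if self.strand == "+":
                pieces.append((s + offset, s + offset + take))
            else:
                pieces.append((e - offset - take, e - offset))
            remaining -= take
            offset = 0
            if remaining == 0:
                break
        return tuple(sorted(pieces))


@dataclass(frozen=True)
class TssGroup:
    """Isoforms of one gene whose TSSs chain together within a distance."""

    group_id: str
    gene_id: str
    chrom: str
    member_transcript_ids: tuple[str, ...]
    member_tsss: tuple[int, ...]
    representative_tss: int


@dataclass(frozen=True)
class DistinguishabilityReport:
    transcript_id: str
    indistinguishable: bool
    fragment_length: int
    witness_fragments: int


# ---------------------------------------------------------------------------
# GTF parsing


def _validate_gtf_lines(path: str) -> None:
    required = ("gene_id", "transcript_id")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "exon":
                continue
            attrs = fields[8]
            for key in required:
                if key not in attrs:
                    raise ValueError(
                        f"{path}:{lineno}: exon record missing attribute {key!r}"
                    )


def parse_annotation(gtf_path: str) -> list[Transcript]:
    """Read a GENCODE-dialect GTF into :class:`Transcript` records.

    Exons are collected per ``transcript_id``, merged and sorted; output is
    ordered by (chrom, span start, transcript_id).  Records missing
    ``gene_id``/``transcript_id`` raise with the offending line number.
    """
    _validate_gtf_lines(gtf_path)
    db = gffutils.create_db(
        gtf_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        rec = exons.setdefault(
            tid, {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand, "exons": []}
        )
        # GTF is 1-based closed; convert to 0-based half-open
        rec["exons"].append((feat.start - 1, feat.end))
    declared = {
        feat.attributes["transcript_id"][0]
        for feat in db.features_of_type("transcript")
        if "transcript_id" in feat.attributes
    }
    exonless = sorted(declared - set(exons))
    if exonless:
        raise ValueError(f"transcripts with zero exons rejected: {exonless}")
    transcripts = []
    for tid, rec in exons.items():
        merged = sorted(set(rec["exons"]))
        transcripts.append(
            Transcript(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(merged),
            )
        )
    transcripts.sort(key=lambda t: (t.chrom, t.span[0], t.transcript_id))
    return transcripts


# ---------------------------------------------------------------------------
# TSS groups


def cluster_tss_groups(
    transcripts: Iterable[Transcript], distance: int = 500
) -> list[TssGroup]:
    """Single-linkage clustering of each gene's isoform TSSs.

    Two isoforms of the same gene fall in one group when a chain of member
    TSSs with consecutive gaps <= ``distance`` (inclusive) connects them.
    The group representative is the minimum member TSS.  Groups from
    different genes never merge.
    """
    by_gene: dict[str, list[Transcript]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    groups: list[TssGroup] = []
    for gene_id in sorted(by_gene):
        members = sorted(by_gene[gene_id], key=lambda t: (t.tss, t.transcript_id))
        # in 1-D, single linkage == split at consecutive gaps > distance
        clusters: list[list[Transcript]] = []
        for t in members:
            if clusters and t.tss - clusters[-1][-1].tss <= distance:
                clusters[-1].append(t)
            else:
                clusters.append([t])
        for i, cl in enumerate(clusters, start=1):
            groups.append(
                TssGroup(
                    group_id=f"{gene_id}:tg{i}",
                    gene_id=gene_id,
                    chrom=cl[0].chrom,
                    member_transcript_ids=tuple(t.transcript_id for t in cl),
                    member_tsss=tuple(t.tss for t in cl),
                    representative_tss=min(t.tss for t in cl),
                )
            )
    return groups


# ---------------------------------------------------------------------------
# Effective lengths


def effective_lengths(
    transcripts: Iterable[Transcript],
    fragment_length_model: int | Mapping[int, float],
) -> dict[str, float]:
    """Number of valid fragment start positions per transcript.

    With a fixed fragment length ``L``: ``max(len - L + 1, 1)``.  With a
    discrete length distribution ``P(l)``: ``max(sum_l P(l) * max(len - l + 1,
    0), 1)``.
    """
    if isinstance(fragment_length_model, Mapping):
        dist = dict(fragment_length_model)
        if not dist or any(l <= 0 for l in dist):
            raise ValueError("fragment lengths must be positive")
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("fragment length probabilities must sum to 1")

        def ell(n: int) -> float:
            return max(sum(p * max(n - l + 1, 0) for l, p in dist.items()), 1.0)

    else:
        L = int(fragment_length_model)
        if L <= 0:
            raise ValueError("fragment length must be positive")

        def ell(n: int) -> float:
            return float(max(n - L + 1, 1))

    return {t.transcript_id: ell(t.length) for t in transcripts}


# ---------------------------------------------------------------------------
# Distinguishability


def fragment_compatible(
    source: Transcript, p: int, length: int, target: Transcript
) -> int | None:
    """Transcript coordinate in ``target`` where a fragment of ``source``
    starting at ``p`` aligns, or None.

    Compatibility is structural: the fragment's genomic exonic footprint must
    be reproduced exactly as a contiguous sub-path of ``target``'s exon chain.
    """
    fp = source.footprint(p, length)
    first_base = fp[0][0] if target.strand == "+" else fp[-1][1] - 1
    q = target.genomic_to_transcript(first_base)
    if q is None or q + length > target.length:
        return None
    if target.footprint(q, length) == fp:
        return q
    return None


def distinguishability(
    transcripts: Sequence[Transcript], fragment_length: int
) -> list[DistinguishabilityReport]:
    """Per-isoform distinguishability within one gene locus.

    An isoform is indistinguishable when every fragment it can generate is
    structurally compatible with at least one other isoform of the gene —
    i.e. it has zero witness fragments of its own.
    """
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    genes = {t.gene_id for t in transcripts}
    if len(genes) > 1:
        raise ValueError(f"transcripts span multiple genes: {sorted(genes)}")
    reports = []
    for t in transcripts:
        others = [o for o in transcripts if o.transcript_id != t.transcript_id]
        witnesses = 0
        for p in range(0, t.length - fragment_length + 1):
            if not any(
                fragment_compatible(t, p, fragment_length, o) is not None
                for o in others
            ):
                witnesses += 1
        reports.append(
            DistinguishabilityReport(
                transcript_id=t.transcript_id,
                indistinguishable=(witnesses == 0),
                fragment_length=fragment_length,
                witness_fragments=witnesses,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# Table output


def write_transcript_table(
    path: str,
    transcripts: Sequence[Transcript],
    eff_lengths: Mapping[str, float],
    tss_groups: Sequence[TssGroup],
) -> pd.DataFrame:
    """Write the fixed-column transcript table TSV and return it."""
    group_of = {
        tid: g.group_id for g in tss_groups for tid in g.member_transcript_ids
    }
    rows = [
        {
            "transcript_id": t.transcript_id,
            "gene_id": t.gene_id,
            "chrom": t.chrom,
            "strand": t.strand,
            "tss": t.tss,
            "length": t.length,
            "effective_length": eff_lengths[t.transcript_id],
            "tss_group_id": group_of[t.transcript_id],
        }
        for t in transcripts
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "gene_id",
            "chrom",
            "strand",
            "tss",
            "length",
            "effective_length",
            "tss_group_id",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    return df
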