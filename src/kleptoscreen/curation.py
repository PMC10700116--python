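"""Gene-model curation and annotation summary statistics.

Two annotation runs are merged: the primary run on the repeat-masked assembly
plus any gene models unique to an unmasked run that can be "rescued". An
unmasked model is rescued only if it does not intersect any masked gene span,
has a significant BLASTp hit to model animal proteomes (e < 1e-3), does not
intersect a classified repeat element, and has no exon more than half covered
by simple sequence repeats. The merged set is then scored against three
evidence sources (RNA-seq expression, orthology, functional annotation); the
high-confidence set is every gene with at least two of the three.

All coordinates are 1-based inclusive (GFF3 convention); interval overlap of
[s1,e1] and [s2,e2] is max(0, min(e1,e2) - max(s1,s2) + 1).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GeneModel",
    "AnnotationSummary",
    "overlap_bp",
    "interval_overlap",
    "rescue_unmasked_models",
    "high_confidence_set",
    "percent",
    "summarize_annotation",
]


@dataclass(frozen=True)
class GeneModel:
    """A contig-anchored exon structure from one annotation run."""

    gene_id: str
    contig_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    transcripts: int = 1
    source_run: str = "masked"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        prev_end = 0
        for s, e in self.exons:
            if e < s:
                raise ValueError(f"exon end < start in {self.gene_id}")
            if s <= prev_end:
                raise ValueError(f"exons overlap or are unsorted in {self.gene_id}")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        """Genomic span length (introns included)."""
        s, e = self.span
        return e - s + 1


def overlap_bp(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Overlap in bp between two 1-based inclusive intervals."""
    for s, e in (a, b):
        if e < s:
            raise ValueError(f"interval end < start: {(s, e)}")
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def interval_overlap(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, float]]:
    """Per-interval-of-a total overlap with b, as (bp, fraction of a).

    Overlapping b intervals are not merged; callers that need merged coverage
    (the simple-repeat exon rule) should pass disjoint intervals.
    """
    out = []
    for iv in a:
        bp = sum(overlap_bp(iv, jv) for jv in b)
        out.append((bp, bp / (iv[1] - iv[0] + 1)))
    return out


def _covered_fraction(iv: tuple[int, int], others: Sequence[tuple[int, int]]) -> float:
    """Fraction of iv covered by the union of others (union taken properly)."""
    s, e = iv
    clipped = sorted(
        (max(s, x), min(e, y)) for x, y in others if overlap_bp(iv, (x, y)) > 0
    )
    covered = 0
    cur_s = cur_e = None
    for x, y in clipped:
        if cur_e is None or x > cur_e + 1:
            if cur_e is not None:
                covered += cur_e - cur_s + 1
            cur_s, cur_e = x, y
        else:
            cur_e = max(cur_e, y)
    if cur_e is not None:
        covered += cur_e - cur_s + 1
    return covered / (e - s + 1)


def rescue_unmasked_models(
    masked: Iterable[GeneModel],
    unmasked: Iterable[GeneModel],
    blast_best_evalue: Mapping[str, float],
    repeats: Mapping[str, Sequence[tuple[int, int]]],
    simple_repeats: Mapping[str, Sequence[tuple[int, int]]],
    max_evalue: float = 1e-3,
    simple_repeat_frac: float = 0.5,
) -> list[GeneModel]:
    """Merge the masked gene set with rescue-qualified unmasked models.

    ``repeats`` / ``simple_repeats`` map contig id to interval lists.
    ``blast_best_evalue`` maps an unmasked gene id to its best BLASTp e-value
    against the model-animal proteome database (absent = no significant hit).
    Rescue requires zero-bp overlap with every masked gene span on the same
    contig, best e-value < ``max_evalue``, zero-bp overlap with classified
    repeats, and no exon with more than ``simple_repeat_frac`` of its length
    covered by simple repeats.
    """
    masked = list(masked)
    merged = list(masked)
    masked_spans: dict[str, list[tuple[int, int]]] = {}
    for m in masked:
        masked_spans.setdefault(m.contig_id, []).append(m.span)

    for u in sorted(unmasked, key=lambda g: g.gene_id):
        if any(overlap_bp(u.span, mv) > 0 for mv in masked_spans.get(u.contig_id, ())):
            continue
        ev = blast_best_evalue.get(u.gene_id)
        if ev is None or not ev < max_evalue:
            continue
        contig_repeats = repeats.get(u.contig_id, ())
        if any(
            overlap_bp(exon, rv) > 0 for exon in u.exons for rv in contig_repeats
        ):
            continue
        contig_simple = simple_repeats.get(u.contig_id, ())
        if any(
            _covered_fraction(exon, contig_simple) > simple_repeat_frac
            for exon in u.exons
        ):
            continue
        merged.append(u)
    return merged


def high_confidence_set(evidence: pd.DataFrame) -> set[str]:
    """Genes with >= 2 of the 3 evidence sources.

    ``evidence`` is indexed by gene id with boolean columns ``has_rnaseq``,
    ``has_orthology`` and ``has_function``.
    """
    required = {"has_rnaseq", "has_orthology", "has_function"}
    missing = required - set(evidence.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    n_support = evidence[sorted(required)].astype(bool).sum(axis=1)
    return set(evidence.index[n_support >= 2])


def percent(count: int, total: int) -> float:
    """100*count/total, half-up rounded to 2 decimals (as printed in reports)."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = (Decimal(count) * 100 / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass(frozen=True)
class AnnotationSummary:
    """Summary statistics of a gene-model set (one column of a report table)."""

    n_genes: int
    n_transcripts: int
    mean_gene_length: float
    median_gene_length: float
    mean_exons_per_transcript: float
    median_exons_per_transcript: float
    mean_exon_length: float
    median_exon_length: float
    evidence_counts: dict = field(default_factory=dict)
    evidence_percents: dict = field(default_factory=dict)

    def as_rows(self) -> list[tuple[str, str]]:
        rows = [
            ("No. protein-coding genes", f"{self.n_genes:,}"),
            ("No. transcripts", f"{self.n_transcripts:,}"),
            ("Mean gene length", f"{self.mean_gene_length:,.2f} bp"),
            ("Median gene length", f"{self.median_gene_length:,.0f} bp"),
            ("Mean no. exons per transcript", f"{self.mean_exons_per_transcript:.2f}"),
            ("Median no. exons per transcript", f"{self.median_exons_per_transcript:.0f}"),
            ("Mean exon length", f"{self.mean_exon_length:,.2f} bp"),
            ("Median exon length", f"{self.median_exon_length:,.0f} bp"),
        ]
        for name, count in self.evidence_counts.items():
            rows.append((name, f"{count:,} ({self.evidence_percents[name]:.2f}%)"))
        return rows


_EVIDENCE_LABELS = {
    "has_rnaseq": "No. genes supported by RNA-Seq",
    "has_function": "No. genes with functional annotation",
    "has_orthology": "No. genes assigned to an orthogroup",
}


def summarize_annotation(
    models: Sequence[GeneModel], evidence: pd.DataFrame | None = None
) -> AnnotationSummary:
    """Compute report-table summary statistics for a gene-model set.

    Gene length is the genomic span including introns; the median of an
    even-sized list is the mean of the central pair. Evidence percentages are
    half-up rounded to two decimals against the set size.
    """
    models = list(models)
    if not models:
        raise ValueError("empty gene-model set")
    gene_lengths = [m.length for m in models]
    exon_lengths = [e - s + 1 for m in models for s, e in m.exons]
    exons_per_tx = [len(m.exons) for m in models]
    counts: dict[str, int] = {}
    percents: dict[str, float] = {}
    if evidence is not None:
        ids = [m.gene_id for m in models]
        sub = evidence.reindex(ids).fillna(False)
        for col, label in _EVIDENCE_LABELS.items():
            if col in sub.columns:
                c = int(sub[col].astype(bool).sum())
                counts[label] = c
                percents[label] = percent(c, len(models))
    return AnnotationSummary(
        n_genes=len(models),
        n_transcripts=sum(m.transcripts for m in models),
        mean_gene_length=sum(gene_lengths) / len(gene_lengths),
        median_gene_length=statistics.median(gene_lengths),
        mean_exons_per_transcript=sum(exons_per_tx) / len(exons_per_tx),
        median_exons_per_transcript=statistics.median(exons_per_tx),
        mean_exon_length=sum(exon_lengths) / len(exon_lengths),
        median_exon_length=statistics.median(exon_lengths),
        evidence_counts=counts,
        evidence_percents=percents,
    )
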