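"""Alien Index screening of protein homology hits.

The Alien Index (AI) compares, for every predicted protein, the strength of
its best database hit *outside* the recipient lineage (Metazoa for a sea slug)
with the best hit *inside* the recipient lineage, after skipping hits to the
query's own sublineage (Placobranchoidea, which contains all sequenced
kleptoplastic slugs and therefore cannot vouch for vertical inheritance).
Hit strength is a normalized bitscore: the best HSP bitscore to a subject
divided by the query's self-alignment bitscore, clamped to [0, 1].

    AI = nbsO - nbsM,  AI in [-1, 1]

AI > 0 means the protein looks more like a non-metazoan sequence — either
horizontal transfer or contamination. Whole-contig contamination and
per-gene HGT candidacy are then decided by simple, fully specified rules.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "HomologyHit",
    "AIRecord",
    "ContigVerdict",
    "OrganelleHit",
    "normalized_bitscore",
    "collapse_best_hsp",
    "alien_index",
    "alien_index_table",
    "flag_contaminant_contigs",
    "filter_hgt_candidates",
    "flag_organelle_contigs",
]

RECIPIENT = "Metazoa"
SKIP = "Placobranchoidea"


@dataclass(frozen=True)
class HomologyHit:
    """One query->subject match (one HSP) with taxonomic lineage."""

    query_id: str
    subject_id: str
    bitscore: float
    evalue: float
    lineage: tuple[str, ...]
    is_self: bool = False

    def __post_init__(self):
        if self.bitscore < 0:
            raise ValueError(f"negative bitscore for {self.query_id}->{self.subject_id}")
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.query_id}->{self.subject_id}")


@dataclass(frozen=True)
class AIRecord:
    """Per-gene Alien Index result."""

    gene_id: str
    nbsO: float
    nbsM: float
    AI: float
    n_hits: int
    top_outgroup_subject: str | None = None


@dataclass(frozen=True)
class ContigVerdict:
    contig_id: str
    status: str  # nuclear | bacterial_contaminant | mitochondrial | kleptoplast
    evidence: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class OrganelleHit:
    """A tblastn-style hit of an organellar protein onto an assembly contig."""

    contig_id: str
    organelle: str  # mitochondrial | kleptoplast
    query_protein: str
    evalue: float


def normalized_bitscore(hit_bitscore: float, self_bitscore: float) -> float:
    """Bitscore of a hit divided by the query's self-alignment bitscore.

    Clamped to [0, 1]; a hit can occasionally out-score the self alignment
    (HSP bookkeeping differences), which must not push AI outside [-1, 1].
    """
    if self_bitscore <= 0:
        raise ValueError("self bitscore must be positive (self-hit missing?)")
    return min(1.0, max(0.0, hit_bitscore / self_bitscore))


def collapse_best_hsp(hits: Iterable[HomologyHit]) -> list[HomologyHit]:
    """Keep the single best-scoring HSP per subject.

    Ties on bitscore are broken by lower e-value, then lexicographically
    smallest subject id, so the result is deterministic.
    """
    best: dict[str, HomologyHit] = {}
    for h in hits:
        cur = best.get(h.subject_id)
        if cur is None or (-h.bitscore, h.evalue) < (-cur.bitscore, cur.evalue):
            best[h.subject_id] = h
    return [best[s] for s in sorted(best)]


def _is_self(hit: HomologyHit, gene_id: str) -> bool:
    return hit.is_self or hit.subject_id == gene_id


def alien_index(
    hits: Sequence[HomologyHit],
    recipient: str = RECIPIENT,
    skip: str = SKIP,
) -> AIRecord:
    """Compute the Alien Index for one gene from its homology hits.

    ``nbsM`` is the best normalized bitscore among hits whose lineage contains
    ``recipient`` but not ``skip``; ``nbsO`` the best among hits whose lineage
    contains neither. A side with no qualifying hit contributes nbs = 0, so a
    lineage-restricted gene gets AI = nbsO. The hit list must contain the
    query's self-hit (same subject id, or ``is_self``) to normalize against.
    """
    hits = list(hits)
    if not hits:
        raise ValueError("empty hit list")
    gene_id = hits[0].query_id
    collapsed = collapse_best_hsp(hits)

    self_hits = [h for h in collapsed if _is_self(h, gene_id)]
    if not self_hits:
        raise ValueError(f"no self-hit found for gene {gene_id}")
    self_bs = max(h.bitscore for h in self_hits)

    nbsO = 0.0
    nbsM = 0.0
    top_out: str | None = None
    for h in collapsed:
        if skip in h.lineage:
            continue  # skip-lineage hits count on neither side
        nbs = normalized_bitscore(h.bitscore, self_bs)
        if recipient in h.lineage:
            nbsM = max(nbsM, nbs)
        elif nbs > nbsO or (nbs == nbsO and top_out is None):
            nbsO = nbs
            top_out = h.subject_id
    ai = nbsO - nbsM
    return AIRecord(gene_id, nbsO, nbsM, ai, n_hits=len(collapsed), top_outgroup_subject=top_out)


def alien_index_table(
    hits: Iterable[HomologyHit],
    recipient: str = RECIPIENT,
    skip: str = SKIP,
) -> list[AIRecord]:
    """Group a flat hit table by query and compute one AIRecord per gene."""
    by_gene: dict[str, list[HomologyHit]] = defaultdict(list)
    for h in hits:
        by_gene[h.query_id].append(h)
    return [alien_index(by_gene[g], recipient, skip) for g in sorted(by_gene)]


def flag_contaminant_contigs(
    records: Sequence[AIRecord],
    gene_to_contig: Mapping[str, str],
    high_ai: float = 0.1,
) -> list[ContigVerdict]:
    """Flag whole contigs as bacterial contamination from their genes' AI.

    A contig is flagged iff the minimum AI over its genes is > 0, or at least
    half of its genes have AI > ``high_ai``. All other contigs with genes are
    reported as nuclear.
    """
    by_contig: dict[str, list[AIRecord]] = defaultdict(list)
    for r in records:
        try:
            contig = gene_to_contig[r.gene_id]
        except KeyError:
            raise KeyError(f"gene {r.gene_id} has no contig mapping") from None
        by_contig[contig].append(r)

    verdicts = []
    for contig in sorted(by_contig):
        recs = by_contig[contig]
        ais = [r.AI for r in recs]
        min_rule = min(ais) > 0
        frac_rule = sum(a > high_ai for a in ais) >= 0.5 * len(ais)
        if min_rule or frac_rule:
            rule = "min_ai_gt0" if min_rule else "half_genes_ai_gt0.1"
            ev = (rule,) + tuple(r.gene_id for r in recs)
            verdicts.append(ContigVerdict(contig, "bacterial_contaminant", ev))
        else:
            verdicts.append(ContigVerdict(contig, "nuclear"))
    return verdicts


def filter_hgt_candidates(
    records: Sequence[AIRecord],
    contaminant_contigs: set[str],
    gene_to_contig: Mapping[str, str],
    min_ai: float = 0.1,
    min_hits: int = 50,
) -> list[AIRecord]:
    """Retain phylogenetically informative HGT candidates.

    A gene is kept iff AI > min_ai (strict), its total database hits
    (post-HSP-collapse subjects) >= min_hits, and it does not sit on a
    contamination-flagged contig.
    """
    out = []
    for r in records:
        if r.AI > min_ai and r.n_hits >= min_hits:
            if gene_to_contig.get(r.gene_id) not in contaminant_contigs:
                out.append(r)
    return out


def flag_organelle_contigs(
    hits: Iterable[OrganelleHit],
    max_evalue: float = 1e-5,
    min_hits: int = 2,
) -> list[ContigVerdict]:
    """Flag contigs as organelle-derived from organellar-protein tblastn hits.

    A contig is flagged for an organelle iff it has >= ``min_hits`` hits with
    e-value <= ``max_evalue`` to that organelle's protein set. If a contig
    qualifies for both organelles the one with more qualifying hits wins
    (tie: smaller minimum e-value).
    """
    sig: dict[str, dict[str, list[OrganelleHit]]] = defaultdict(lambda: defaultdict(list))
    for h in hits:
        if h.organelle not in ("mitochondrial", "kleptoplast"):
            raise ValueError(f"unknown organelle {h.organelle!r}")
        if h.evalue <= max_evalue:
            sig[h.contig_id][h.organelle].append(h)

    verdicts = []
    for contig in sorted(sig):
        qualifying = {o: hs for o, hs in sig[contig].items() if len(hs) >= min_hits}
        if not qualifying:
            continue
        winner = min(
            qualifying, key=lambda o: (-len(qualifying[o]), min(h.evalue for h in qualifying[o]))
        )
        ev = tuple(h.query_protein for h in qualifying[winner])
        verdicts.append(ContigVerdict(contig, winner, ev))
    return verdicts
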