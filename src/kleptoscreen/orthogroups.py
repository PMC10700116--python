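"""Orthogroup presence/absence patterns and candidate-gene discovery.

Five gastropod proteomes anchor the comparison: four kleptoplastic sacoglossan
slugs and one non-kleptoplastic outgroup (a sea hare). Orthogroups are
classified by which species they contain; the interesting class is
"klepto_specific" — present in all four kleptoplastic species and absent in
the outgroup — whose focal-species members that are also fed-stage DEGs form
the kleptoplasty candidate gene set. Hypergeometric upper-tail tests score
functional-term enrichment of any gene set against a background universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .stats import bh_adjust

__all__ = [
    "Orthogroup",
    "PatternClass",
    "select_longest_isoform",
    "classify_patterns",
    "candidate_genes",
    "hypergeom_enrichment",
    "extract_domain_span",
]


@dataclass(frozen=True)
class Orthogroup:
    og_id: str
    members: tuple[tuple[str, tuple[str, ...]], ...]  # (species, gene ids), genes may be empty

    @property
    def present_species(self) -> frozenset[str]:
        return frozenset(sp for sp, genes in self.members if genes)

    def genes_of(self, species: str) -> tuple[str, ...]:
        for sp, genes in self.members:
            if sp == species:
                return genes
        return ()


@dataclass(frozen=True)
class PatternClass:
    og_id: str
    present_species: frozenset[str]
    pattern: str  # conserved_all | klepto_specific | singleton | other


def select_longest_isoform(isoforms: Mapping[str, str]) -> str:
    """Pick the representative isoform id for a gene: longest protein,
    ties broken by lexicographically smallest id."""
    if not isoforms:
        raise ValueError("gene has no isoforms")
    return min(isoforms, key=lambda i: (-len(isoforms[i]), i))


def classify_patterns(
    orthogroups: Iterable[Orthogroup],
    kleptoplastic: set[str],
    outgroup: set[str],
) -> list[PatternClass]:
    """Assign each orthogroup a presence/absence pattern class.

    conserved_all: present in every declared species; klepto_specific: all
    kleptoplastic present and every outgroup species absent; singleton:
    exactly one species; everything else: other.
    """
    declared = kleptoplastic | outgroup
    out = []
    for og in orthogroups:
        present = og.present_species
        undeclared = present - declared
        if undeclared:
            raise ValueError(f"undeclared species in {og.og_id}: {sorted(undeclared)}")
        if present == declared:
            cls = "conserved_all"
        elif kleptoplastic <= present and not (present & outgroup):
            cls = "klepto_specific"
        elif len(present) == 1:
            cls = "singleton"
        else:
            cls = "other"
        out.append(PatternClass(og.og_id, present, cls))
    return out


def candidate_genes(
    patterns: Sequence[PatternClass],
    orthogroups: Mapping[str, Orthogroup],
    focal_species: str,
    deg_set: set[str],
) -> dict[str, set[str]]:
    """Per pattern class, focal-species genes intersected with the DEG set."""
    out: dict[str, set[str]] = {}
    for pc in patterns:
        genes = set(orthogroups[pc.og_id].genes_of(focal_species))
        out.setdefault(pc.pattern, set()).update(genes & deg_set)
    return out


def hypergeom_enrichment(
    gene_set: set[str],
    term_map: Mapping[str, Sequence[str]],
    background: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of functional terms, BH-adjusted.

    For each term with at least one hit in the gene set: N = background size,
    K = background genes carrying the term, n = gene-set size, k = gene-set
    genes carrying the term, p = P(X >= k) for X ~ Hypergeom(N, K, n).
    Terms with k = 0 are not tested.
    """
    if not gene_set <= background:
        raise ValueError("gene set must be a subset of the background")
    n_bg = len(background)
    n_set = len(gene_set)
    term_bg: dict[str, int] = {}
    term_hits: dict[str, int] = {}
    for gene in background:
        for term in term_map.get(gene, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in gene_set:
                term_hits[term] = term_hits.get(term, 0) + 1
    rows = []
    for term in sorted(term_hits):
        k, big_k = term_hits[term], term_bg[term]
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n_set))
        rows.append((term, k, big_k, n_set, n_bg, p))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "pvalue"])
    df["fdr"] = bh_adjust(df["pvalue"].to_numpy()) if len(df) else []
    return df


def extract_domain_span(
    domain_hits: Sequence[tuple[str, int, int]],
    required_profiles: set[str],
    min_len: int = 350,
    max_len: int = 650,
) -> tuple[int, int] | None:
    """Maximum region spanning all required domain profiles, length-filtered.

    ``domain_hits`` are (profile id, start, end), 1-based inclusive on the
    protein. Returns [min start, max end] over the required profiles' hits if
    every required profile has a hit and the span length lies within
    [min_len, max_len]; otherwise None.
    """
    hits_of: dict[str, list[tuple[int, int]]] = {}
    for prof, start, end in domain_hits:
        if start < 1 or end < start:
            raise ValueError(f"malformed domain hit {(prof, start, end)}")
        hits_of.setdefault(prof, []).append((start, end))
    if not required_profiles <= set(hits_of):
        return None
    starts = [s for p in required_profiles for s, _ in hits_of[p]]
    ends = [e for p in required_profiles for _, e in hits_of[p]]
    span = (min(starts), max(ends))
    length = span[1] - span[0] + 1
    if min_len <= length <= max_len:
        return span
    return None
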