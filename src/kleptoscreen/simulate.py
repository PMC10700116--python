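"""Self-contained synthetic genome-study generator with recorded ground truth.

The generator emulates the data shapes of a sea-slug genome project so that
every downstream stage (Alien Index screening, gene-model curation,
expression analysis, orthogroup candidate discovery, tree checks) can be
exercised and scored without any external downloads:

* a mostly recipient-lineage (metazoan) gene complement on nuclear contigs;
* spiked bacterial contaminant contigs whose genes hit non-metazoan
  sequences with normalized bitscores near 1;
* exactly ``n_hgt_genes`` genuine HGT genes — strong non-metazoan best hit,
  sitting on contigs of otherwise metazoan-hit genes, with a supporting
  donor-clade phylogeny;
* organelle-derived contigs detectable from organellar-protein hits;
* a 4-stage x 3-replicate count matrix under a negative-binomial noise
  model with fed-stage (juvenile) upregulation spiked into ``n_deg`` genes;
* orthogroup tables in which a subset of the spiked DEGs are members of
  kleptoplast-specific gene families (the planted candidate set).

One integer seed fully determines every output file; component-local
substreams are derived from it by fixed offsets so the pieces regenerate
reproducibly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as kio
from .curation import GeneModel
from .expression import CountMatrix, STAGES
from .homology import HomologyHit, OrganelleHit
from .orthogroups import Orthogroup

__all__ = [
    "FixtureConfig",
    "FixtureConfigError",
    "GroundTruth",
    "StudyBundle",
    "simulate_nb_counts",
    "simulate_study",
]

SPECIES = ("Ecla", "Echl", "Pocc", "Emar", "Acal")
KLEPTO_SPECIES = {"Ecla", "Echl", "Pocc", "Emar"}
OUTGROUP_SPECIES = {"Acal"}

# fixed 3-level toy taxonomy: (domain, clade, species)
LIN_SELF = ("Metazoa", "Placobranchoidea", "Elysia_crispata")
LIN_SKIP = [
    ("Metazoa", "Placobranchoidea", "Elysia_chlorotica"),
    ("Metazoa", "Placobranchoidea", "Plakobranchus_ocellatus"),
]
LIN_METAZOA = [
    ("Metazoa", "Aplysiida", "Aplysia_californica"),
    ("Metazoa", "Bivalvia", "Crassostrea_virginica"),
    ("Metazoa", "Vertebrata", "Danio_rerio"),
    ("Metazoa", "Vertebrata", "Mus_musculus"),
]
LIN_BACTERIA = [
    ("Bacteria", "Proteobacteria", "Escherichia_coli"),
    ("Bacteria", "Proteobacteria", "Vibrio_harveyi"),
    ("Bacteria", "Firmicutes", "Bacillus_subtilis"),
    ("Bacteria", "Cyanobacteriota", "Synechococcus_elongatus"),
]
LIN_ALGAE = [
    ("Viridiplantae", "Bryopsidales", "Penicillus_capitatus"),
    ("Viridiplantae", "Chlorophyta", "Chlamydomonas_reinhardtii"),
]
LIN_VIRUS = [
    ("Riboviria", "Negarnaviricota", "Hubei_myriapoda_virus"),
    ("Riboviria", "Negarnaviricota", "Beihai_rhabdo_virus"),
    ("Riboviria", "Lenarviricota", "Wenling_narna_virus"),
]


class FixtureConfigError(ValueError):
    """Invalid fixture configuration; the message names the offending field."""


@dataclass(frozen=True)
class FixtureConfig:
    """Study-design knobs for the synthetic fixture (defaults = the study
    conditions: 4 developmental stages x 3 biological replicates)."""

    n_contigs: int = 40
    genes_per_contig: tuple[int, int] = (3, 7)
    n_contaminant_contigs: int = 3
    n_hgt_genes: int = 1
    n_organelle_contigs: int = 2
    n_stages: int = 4
    reps_per_stage: int = 3
    n_deg: int = 50
    deg_log2fc: float = 3.0
    nb_dispersion: float = 0.1
    library_size_mean: int = 200_000
    seed: int = 0

    def validate(self) -> None:
        for fld in (
            "n_contigs", "n_contaminant_contigs", "n_hgt_genes",
            "n_organelle_contigs", "reps_per_stage", "n_deg", "library_size_mean",
        ):
            if getattr(self, fld) < 0:
                raise FixtureConfigError(f"{fld} must be >= 0")
        if self.n_stages != 4:
            raise FixtureConfigError("n_stages is fixed at 4 (egg, veliger, larva, juvenile)")
        lo, hi = self.genes_per_contig
        if lo < 1 or hi < lo:
            raise FixtureConfigError("genes_per_contig must be a range with 1 <= lo <= hi")
        if self.deg_log2fc <= 0:
            raise FixtureConfigError("deg_log2fc must be > 0")
        if self.nb_dispersion < 0:
            raise FixtureConfigError("nb_dispersion must be >= 0")
        if self.n_hgt_genes > self.n_contigs:
            raise FixtureConfigError("n_hgt_genes cannot exceed n_contigs")


@dataclass
class GroundTruth:
    contaminant_contig_ids: set[str] = field(default_factory=set)
    hgt_gene_ids: set[str] = field(default_factory=set)
    organelle_contig_ids: set[str] = field(default_factory=set)
    deg_gene_ids: set[str] = field(default_factory=set)
    klepto_candidate_gene_ids: set[str] = field(default_factory=set)
    rescued_gene_ids: set[str] = field(default_factory=set)
    stage_means: pd.DataFrame | None = None


@dataclass
class StudyBundle:
    """Everything one synthetic study produced, in memory plus on disk."""

    config: FixtureConfig
    genome: dict[str, str]
    masked_models: list[GeneModel]
    unmasked_models: list[GeneModel]
    repeats: dict[str, list[tuple[int, int, str]]]
    rescue_blast_evalues: dict[str, float]
    hits: list[HomologyHit]
    organelle_hits: list[OrganelleHit]
    gene_to_contig: dict[str, str]
    count_matrix: CountMatrix
    orthogroups: list[Orthogroup]
    annotations: dict[str, tuple[str, ...]]
    trees: dict[str, tuple[str, dict[str, str]]]  # gene -> (newick, leaf class map)
    truth: GroundTruth
    paths: dict[str, Path] = field(default_factory=dict)


def _rng(cfg: FixtureConfig, offset: int) -> np.random.Generator:
    # fixed-offset substreams off the single global seed
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), offset]))


def simulate_nb_counts(means, dispersion: float, libsizes, seed: int) -> np.ndarray:
    """Draw integer counts ~ NB(mean scaled by library size, dispersion).

    ``means`` is genes x samples expected counts at the average library size;
    sample means are scaled by ``libsizes / mean(libsizes)``. Dispersion 0
    reduces to Poisson; otherwise counts come from the gamma-Poisson mixture
    with Var = mu + dispersion * mu^2.
    """
    means = np.asarray(means, dtype=float)
    if (means < 0).any():
        raise ValueError("means must be >= 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    libsizes = np.asarray(libsizes, dtype=float)
    mu = means * (libsizes / libsizes.mean())
    rng = np.random.default_rng(seed)
    if dispersion == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
    return rng.poisson(lam)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _make_gene(gene_id, contig_id, rng, start, source_run="masked") -> GeneModel:
    n_exons = int(rng.integers(1, 5))
    exons = []
    pos = start
    for _ in range(n_exons):
        ln = int(rng.integers(150, 1500))
        exons.append((pos, pos + ln - 1))
        pos += ln + int(rng.integers(50, 500))
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(gene_id, contig_id, strand, tuple(exons), source_run=source_run)


def _nbs_to_hit(gene_id, subject, nbs, self_bs, lineage) -> HomologyHit:
    bs = round(nbs * self_bs, 1)
    evalue = float(np.clip(10.0 ** (-5 - 120 * nbs), 1e-180, 10.0))
    evalue = float(f"{evalue:g}")  # quantized so tabular output round-trips
    return HomologyHit(gene_id, subject, bs, evalue, lineage)


def _gene_hits(rng, gene_id, kind: str) -> list[HomologyHit]:
    """Build a hit table (self-hit included) for one gene of a given kind."""
    self_bs = float(rng.integers(300, 900))
    hits = [HomologyHit(gene_id, gene_id, self_bs, 1e-180, LIN_SELF, is_self=True)]
    sub = 0

    def add(nbs, lineage):
        nonlocal sub
        sub += 1
        hits.append(_nbs_to_hit(gene_id, f"{lineage[2]}_p{sub}", nbs, self_bs, lineage))

    if kind == "metazoan":
        best_m = rng.uniform(0.5, 0.95)
        add(best_m, LIN_METAZOA[rng.integers(len(LIN_METAZOA))])
        for _ in range(int(rng.integers(4, 15))):
            add(rng.uniform(0.2, best_m), LIN_METAZOA[rng.integers(len(LIN_METAZOA))])
        # close relatives hit hard but are skipped by the AI rule
        for _ in range(int(rng.integers(1, 3))):
            add(rng.uniform(0.9, 1.0), LIN_SKIP[rng.integers(len(LIN_SKIP))])
        if rng.random() < 0.6:  # weak out-lineage hits keep AI < 0
            cap = max(0.05, best_m - 0.1)
            pool = LIN_BACTERIA + LIN_ALGAE
            for _ in range(int(rng.integers(1, 4))):
                add(rng.uniform(0.03, cap * 0.8), pool[rng.integers(len(pool))])
    elif kind == "skip_only":
        for _ in range(int(rng.integers(1, 4))):
            add(rng.uniform(0.7, 1.0), LIN_SKIP[rng.integers(len(LIN_SKIP))])
    elif kind == "contaminant":
        best_b = rng.uniform(0.88, 0.99)
        add(best_b, LIN_BACTERIA[rng.integers(len(LIN_BACTERIA))])
        for _ in range(int(rng.integers(3, 10))):
            add(rng.uniform(0.5, best_b), LIN_BACTERIA[rng.integers(len(LIN_BACTERIA))])
        if rng.random() < 0.5:  # spurious weak metazoan hit
            add(rng.uniform(0.02, 0.15), LIN_METAZOA[rng.integers(len(LIN_METAZOA))])
    elif kind == "hgt":
        add(0.85, LIN_VIRUS[0])  # donor best hit
        add(rng.uniform(0.2, 0.3), LIN_METAZOA[rng.integers(len(LIN_METAZOA))])
        add(rng.uniform(0.9, 1.0), LIN_SKIP[0])
        # enough database breadth to pass the >= 50 total-hits filter
        pool = LIN_VIRUS + LIN_BACTERIA
        for _ in range(55):
            add(rng.uniform(0.15, 0.75), pool[rng.integers(len(pool))])
    else:  # pragma: no cover
        raise ValueError(kind)
    return hits


def _hgt_tree(gene_id: str) -> tuple[str, dict[str, str]]:
    newick = (
        f"((({gene_id}:0.12,(HubeiVirus_RdRp:0.10,BeihaiVirus_RdRp:0.15)99:0.08)98:0.20,"
        "WenlingVirus_RdRp:0.35)97:0.30,"
        "(Acal_homolog:0.22,Cvir_homolog:0.25)96:0.18,Drer_homolog:0.40);"
    )
    classes = {
        gene_id: "skip",
        "HubeiVirus_RdRp": "other",
        "BeihaiVirus_RdRp": "other",
        "WenlingVirus_RdRp": "other",
        "Acal_homolog": "recipient",
        "Cvir_homolog": "recipient",
        "Drer_homolog": "recipient",
    }
    return newick, classes


def _decoy_tree(gene_id: str) -> tuple[str, dict[str, str]]:
    newick = (
        f"((({gene_id}:0.05,Acal_homolog:0.06)99:0.10,Cvir_homolog:0.12)98:0.20,"
        "(EcoliK12_p:0.30,Vharveyi_p:0.28)97:0.22,Bsub_p:0.45);"
    )
    classes = {
        gene_id: "skip",
        "Acal_homolog": "recipient",
        "Cvir_homolog": "recipient",
        "EcoliK12_p": "other",
        "Vharveyi_p": "other",
        "Bsub_p": "other",
    }
    return newick, classes


def simulate_study(config: FixtureConfig, outdir: str | Path) -> StudyBundle:
    """Generate the full synthetic study into ``outdir`` and return it.

    See the module docstring for what is spiked. All files round-trip
    through this package's readers; rerunning with the same config yields
    byte-identical files.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = GroundTruth()
    genome: dict[str, str] = {}
    masked: list[GeneModel] = []
    gene_to_contig: dict[str, str] = {}
    gene_kind: dict[str, str] = {}
    hits: list[HomologyHit] = []

    rng_struct = _rng(config, 1)
    rng_hits = _rng(config, 2)
    rng_expr = _rng(config, 3)
    rng_og = _rng(config, 4)
    rng_seq = _rng(config, 5)

    # --- nuclear + contaminant contigs with gene models ---------------------
    lo, hi = config.genes_per_contig
    n_total_contigs = config.n_contigs + config.n_contaminant_contigs
    contaminant_contigs = [
        f"contig_{config.n_contigs + i + 1}" for i in range(config.n_contaminant_contigs)
    ]
    truth.contaminant_contig_ids = set(contaminant_contigs)

    hgt_host_contigs: list[str] = []
    gid_counter = 0
    for c in range(1, n_total_contigs + 1):
        contig = f"contig_{c}"
        is_contam = contig in truth.contaminant_contig_ids
        n_genes = int(rng_struct.integers(2, 4)) if is_contam else int(rng_struct.integers(lo, hi + 1))
        pos = int(rng_struct.integers(300, 800))
        for _ in range(n_genes):
            gid_counter += 1
            gid = f"Ecla{c}g{gid_counter}"
            g = _make_gene(gid, contig, rng_struct, pos)
            pos = g.span[1] + int(rng_struct.integers(300, 1200))
            masked.append(g)
            gene_to_contig[gid] = contig
            if is_contam:
                gene_kind[gid] = "contaminant"
            elif rng_struct.random() < 0.05:
                gene_kind[gid] = "skip_only"
            else:
                gene_kind[gid] = "metazoan"
        genome[contig] = ""  # sequence filled in after unmasked placement
        if not is_contam and n_genes >= 3:
            hgt_host_contigs.append(contig)

    # plant the HGT genes on multi-gene nuclear contigs (never contaminant)
    if config.n_hgt_genes > len(hgt_host_contigs):
        raise FixtureConfigError(
            "n_hgt_genes exceeds the number of nuclear contigs with >= 3 genes"
        )
    for i in range(config.n_hgt_genes):
        host = hgt_host_contigs[i * 2 % len(hgt_host_contigs)]
        gid = sorted(g for g, c in gene_to_contig.items() if c == host)[0]
        gene_kind[gid] = "hgt"
        truth.hgt_gene_ids.add(gid)

    for g in masked:
        hits.extend(_gene_hits(rng_hits, g.gene_id, gene_kind[g.gene_id]))

    # --- unmasked run: overlapping copies plus rescue candidates ------------
    unmasked: list[GeneModel] = []
    repeats: dict[str, list[tuple[int, int, str]]] = {}
    rescue_blast: dict[str, float] = {}
    nuclear_contigs = [f"contig_{c}" for c in range(1, config.n_contigs + 1)]
    for g in masked[: len(masked) // 2]:  # redundant rediscoveries, never rescued
        unmasked.append(dataclasses.replace(g, gene_id="u_" + g.gene_id, source_run="unmasked"))

    def place_after(contig: str) -> int:
        ends = [m.span[1] for m in masked if m.contig_id == contig]
        return (max(ends) if ends else 500) + 2000

    if len(nuclear_contigs) >= 6:
        # three rescues that pass every criterion
        for i, contig in enumerate(nuclear_contigs[:3]):
            gid = f"EclaU{i + 1}"
            g = _make_gene(gid, contig, rng_struct, place_after(contig), "unmasked")
            unmasked.append(g)
            rescue_blast[gid] = 10.0 ** -float(rng_struct.integers(4, 30))
            gene_to_contig[gid] = contig
            truth.rescued_gene_ids.add(gid)
        # three that each fail exactly one criterion
        c4, c5, c6 = nuclear_contigs[3:6]
        g = _make_gene("EclaF_repeat", c4, rng_struct, place_after(c4), "unmasked")
        unmasked.append(g)
        rescue_blast["EclaF_repeat"] = 1e-8
        gene_to_contig["EclaF_repeat"] = c4
        repeats.setdefault(c4, []).append((g.exons[0][0] - 10, g.exons[0][0] + 50, "LINE"))

        g = _make_gene("EclaF_evalue", c5, rng_struct, place_after(c5), "unmasked")
        unmasked.append(g)
        rescue_blast["EclaF_evalue"] = 0.01
        gene_to_contig["EclaF_evalue"] = c5

        g = _make_gene("EclaF_simple", c6, rng_struct, place_after(c6), "unmasked")
        unmasked.append(g)
        rescue_blast["EclaF_simple"] = 1e-8
        gene_to_contig["EclaF_simple"] = c6
        xs, xe = g.exons[0]
        cover_end = xs + int(0.6 * (xe - xs + 1)) - 1  # 60% of the first exon
        repeats.setdefault(c6, []).append((xs, cover_end, "Simple_repeat"))

    # background repeats in intergenic space
    for contig in nuclear_contigs[6:12]:
        start = place_after(contig) + 5000
        repeats.setdefault(contig, []).append((start, start + int(rng_struct.integers(200, 800)), "LTR"))

    # --- contig sequences (length covers everything placed on them) ---------
    all_models = masked + unmasked
    for contig in list(genome):
        end = max(
            [m.span[1] for m in all_models if m.contig_id == contig]
            + [e for _, e, _ in repeats.get(contig, ())]
            + [2500]
        )
        genome[contig] = _random_seq(rng_seq, end + 500)

    # --- organelle contigs and their tblastn hit table ----------------------
    organelle_hits: list[OrganelleHit] = []
    for i in range(config.n_organelle_contigs):
        contig = f"organelle_contig_{i + 1}"
        genome[contig] = _random_seq(rng_seq, 3000)
        truth.organelle_contig_ids.add(contig)
        organelle = "mitochondrial" if i % 2 == 0 else "kleptoplast"
        prefix = "Pocc_mt" if organelle == "mitochondrial" else "Rlew_cp"
        for j in range(3):
            ev = float(f"{10.0 ** -float(rng_struct.integers(6, 40)):g}")
            organelle_hits.append(OrganelleHit(contig, organelle, f"{prefix}_p{j + 1}", ev))
    if nuclear_contigs:
        # decoys that must NOT be flagged: one hit only; two hits above cutoff
        organelle_hits.append(OrganelleHit(nuclear_contigs[0], "kleptoplast", "Rlew_cp_p9", 1e-7))
        organelle_hits.append(OrganelleHit(nuclear_contigs[-1], "mitochondrial", "Pocc_mt_p9", 1e-4))
        organelle_hits.append(OrganelleHit(nuclear_contigs[-1], "mitochondrial", "Pocc_mt_p8", 2e-4))

    # --- expression: stage means, spiked DEGs, NB counts --------------------
    count_genes = sorted(
        [g.gene_id for g in masked] + sorted(rescue_blast), key=str
    )
    n_genes = len(count_genes)
    base = np.exp(rng_expr.normal(np.log(150.0), 1.0, n_genes))
    means = pd.DataFrame(
        np.tile(base[:, None], (1, 4)), index=count_genes, columns=list(STAGES)
    )
    uniform_pool = [
        g for g in count_genes
        if gene_kind.get(g, "metazoan") == "metazoan" and g not in truth.rescued_gene_ids
        and not g.startswith("EclaF")
    ]
    rng_expr.shuffle(uniform_pool)
    n_silent = max(1, n_genes // 8)
    n_restricted = max(1, n_genes // 10)
    needed = config.n_deg + n_silent + n_restricted
    if needed > len(uniform_pool):
        raise FixtureConfigError(
            f"n_deg={config.n_deg} too large for the simulated gene count ({len(uniform_pool)} eligible)"
        )
    silent = uniform_pool[:n_silent]
    restricted = uniform_pool[n_silent:n_silent + n_restricted]
    deg = sorted(uniform_pool[n_silent + n_restricted:n_silent + n_restricted + config.n_deg])
    means.loc[silent, :] = 0.0
    for i, g in enumerate(restricted):  # expressed in a subset of unfed stages only
        off = [["veliger", "larva", "juvenile"], ["egg", "juvenile"], ["juvenile"]][i % 3]
        means.loc[g, off] = 0.0
    means.loc[deg, "juvenile"] *= 2.0 ** config.deg_log2fc
    truth.deg_gene_ids = set(deg)
    truth.stage_means = means

    # scale so each stage's expected library is library_size_mean
    scale = config.library_size_mean / means.sum(axis=0).replace(0, 1)
    sample_names = [f"{st}_{r + 1}" for st in STAGES for r in range(config.reps_per_stage)]
    stage_of_sample = {s: s.rsplit("_", 1)[0] for s in sample_names}
    depth = rng_expr.uniform(0.7, 1.3, len(sample_names))
    sample_means = np.column_stack(
        [means[stage_of_sample[s]].to_numpy() * scale[stage_of_sample[s]] for s in sample_names]
    )
    libsizes = config.library_size_mean * depth
    counts = simulate_nb_counts(
        sample_means, config.nb_dispersion, libsizes, seed=int(_rng(config, 6).integers(2**31))
    )
    tx_len = rng_expr.integers(400, 3000, n_genes).astype(float)
    lengths = tx_len[:, None] * rng_expr.uniform(0.98, 1.02, (n_genes, len(sample_names)))
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=count_genes, columns=sample_names),
        eff_lengths=pd.DataFrame(lengths.round(2), index=count_genes, columns=sample_names),
        stage_of_sample=stage_of_sample,
    )

    # --- orthogroups: conserved, klepto-specific (with planted candidates) --
    orthogroups: list[Orthogroup] = []
    og_i = 0

    def og(members: dict[str, list[str]]) -> None:
        nonlocal og_i
        og_i += 1
        orthogroups.append(
            Orthogroup(
                f"OG{og_i:07d}",
                tuple((sp, tuple(members.get(sp, ()))) for sp in SPECIES),
            )
        )

    def fake(sp: str) -> list[str]:
        return [f"{sp}_g{og_i + 1:05d}"]

    klepto_candidates = sorted(deg)[: min(8, len(deg))]
    truth.klepto_candidate_gene_ids = set(klepto_candidates)
    assigned = set()
    for g in klepto_candidates:
        og({"Ecla": [g], "Echl": fake("Echl"), "Pocc": fake("Pocc"), "Emar": fake("Emar")})
        assigned.add(g)
    # klepto-specific orthogroups whose focal members are NOT DEGs
    non_deg = [g for g in uniform_pool if g not in truth.deg_gene_ids and g not in assigned]
    for g in non_deg[:5]:
        og({"Ecla": [g], "Echl": fake("Echl"), "Pocc": fake("Pocc"), "Emar": fake("Emar")})
        assigned.add(g)
    # conserved-in-all orthogroups hoover up ~60% of the remaining genes
    remaining = [g for g in count_genes if g not in assigned and gene_kind.get(g) != "contaminant"]
    n_cons = int(0.6 * len(remaining))
    for g in remaining[:n_cons]:
        og({"Ecla": [g], "Echl": fake("Echl"), "Pocc": fake("Pocc"),
            "Emar": fake("Emar"), "Acal": fake("Acal")})
        assigned.add(g)
    # pattern variety: non-focal, partial, singleton orthogroups
    og({"Echl": fake("Echl"), "Pocc": fake("Pocc")})
    og({"Acal": fake("Acal")})
    leftovers = [g for g in remaining[n_cons:]]
    for g in leftovers[:3]:
        og({"Ecla": [g], "Acal": fake("Acal")})
        assigned.add(g)

    # --- functional annotations (enriched term planted in candidates) -------
    term_pool = [f"GO:{7000000 + i}" for i in range(25)] + [f"KEGG:K{10000 + i}" for i in range(10)]
    annotations: dict[str, tuple[str, ...]] = {}
    for g in count_genes:
        if rng_og.random() < 0.5:
            k = int(rng_og.integers(1, 4))
            idx = rng_og.choice(len(term_pool), size=k, replace=False)
            annotations[g] = tuple(sorted(term_pool[i] for i in idx))
    ros_term = "GO:2000377"  # regulation of ROS metabolic process
    for g in klepto_candidates:
        annotations[g] = tuple(sorted(set(annotations.get(g, ())) | {ros_term}))
    for g in non_deg[5:8]:
        annotations[g] = tuple(sorted(set(annotations.get(g, ())) | {ros_term}))

    # --- candidate trees ----------------------------------------------------
    trees: dict[str, tuple[str, dict[str, str]]] = {}
    for g in sorted(truth.hgt_gene_ids):
        trees[g] = _hgt_tree(g)
    if uniform_pool:
        decoy = sorted(uniform_pool)[0]
        trees[decoy] = _decoy_tree(decoy)

    # --- proteins (longest-isoform selection input; lengths only matter) ----
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    proteins = {
        g.gene_id: "".join(aa[rng_seq.integers(0, 20, max(50, g.length // 9))])
        for g in masked[:20]
    }

    # --- write everything ---------------------------------------------------
    paths: dict[str, Path] = {}

    def p(name: str) -> Path:
        paths[name] = outdir / name
        return paths[name]

    kio.write_fasta(p("genome.fasta"), genome)
    kio.write_fasta(p("proteins.fasta"), proteins)
    kio.write_gene_models(p("models_masked.gff3"), masked)
    kio.write_gene_models(p("models_unmasked.gff3"), unmasked)
    kio.write_repeats(p("repeats.gff3"), repeats)
    kio.write_hits(p("hits.tsv"), hits)
    kio.write_organelle_hits(p("organelle_hits.tsv"), organelle_hits)
    kio.write_gene_map(p("gene_map.tsv"), gene_to_contig)
    kio._write_tsv(
        p("rescue_blast.tsv"), ["gene_id", "evalue"],
        [(g, f"{e:g}") for g, e in sorted(rescue_blast.items())],
    )
    kio.write_matrix(p("counts.tsv"), cm.counts)
    kio.write_matrix(p("eff_lengths.tsv"), cm.eff_lengths)
    kio.write_stage_map(p("stages.tsv"), stage_of_sample)
    kio.write_orthogroups(p("orthogroups.tsv"), orthogroups, SPECIES)
    kio.write_annotations(p("annotations.tsv"), annotations)
    tree_dir = outdir / "trees"
    tree_dir.mkdir(exist_ok=True)
    for g, (nwk, classes) in trees.items():
        (tree_dir / f"{g}.nwk").write_text(nwk + "\n")
        kio._write_tsv(tree_dir / f"{g}.classes.tsv", ["leaf", "class"], sorted(classes.items()))
    paths["trees"] = tree_dir
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    kio.write_id_set(truth_dir / "contaminant_contigs.tsv", truth.contaminant_contig_ids)
    kio.write_id_set(truth_dir / "hgt_genes.tsv", truth.hgt_gene_ids)
    kio.write_id_set(truth_dir / "organelle_contigs.tsv", truth.organelle_contig_ids)
    kio.write_id_set(truth_dir / "deg_genes.tsv", truth.deg_gene_ids)
    kio.write_id_set(truth_dir / "klepto_candidates.tsv", truth.klepto_candidate_gene_ids)
    kio.write_id_set(truth_dir / "rescued_genes.tsv", truth.rescued_gene_ids)
    kio.write_matrix(truth_dir / "stage_means.tsv", means.round(6))
    paths["truth"] = truth_dir

    return StudyBundle(
        config=config,
        genome=genome,
        masked_models=masked,
        unmasked_models=unmasked,
        repeats=repeats,
        rescue_blast_evalues=rescue_blast,
        hits=hits,
        organelle_hits=organelle_hits,
        gene_to_contig=gene_to_contig,
        count_matrix=cm,
        orthogroups=orthogroups,
        annotations=annotations,
        trees=trees,
        truth=truth,
        paths=paths,
    )
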