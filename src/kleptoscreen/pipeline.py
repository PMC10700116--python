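"""End-to-end orchestration: screen -> curate -> express -> compare -> trees.

Every stage is a pure function of the declared input files plus the run
configuration; the manifest records input hashes, thresholds and per-stage
outputs so a rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import io as kio
from .curation import (
    high_confidence_set,
    rescue_unmasked_models,
    summarize_annotation,
)
from .expression import (
    differential_expression,
    expression_intersections,
    length_scaled_tpm,
    stage_expression,
    tmm_factors,
)
from .homology import (
    alien_index_table,
    filter_hgt_candidates,
    flag_contaminant_contigs,
    flag_organelle_contigs,
)
from .orthogroups import candidate_genes, classify_patterns, hypergeom_enrichment
from .simulate import KLEPTO_SPECIES, OUTGROUP_SPECIES
from .trees import collapse_low_support, hgt_support_check, midpoint_root, read_newick

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger("kleptoscreen")


@dataclass
class RunConfig:
    """Input paths, thresholds and species roles for a full run."""

    input_dir: Path
    output_dir: Path
    recipient: str = "Metazoa"
    skip: str = "Placobranchoidea"
    min_ai: float = 0.1
    min_hits: int = 50
    organelle_evalue: float = 1e-5
    rescue_evalue: float = 1e-3
    simple_repeat_frac: float = 0.5
    tpm_threshold: float = 1.0
    tpm_comparator: str = ">="
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.01
    support_threshold: int = 95
    fed_stage: str = "juvenile"
    focal_species: str = "Ecla"
    klepto_species: frozenset = frozenset(KLEPTO_SPECIES)
    outgroup_species: frozenset = frozenset(OUTGROUP_SPECIES)
    seed: int = 0

    def validate(self) -> None:
        if not -1 <= self.min_ai <= 1:
            raise ValueError("min_ai must lie in [-1, 1]")
        if self.min_hits < 0:
            raise ValueError("min_hits must be >= 0")
        for name in ("organelle_evalue", "rescue_evalue"):
            if not 0 < getattr(self, name) <= 10:
                raise ValueError(f"{name} out of range")
        if not 0 <= self.simple_repeat_frac <= 1:
            raise ValueError("simple_repeat_frac must lie in [0, 1]")
        if self.tpm_comparator not in (">=", ">"):
            raise ValueError("tpm_comparator must be '>=' or '>'")
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must lie in (0, 1]")
        if not 0 <= self.support_threshold <= 100:
            raise ValueError("support_threshold must lie in [0, 100]")
        if not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input dir {self.input_dir} does not exist")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute all five stages on the inputs in ``config.input_dir``.

    Expects the file layout written by :func:`kleptoscreen.simulate.simulate_study`
    (the same layout a real study would be converted into). Returns the
    manifest dictionary, which is also written to ``manifest.json``.
    """
    config.validate()
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "thresholds": _threshold_dict(config), "inputs": {}}
    stages_done = []

    input_files = sorted(f for f in indir.rglob("*") if f.is_file() and "truth" not in f.parts)
    manifest["inputs"] = {str(f.relative_to(indir)): _sha256(f) for f in input_files}

    def stage(name):
        log.info("[%s] starting", name)
        stages_done.append(name)
        return {}

    try:
        # -- screen ----------------------------------------------------------
        info = manifest["stages"]["screen"] = stage("screen")
        hits = kio.read_hits(indir / "hits.tsv")
        gene_map = kio.read_gene_map(indir / "gene_map.tsv")
        records = alien_index_table(hits, config.recipient, config.skip)
        mapped = [r for r in records if r.gene_id in gene_map]
        verdicts = flag_contaminant_contigs(mapped, gene_map)
        contaminant = {v.contig_id for v in verdicts if v.status == "bacterial_contaminant"}
        candidates = filter_hgt_candidates(
            mapped, contaminant, gene_map, config.min_ai, config.min_hits
        )
        organelle = flag_organelle_contigs(
            kio.read_organelle_hits(indir / "organelle_hits.tsv"),
            max_evalue=config.organelle_evalue,
        )
        kio.write_ai_table(outdir / "ai_table.tsv", records)
        kio.write_verdicts(outdir / "contig_verdicts.tsv", list(verdicts) + list(organelle))
        kio.write_id_set(outdir / "hgt_candidates.txt", [r.gene_id for r in candidates])
        flagged_contigs = contaminant | {v.contig_id for v in organelle}
        info.update(
            n_genes=len(records),
            n_contaminant_contigs=len(contaminant),
            n_organelle_contigs=len(organelle),
            n_hgt_candidates=len(candidates),
            outputs=["ai_table.tsv", "contig_verdicts.tsv", "hgt_candidates.txt"],
        )

        # -- curate (merge; evidence joined after express/compare) -----------
        info = manifest["stages"]["curate"] = stage("curate")
        masked = kio.read_gene_models(indir / "models_masked.gff3")
        unmasked = kio.read_gene_models(indir / "models_unmasked.gff3")
        classified, simple = kio.split_repeats(kio.read_repeats(indir / "repeats.gff3"))
        rescue_ev = dict(
            pd.read_csv(indir / "rescue_blast.tsv", sep="\t").itertuples(index=False)
        )
        merged = rescue_unmasked_models(
            masked, unmasked, rescue_ev, classified, simple,
            max_evalue=config.rescue_evalue,
            simple_repeat_frac=config.simple_repeat_frac,
        )
        final_models = [m for m in merged if m.contig_id not in flagged_contigs]
        kio.write_gene_models(outdir / "models_merged.gff3", final_models)
        info.update(
            n_masked=len(masked),
            n_rescued=len(merged) - len(masked),
            n_final=len(final_models),
            outputs=["models_merged.gff3"],
        )
        final_ids = {m.gene_id for m in final_models}

        # -- express ---------------------------------------------------------
        info = manifest["stages"]["express"] = stage("express")
        cm = kio.read_count_matrix(
            indir / "counts.tsv", indir / "eff_lengths.tsv", indir / "stages.tsv"
        )
        keep = [g for g in cm.counts.index if g in final_ids]
        cm.counts = cm.counts.loc[keep]
        cm.eff_lengths = cm.eff_lengths.loc[keep]
        lstpm = length_scaled_tpm(cm.counts, cm.eff_lengths)
        sexpr = stage_expression(
            lstpm, cm.stage_of_sample, config.tpm_threshold, config.tpm_comparator
        )
        upset = expression_intersections(sexpr)
        de = differential_expression(
            cm,
            fed_stage=config.fed_stage,
            tpm_threshold=config.tpm_threshold,
            comparator=config.tpm_comparator,
            fc_threshold=config.fc_threshold,
            fdr_threshold=config.fdr_threshold,
        )
        degs = set(de.index[de["is_deg"]])
        kio.write_matrix(outdir / "length_scaled_tpm.tsv", lstpm.round(4))
        kio.write_matrix(outdir / "stage_expression.tsv", sexpr.round(4))
        upset.rename("n_genes").to_frame().assign(
            stage_subset=["+".join(k) if k else "none" for k in upset.index]
        )[["stage_subset", "n_genes"]].to_csv(outdir / "upset_counts.tsv", sep="\t", index=False)
        kio.write_matrix(outdir / "de_table.tsv", de.round(6))
        kio.write_id_set(outdir / "degs.txt", degs)
        info.update(
            n_tested=len(de),
            n_degs=len(degs),
            tmm_factors={s: round(float(v), 6) for s, v in
                         tmm_factors(cm.counts.loc[de.index]).items()},
            outputs=["length_scaled_tpm.tsv", "stage_expression.tsv",
                     "upset_counts.tsv", "de_table.tsv", "degs.txt"],
        )

        # -- compare ---------------------------------------------------------
        info = manifest["stages"]["compare"] = stage("compare")
        ogs = kio.read_orthogroups(indir / "orthogroups.tsv")
        annotations = kio.read_annotations(indir / "annotations.tsv")
        patterns = classify_patterns(
            ogs, set(config.klepto_species), set(config.outgroup_species)
        )
        og_by_id = {og.og_id: og for og in ogs}
        cands = candidate_genes(patterns, og_by_id, config.focal_species, degs)
        background = set(de.index)  # the tested (expression-filtered) universe
        klepto_cands = cands.get("klepto_specific", set())
        enrich = hypergeom_enrichment(klepto_cands & background, annotations, background)
        kio._write_tsv(
            outdir / "pattern_classes.tsv",
            ["og_id", "pattern", "present_species"],
            [(p.og_id, p.pattern, ",".join(sorted(p.present_species))) for p in patterns],
        )
        for cls, genes in sorted(cands.items()):
            kio.write_id_set(outdir / f"candidates_{cls}.txt", genes)
        enrich.round(8).to_csv(outdir / "enrichment_klepto_specific.tsv", sep="\t", index=False)
        info.update(
            n_orthogroups=len(ogs),
            pattern_counts=pd.Series([p.pattern for p in patterns]).value_counts().to_dict(),
            n_klepto_candidates=len(klepto_cands),
            outputs=["pattern_classes.tsv", "enrichment_klepto_specific.tsv"],
        )

        # -- evidence join + summary (uses express/compare results) ----------
        og_evidence = {
            g
            for og in ogs
            if len(og.present_species) > 1
            for g in og.genes_of(config.focal_species)
        }
        flag_cols = [c for c in sexpr.columns if c.startswith("expressed_")]
        evidence = pd.DataFrame(
            {
                "has_rnaseq": [
                    bool(sexpr.loc[g, flag_cols].any()) if g in sexpr.index else False
                    for g in sorted(final_ids)
                ],
                "has_orthology": [g in og_evidence for g in sorted(final_ids)],
                "has_function": [bool(annotations.get(g)) for g in sorted(final_ids)],
            },
            index=sorted(final_ids),
        )
        hc = high_confidence_set(evidence)
        summary = summarize_annotation(final_models, evidence)
        kio.write_id_set(outdir / "high_confidence_genes.txt", hc)
        evidence.to_csv(outdir / "evidence.tsv", sep="\t", index_label="gene_id")
        with open(outdir / "annotation_summary.tsv", "w") as fh:
            for k, v in summary.as_rows():
                fh.write(f"{k}\t{v}\n")
        manifest["stages"]["curate"]["n_high_confidence"] = len(hc)

        # -- trees -----------------------------------------------------------
        info = manifest["stages"]["trees"] = stage("trees")
        tree_dir = indir / "trees"
        rows = []
        if tree_dir.is_dir():
            for nwk in sorted(tree_dir.glob("*.nwk")):
                gene = nwk.stem
                st = read_newick(nwk.read_text())
                st = collapse_low_support(
                    midpoint_root(st), threshold=config.support_threshold
                )
                classes = dict(
                    pd.read_csv(tree_dir / f"{gene}.classes.tsv", sep="\t").itertuples(index=False)
                )
                verdict, report = hgt_support_check(st, gene, classes)
                rows.append((gene, verdict, report["clade_size"],
                             ",".join(report["clade_leaves"])))
        kio._write_tsv(
            outdir / "tree_verdicts.tsv",
            ["gene_id", "verdict", "clade_size", "clade_leaves"], rows,
        )
        info.update(
            n_trees=len(rows),
            n_supported=sum(1 for r in rows if r[1] == "supported"),
            outputs=["tree_verdicts.tsv"],
        )
    except Exception as err:
        current = stages_done[-1] if stages_done else "setup"
        raise RuntimeError(f"pipeline failed in stage {current!r}: {err}") from err

    manifest["n_stages_completed"] = len(stages_done)
    manifest["output_hashes"] = {
        f.name: _sha256(f) for f in sorted(outdir.iterdir()) if f.is_file() and f.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _threshold_dict(config: RunConfig) -> dict:
    d = asdict(config)
    for k in ("input_dir", "output_dir"):
        d[k] = str(d[k])
    for k in ("klepto_species", "outgroup_species"):
        d[k] = sorted(d[k])
    return d
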