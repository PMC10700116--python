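"""Readers and writers for the pipeline's exchange formats.

Homology hits travel as 12-column BLAST/DIAMOND tabular (outfmt 6) with two
appended columns (subject taxid, semicolon-joined lineage root->species).
Gene models and repeats are GFF3 (1-based inclusive); counts, lengths, stage
maps, orthogroups, annotations and ground truth are plain TSV; trees are
Newick. Everything written here round-trips through the matching reader.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .curation import GeneModel
from .expression import CountMatrix
from .homology import AIRecord, ContigVerdict, HomologyHit, OrganelleHit

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "staxid", "lineage",
]


# -- homology hits -----------------------------------------------------------

def write_hits(path, hits: Iterable[HomologyHit]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            w.writerow(
                [
                    h.query_id, h.subject_id, "100.0", "0", "0", "0",
                    "1", "1", "1", "1",
                    f"{h.evalue:g}", f"{h.bitscore:g}",
                    "0", ";".join(h.lineage),
                ]
            )


def read_hits(path) -> list[HomologyHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != len(BLAST_COLUMNS):
                raise ValueError(f"expected {len(BLAST_COLUMNS)} columns, got {len(f)}")
            hits.append(
                HomologyHit(
                    query_id=f[0],
                    subject_id=f[1],
                    bitscore=float(f[11]),
                    evalue=float(f[10]),
                    lineage=tuple(f[13].split(";")),
                    is_self=f[0] == f[1],
                )
            )
    return hits


def write_organelle_hits(path, hits: Iterable[OrganelleHit]) -> None:
    _write_tsv(path, ["contig_id", "organelle", "query_protein", "evalue"],
               [(h.contig_id, h.organelle, h.query_protein, f"{h.evalue:g}") for h in hits])


def read_organelle_hits(path) -> list[OrganelleHit]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        OrganelleHit(r.contig_id, r.organelle, r.query_protein, float(r.evalue))
        for r in df.itertuples()
    ]


# -- AI results and verdicts -------------------------------------------------

def write_ai_table(path, records: Iterable[AIRecord]) -> None:
    _write_tsv(
        path,
        ["gene_id", "nbsO", "nbsM", "AI", "n_hits", "top_outgroup_subject"],
        [
            (r.gene_id, f"{r.nbsO:.6f}", f"{r.nbsM:.6f}", f"{r.AI:.6f}",
             r.n_hits, r.top_outgroup_subject or "")
            for r in records
        ],
    )


def write_verdicts(path, verdicts: Iterable[ContigVerdict]) -> None:
    _write_tsv(
        path,
        ["contig_id", "status", "evidence"],
        [(v.contig_id, v.status, ",".join(v.evidence)) for v in verdicts],
    )


# -- FASTA -------------------------------------------------------------------

def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# -- GFF3 gene models and repeats -------------------------------------------

def write_gene_models(path, models: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s, e = m.span
            fh.write(
                "\t".join(
                    [m.contig_id, "kleptoscreen", "gene", str(s), str(e), ".",
                     m.strand, ".", f"ID={m.gene_id};source_run={m.source_run}"]
                )
                + "\n"
            )
            for i, (xs, xe) in enumerate(m.exons, 1):
                fh.write(
                    "\t".join(
                        [m.contig_id, "kleptoscreen", "exon", str(xs), str(xe), ".",
                         m.strand, ".", f"ID={m.gene_id}.exon{i};Parent={m.gene_id}"]
                    )
                    + "\n"
                )


def _parse_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gene_models(path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig, _, ftype, start, end, _, strand, _, attrs = f
            a = _parse_attrs(attrs)
            if ftype == "gene":
                gid = a["ID"]
                genes[gid] = {
                    "contig": contig,
                    "strand": strand,
                    "source_run": a.get("source_run", "masked"),
                    "exons": [],
                }
                order.append(gid)
            elif ftype == "exon":
                gid = a["Parent"]
                genes[gid]["exons"].append((int(start), int(end)))
    return [
        GeneModel(
            gene_id=gid,
            contig_id=g["contig"],
            strand=g["strand"],
            exons=tuple(sorted(g["exons"])),
            source_run=g["source_run"],
        )
        for gid, g in ((gid, genes[gid]) for gid in order)
    ]


def write_repeats(path, repeats: Mapping[str, Sequence[tuple[int, int, str]]]) -> None:
    """Repeat intervals per contig as GFF3; third tuple item is the class
    (e.g. LINE, LTR, Simple_repeat)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        i = 0
        for contig in sorted(repeats):
            for s, e, cls in repeats[contig]:
                i += 1
                fh.write(
                    "\t".join(
                        [contig, "kleptoscreen", "repeat", str(s), str(e), ".", "+",
                         ".", f"ID=rep{i};repeat_class={cls}"]
                    )
                    + "\n"
                )


def read_repeats(path) -> dict[str, list[tuple[int, int, str]]]:
    out: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            a = _parse_attrs(f[8])
            out.setdefault(f[0], []).append((int(f[3]), int(f[4]), a.get("repeat_class", "Unknown")))
    return out


def split_repeats(
    repeats: Mapping[str, Sequence[tuple[int, int, str]]]
) -> tuple[dict[str, list[tuple[int, int]]], dict[str, list[tuple[int, int]]]]:
    """Split a repeat map into (classified, simple) interval maps."""
    classified: dict[str, list[tuple[int, int]]] = {}
    simple: dict[str, list[tuple[int, int]]] = {}
    for contig, ivs in repeats.items():
        for s, e, cls in ivs:
            target = simple if cls == "Simple_repeat" else classified
            target.setdefault(contig, []).append((s, e))
    return classified, simple


# -- counts / stages ---------------------------------------------------------

def write_matrix(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_stage_map(path, stage_of_sample: Mapping[str, str]) -> None:
    _write_tsv(path, ["sample", "stage"], sorted(stage_of_sample.items()))


def read_stage_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"], df["stage"]))


def read_count_matrix(counts_path, lengths_path, stages_path) -> CountMatrix:
    return CountMatrix(
        counts=read_matrix(counts_path).astype(int),
        eff_lengths=read_matrix(lengths_path),
        stage_of_sample=read_stage_map(stages_path),
    )


# -- orthogroups / annotations ----------------------------------------------

def write_orthogroups(path, orthogroups, species: Sequence[str]) -> None:
    """OrthoFinder-style Orthogroups.tsv: comma-joined members per species."""
    rows = []
    for og in orthogroups:
        rows.append([og.og_id] + [", ".join(og.genes_of(sp)) for sp in species])
    _write_tsv(path, ["Orthogroup"] + list(species), rows)


def read_orthogroups(path):
    from .orthogroups import Orthogroup

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    species = list(df.columns[1:])
    out = []
    for row in df.itertuples(index=False):
        members = tuple(
            (sp, tuple(g.strip() for g in cell.split(",") if g.strip()))
            for sp, cell in zip(species, row[1:])
        )
        out.append(Orthogroup(og_id=row[0], members=members))
    return out


def write_annotations(path, term_map: Mapping[str, Sequence[str]]) -> None:
    _write_tsv(
        path,
        ["gene_id", "terms"],
        [(g, ",".join(terms)) for g, terms in sorted(term_map.items())],
    )


def read_annotations(path) -> dict[str, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return {
        r.gene_id: tuple(t for t in r.terms.split(",") if t) for r in df.itertuples()
    }


# -- misc --------------------------------------------------------------------

def write_gene_map(path, gene_to_contig: Mapping[str, str]) -> None:
    _write_tsv(path, ["gene_id", "contig_id"], sorted(gene_to_contig.items()))


def read_gene_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene_id"], df["contig_id"]))


def write_id_set(path, ids: Iterable[str]) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in sorted(ids)))


def read_id_set(path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def _write_tsv(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)
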