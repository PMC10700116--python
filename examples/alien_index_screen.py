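"""Alien Index screening on a hand-built homology hit table.

Scores three genes against a toy database, flags a contaminant contig, and
filters HGT candidates the same way a genome-wide screen would.
"""

from kleptoscreen import (
    HomologyHit,
    alien_index,
    filter_hgt_candidates,
    flag_contaminant_contigs,
)

MET = ("Metazoa", "Aplysiida", "Aplysia_californica")
BAC = ("Bacteria", "Proteobacteria", "Escherichia_coli")
SELF = ("Metazoa", "Placobranchoidea", "Elysia_crispata")


def hits_for(gene, rows):
    out = [HomologyHit(gene, gene, 200.0, 1e-180, SELF, is_self=True)]
    out += [HomologyHit(gene, s, bs, ev, lin) for s, bs, ev, lin in rows]
    return out


genes = {
    # ordinary slug genes: best hit is another metazoan -> AI < 0
    "slug_gene1": hits_for("slug_gene1", [("Acal_p1", 160, 1e-60, MET), ("Ecoli_p1", 30, 1e-4, BAC)]),
    "slug_gene2": hits_for("slug_gene2", [("Cvir_p1", 140, 1e-50, MET)]),
    # bacterial contaminant: near-perfect bacterial hit -> AI near 1
    "contam_gene": hits_for("contam_gene", [("Ecoli_p2", 190, 1e-90, BAC)]),
    # HGT-like gene: strong bacterial hit, weak metazoan hit
    "hgt_gene": hits_for(
        "hgt_gene",
        [("Ecoli_p3", 170, 1e-70, BAC), ("Acal_p2", 50, 1e-10, MET)]
        + [(f"Bsub_p{i}", 40.0 + i, 1e-8, BAC) for i in range(55)],
    ),
}

records = [alien_index(h) for h in genes.values()]
gene_map = {"slug_gene1": "contig_1", "slug_gene2": "contig_1",
            "hgt_gene": "contig_1", "contam_gene": "contig_9"}

print("gene          nbsO   nbsM     AI  n_hits")
for r in records:
    print(f"{r.gene_id:12s} {r.nbsO:6.2f} {r.nbsM:6.2f} {r.AI:+6.2f} {r.n_hits:6d}")

verdicts = flag_contaminant_contigs(records, gene_map)
flagged = {v.contig_id for v in verdicts if v.status == "bacterial_contaminant"}
print("contaminant contigs:", sorted(flagged))

cands = filter_hgt_candidates(records, flagged, gene_map)
print("HGT candidates (AI > 0.1, >= 50 hits, off flagged contigs):",
      [r.gene_id for r in cands])
# AI > 0 means the protein resembles non-metazoan sequences more than
# metazoan ones; contig_9 is flagged because every gene on it is alien-like,
# while hgt_gene survives as a candidate because its contig is otherwise slug.
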