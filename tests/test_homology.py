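"""Alien Index scoring, contamination flagging and HGT candidate filtering."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kleptoscreen.homology import (
    AIRecord,
    HomologyHit,
    OrganelleHit,
    alien_index,
    collapse_best_hsp,
    filter_hgt_candidates,
    flag_contaminant_contigs,
    flag_organelle_contigs,
    normalized_bitscore,
)

MET = ("Metazoa", "Aplysiida", "Aplysia_californica")
SKIP = ("Metazoa", "Placobranchoidea", "Elysia_chlorotica")
BAC = ("Bacteria", "Proteobacteria", "Escherichia_coli")
SELF_LIN = ("Metazoa", "Placobranchoidea", "Elysia_crispata")


def hit(subject, bitscore, lineage, query="g1", evalue=1e-20, is_self=False):
    return HomologyHit(query, subject, bitscore, evalue, lineage, is_self)


def self_hit(bitscore=200.0, query="g1"):
    return hit(query, bitscore, SELF_LIN, query=query, is_self=True)


class TestNormalizedBitscore:
    @pytest.mark.parametrize(
        "hit_bs,self_bs,expected",
        [(100, 200, 0.5), (200, 200, 1.0), (210, 200, 1.0), (0, 200, 0.0)],
    )
    def test_ratio_and_clamp(self, hit_bs, self_bs, expected):
        assert normalized_bitscore(hit_bs, self_bs) == expected

    def test_missing_self_hit_rejected(self):
        with pytest.raises(ValueError):
            normalized_bitscore(100, 0)


class TestAlienIndex:
    def test_formula_instance(self):
        rec = alien_index([self_hit(), hit("b1", 180, BAC), hit("m1", 40, MET)])
        assert rec.AI == pytest.approx(0.9 - 0.2)
        assert rec.nbsO == 0.9 and rec.nbsM == 0.2
        assert rec.top_outgroup_subject == "b1"

    def test_skip_only_hits_score_zero(self):
        rec = alien_index([self_hit(), hit("s1", 190, SKIP), hit("s2", 150, SKIP)])
        assert rec.nbsO == rec.nbsM == 0.0 and rec.AI == 0.0

    def test_metazoan_only_gene_negative(self):
        rec = alien_index([self_hit(), hit("m1", 120, MET)])
        assert rec.AI == pytest.approx(-0.6)

    def test_missing_self_hit_errors(self):
        with pytest.raises(ValueError, match="self-hit"):
            alien_index([hit("m1", 120, MET)])

    def test_empty_hit_list_errors(self):
        with pytest.raises(ValueError, match="empty"):
            alien_index([])

    def test_hsp_collapse_keeps_best_per_subject(self):
        hsps = [hit("m1", 100, MET), hit("m1", 150, MET), hit("m1", 150, MET, evalue=1e-30)]
        best = collapse_best_hsp(hsps)
        assert len(best) == 1 and best[0].bitscore == 150 and best[0].evalue == 1e-30

    @settings(deadline=None, max_examples=60)
    @given(
        met=st.lists(st.floats(0, 1), max_size=6),
        out=st.lists(st.floats(0, 1), max_size=6),
        skp=st.lists(st.floats(0, 2), max_size=3),
    )
    def test_range_and_formula_identity(self, met, out, skp):
        """AI stays in [-1, 1] and equals nbsO - nbsM for arbitrary hit mixes,
        including hits out-scoring the self alignment."""
        hits = [self_hit(100.0)]
        hits += [hit(f"m{i}", 100 * v, MET) for i, v in enumerate(met)]
        hits += [hit(f"b{i}", 100 * v, BAC) for i, v in enumerate(out)]
        hits += [hit(f"s{i}", 100 * v, SKIP) for i, v in enumerate(skp)]
        rec = alien_index(hits)
        assert -1.0 <= rec.AI <= 1.0
        assert rec.AI == rec.nbsO - rec.nbsM
        # deleting one side forces the sign
        rec_no_out = alien_index([h for h in hits if h.lineage != BAC])
        assert rec_no_out.AI <= 0
        rec_no_met = alien_index([h for h in hits if h.lineage != MET])
        assert rec_no_met.AI >= 0


def rec(gene, ai, n_hits=100):
    return AIRecord(gene, max(ai, 0), max(-ai, 0), ai, n_hits)


class TestContaminationFlagging:
    @pytest.mark.parametrize(
        "ais,flagged",
        [
            ([0.2, 0.5], True),  # min AI > 0
            ([-0.5, 0.3, 0.4, 0.2], True),  # 3/4 >= half with AI > 0.1
            ([-0.5, 0.05], False),
            ([0.05], True),  # single-gene contig, rule 1 as written
            ([-0.1, 0.2], True),  # exactly half the genes above 0.1 qualifies
        ],
    )
    def test_rules(self, ais, flagged):
        records = [rec(f"g{i}", a) for i, a in enumerate(ais)]
        verdicts = flag_contaminant_contigs(records, {f"g{i}": "c1" for i in range(len(ais))})
        assert (verdicts[0].status == "bacterial_contaminant") is flagged

    def test_monotone_raising_ai_never_unflags(self):
        ais = [0.15, 0.3, -0.2, 0.12]
        gmap = {f"g{i}": "c1" for i in range(4)}
        base = flag_contaminant_contigs([rec(f"g{i}", a) for i, a in enumerate(ais)], gmap)
        assert base[0].status == "bacterial_contaminant"
        for i in range(4):
            bumped = list(ais)
            bumped[i] = min(1.0, bumped[i] + 0.5)
            out = flag_contaminant_contigs(
                [rec(f"g{j}", a) for j, a in enumerate(bumped)], gmap
            )
            assert out[0].status == "bacterial_contaminant"

    def test_unmapped_gene_errors(self):
        with pytest.raises(KeyError):
            flag_contaminant_contigs([rec("g1", 0.2)], {})

    def test_oracle_equivalence_small_fixture(self):
        """Flags match an exhaustive re-implementation that scores every HSP
        without the per-subject collapse shortcut."""
        import itertools
        import random

        rng = random.Random(11)
        genes = {}
        gmap = {}
        for i in range(20):
            gid = f"g{i}"
            contig = f"c{i % 5}"
            gmap[gid] = contig
            self_bs = rng.uniform(100, 300)
            hits = [self_hit(self_bs, query=gid)]
            for j in range(rng.randint(1, 8)):
                lin = rng.choice([MET, BAC, SKIP])
                # multiple HSPs to the same subject on purpose
                subj = f"s{rng.randint(0, 3)}_{lin[0]}"
                for _ in range(rng.randint(1, 3)):
                    hits.append(hit(subj, rng.uniform(10, 350), lin, query=gid))
            genes[gid] = hits

        records = [alien_index(genes[g]) for g in sorted(genes)]
        flags = {
            v.contig_id: v.status == "bacterial_contaminant"
            for v in flag_contaminant_contigs(records, gmap)
        }

        # oracle: no collapse, direct max over every HSP
        oracle_ai = {}
        for gid, hits in genes.items():
            self_bs = max(h.bitscore for h in hits if h.is_self)
            nbs_o = max(
                [min(1, h.bitscore / self_bs) for h in hits
                 if "Metazoa" not in h.lineage and "Placobranchoidea" not in h.lineage],
                default=0.0,
            )
            nbs_m = max(
                [min(1, h.bitscore / self_bs) for h in hits
                 if "Metazoa" in h.lineage and "Placobranchoidea" not in h.lineage],
                default=0.0,
            )
            oracle_ai[gid] = nbs_o - nbs_m
        for rec_ in records:
            assert rec_.AI == pytest.approx(oracle_ai[rec_.gene_id])
        for contig, genes_on in itertools.groupby(sorted(gmap, key=gmap.get), key=gmap.get):
            ais = [oracle_ai[g] for g in genes_on]
            expect = min(ais) > 0 or sum(a > 0.1 for a in ais) >= len(ais) / 2
            assert flags[contig] is expect


class TestHgtCandidateFilter:
    @pytest.mark.parametrize(
        "ai,n_hits,contig,kept",
        [
            (0.15, 60, "nuc", True),
            (0.15, 49, "nuc", False),
            (0.10, 100, "nuc", False),  # strict inequality
            (0.5, 100, "bad", False),  # on a flagged contig
        ],
    )
    def test_filter(self, ai, n_hits, contig, kept):
        r = rec("g1", ai, n_hits)
        out = filter_hgt_candidates([r], {"bad"}, {"g1": contig})
        assert (len(out) == 1) is kept


class TestOrganelleFlagging:
    def test_two_significant_hits_flag(self):
        hits = [
            OrganelleHit("c1", "kleptoplast", "p1", 1e-6),
            OrganelleHit("c1", "kleptoplast", "p2", 1e-8),
        ]
        (v,) = flag_organelle_contigs(hits)
        assert v.status == "kleptoplast"

    def test_single_strong_hit_not_flagged(self):
        assert flag_organelle_contigs([OrganelleHit("c1", "mitochondrial", "p1", 1e-20)]) == []

    def test_hits_above_evalue_cutoff_ignored(self):
        hits = [
            OrganelleHit("c1", "kleptoplast", "p1", 1e-4),
            OrganelleHit("c1", "kleptoplast", "p2", 1e-4),
        ]
        assert flag_organelle_contigs(hits) == []


def test_synthetic_study_recovery(bundle, pipeline_run):
    """On the synthetic study every spiked contaminant contig is flagged and
    the spiked HGT gene survives the candidate filter."""
    from kleptoscreen import io as kio

    outdir, _ = pipeline_run
    import csv

    flagged = {
        r["contig_id"]
        for r in csv.DictReader(open(outdir / "contig_verdicts.tsv"), delimiter="\t")
        if r["status"] == "bacterial_contaminant"
    }
    assert bundle.truth.contaminant_contig_ids <= flagged
    assert flagged <= bundle.truth.contaminant_contig_ids  # and no nuclear contig
    assert kio.read_id_set(outdir / "hgt_candidates.txt") == bundle.truth.hgt_gene_ids
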