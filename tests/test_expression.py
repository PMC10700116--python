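"""Length-scaled TPM, TMM, NB exact test, dispersion and DEG calling."""

import math

import numpy as np
import pandas as pd
import pytest

from kleptoscreen.expression import (
    CountMatrix,
    bh_adjust,
    call_degs,
    differential_expression,
    estimate_dispersion,
    expression_intersections,
    length_scaled_counts,
    length_scaled_tpm,
    nb_exact_test,
    stage_expression,
    tmm_factors,
)


def frames(counts, lengths, samples=None):
    samples = samples or [f"s{i}" for i in range(np.shape(counts)[1])]
    genes = [f"g{i}" for i in range(np.shape(counts)[0])]
    return (
        pd.DataFrame(counts, index=genes, columns=samples, dtype=float),
        pd.DataFrame(lengths, index=genes, columns=samples, dtype=float),
    )


class TestLengthScaledTPM:
    def test_uniform_counts_and_lengths(self):
        c, l = frames(np.full((4, 2), 50), np.full((4, 2), 1000))
        tpm = length_scaled_tpm(c, l)
        assert np.allclose(tpm.to_numpy(), 250_000.0)

    def test_zero_column_stays_zero(self):
        c, l = frames([[10, 0], [20, 0]], np.full((2, 2), 500))
        tpm = length_scaled_tpm(c, l)
        assert (tpm.iloc[:, 1] == 0).all()
        assert tpm.iloc[:, 0].sum() == pytest.approx(1e6)

    def test_against_straight_line_reference(self):
        """Two-step reference: TPM -> multiply by mean length -> rescale to
        library size -> back to per-million, coded directly from the
        definition with explicit loops."""
        rng = np.random.default_rng(5)
        c, l = frames(rng.integers(0, 500, (30, 6)), rng.uniform(300, 3000, (30, 6)))
        got = length_scaled_tpm(c, l).to_numpy()

        n_g, n_s = c.shape
        cv, lv = c.to_numpy(), l.to_numpy()
        expected = np.zeros((n_g, n_s))
        for s in range(n_s):
            rates = [cv[g, s] / lv[g, s] for g in range(n_g)]
            tot = sum(rates)
            tpm = [r / tot * 1e6 for r in rates]
            lbar = [sum(lv[g, :]) / n_s for g in range(n_g)]
            weighted = [tpm[g] * lbar[g] for g in range(n_g)]
            wtot = sum(weighted)
            for g in range(n_g):
                expected[g, s] = weighted[g] / wtot * 1e6
        assert np.allclose(got, expected, rtol=1e-9)

    def test_columns_sum_to_library_size_on_count_scale(self):
        rng = np.random.default_rng(6)
        c, l = frames(rng.integers(0, 500, (20, 4)), rng.uniform(300, 3000, (20, 4)))
        lsc = length_scaled_counts(c, l)
        assert np.allclose(lsc.sum(axis=0), c.sum(axis=0))

    def test_zero_length_rejected(self):
        c, l = frames([[1]], [[0]])
        with pytest.raises(ValueError):
            length_scaled_tpm(c, l)


class TestStageExpression:
    STAGE_MAP = {"a1": "egg", "a2": "egg", "a3": "egg"}

    def test_mean_below_threshold(self):
        tpm = pd.DataFrame([[0.5, 1.5, 0.5]], index=["g"], columns=["a1", "a2", "a3"])
        se = stage_expression(tpm, self.STAGE_MAP)
        assert se.loc["g", "mean_egg"] == pytest.approx(0.8333, abs=1e-4)
        assert not se.loc["g", "expressed_egg"]

    def test_comparator_contract_at_exact_threshold(self):
        tpm = pd.DataFrame([[1.0, 1.0, 1.0]], index=["g"], columns=["a1", "a2", "a3"])
        assert stage_expression(tpm, self.STAGE_MAP, comparator=">=").loc["g", "expressed_egg"]
        assert not stage_expression(tpm, self.STAGE_MAP, comparator=">").loc["g", "expressed_egg"]

    def test_unmapped_sample_errors(self):
        tpm = pd.DataFrame([[1.0]], index=["g"], columns=["weird"])
        with pytest.raises(ValueError):
            stage_expression(tpm, self.STAGE_MAP)


class TestIntersections:
    def test_partition_matches_brute_force(self):
        rng = np.random.default_rng(2)
        stages = ["egg", "veliger", "larva", "juvenile"]
        flags = pd.DataFrame(
            rng.random((60, 4)) < 0.5,
            columns=[f"expressed_{s}" for s in stages],
            index=[f"g{i}" for i in range(60)],
        )
        counts = expression_intersections(flags)
        assert counts.sum() == 60
        # brute force gene-by-gene
        expected = {}
        for g in flags.index:
            key = tuple(s for s in stages if flags.loc[g, f"expressed_{s}"])
            expected[key] = expected.get(key, 0) + 1
        assert dict(counts.items()) == expected

    def test_nothing_expressed(self):
        flags = pd.DataFrame(False, index=["g1", "g2"], columns=["expressed_egg"])
        counts = expression_intersections(flags)
        assert counts[()] == 2 and counts.sum() == 2


def reference_tmm(counts: np.ndarray, trim_m=0.3, trim_a=0.05):
    """Independent textbook implementation: sort-based trimming with plain
    python bookkeeping, following the published TMM recipe."""
    lib = counts.sum(axis=0).astype(float)
    uq = []
    for j in range(counts.shape[1]):
        nz = sorted(c / lib[j] for c in counts[:, j] if c > 0)
        uq.append(np.quantile(nz, 0.75))
    ref = int(np.argmin([abs(u - np.mean(uq)) for u in uq]))
    factors = []
    for j in range(counts.shape[1]):
        if j == ref:
            factors.append(1.0)
            continue
        rows = [g for g in range(counts.shape[0]) if counts[g, j] > 0 and counts[g, ref] > 0]
        m = {g: math.log2((counts[g, j] / lib[j]) / (counts[g, ref] / lib[ref])) for g in rows}
        a = {g: 0.5 * math.log2((counts[g, j] / lib[j]) * (counts[g, ref] / lib[ref])) for g in rows}
        n = len(rows)
        by_m = sorted(rows, key=lambda g: m[g])
        by_a = sorted(rows, key=lambda g: a[g])
        lo_m, hi_m = int(np.floor(n * trim_m)), n - int(np.floor(n * trim_m))
        lo_a, hi_a = int(np.floor(n * trim_a)), n - int(np.floor(n * trim_a))
        keep = set(by_m[lo_m:hi_m]) & set(by_a[lo_a:hi_a])
        num = den = 0.0
        for g in keep:
            var = (lib[j] - counts[g, j]) / (lib[j] * counts[g, j]) + (
                lib[ref] - counts[g, ref]
            ) / (lib[ref] * counts[g, ref])
            num += m[g] / var
            den += 1.0 / var
        factors.append(2 ** (num / den))
    f = np.array(factors)
    return f / np.exp(np.mean(np.log(f)))


class TestTMM:
    def test_identical_columns(self):
        c = pd.DataFrame(np.tile(np.arange(1, 21)[:, None], (1, 2)))
        assert np.allclose(tmm_factors(c), [1.0, 1.0])

    def test_pure_depth_difference(self):
        col = np.arange(1, 51)
        c = pd.DataFrame(np.column_stack([col, 2 * col]))
        assert np.allclose(tmm_factors(c), [1.0, 1.0])

    def test_composition_bias_matches_reference(self):
        rng = np.random.default_rng(9)
        base = rng.integers(20, 2000, 400).astype(float)
        biased = base.copy()
        biased[:40] *= 8  # 10% of genes massively up in sample 3
        counts = np.column_stack(
            [
                rng.poisson(base),
                rng.poisson(base * 1.4),
                rng.poisson(biased),
            ]
        )
        got = tmm_factors(pd.DataFrame(counts)).to_numpy()
        want = reference_tmm(counts)
        assert np.allclose(got, want, rtol=0.02)
        assert got[2] < got[0]  # biased sample pushed down

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(10)
        c = pd.DataFrame(rng.integers(0, 300, (100, 5)))
        f = tmm_factors(c)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_column_rejected(self):
        c = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            tmm_factors(c)


def binomial_double_tail_oracle(counts_a, counts_b, tail="2min"):
    """Direct enumeration of the conditional binomial double-tail test for
    equal library sizes and dispersion 0."""
    sa, sb = sum(counts_a), sum(counts_b)
    t = sa + sb
    na, nb = len(counts_a), len(counts_b)
    p = na / (na + nb)
    pmf = [math.comb(t, s) * p**s * (1 - p) ** (t - s) for s in range(t + 1)]
    lower = sum(pmf[: sa + 1])
    upper = sum(pmf[sa:])
    return min(1.0, 2 * min(lower, upper))


class TestExactTest:
    LIBS = np.array([1000.0] * 3)

    def test_identical_groups_give_p_one(self):
        for phi in (0.0, 0.1, 0.5):
            p = nb_exact_test([5, 9, 7], [5, 9, 7], self.LIBS, self.LIBS, phi)
            assert p == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        a, b = [30, 42, 38], [5, 9, 7]
        p1 = nb_exact_test(a, b, self.LIBS, self.LIBS, 0.2)
        p2 = nb_exact_test(b, a, self.LIBS, self.LIBS, 0.2)
        assert p1 == pytest.approx(p2, rel=1e-9)

    @pytest.mark.parametrize(
        "a,b",
        [([3, 5], [20, 18]), ([0, 0], [10, 12]), ([40, 35, 30], [20, 25]), ([1], [1])],
    )
    def test_dispersion_zero_equals_binomial_oracle(self, a, b):
        libs_a = np.full(len(a), 500.0)
        libs_b = np.full(len(b), 500.0)
        got = nb_exact_test(a, b, libs_a, libs_b, 0.0)
        assert got == pytest.approx(binomial_double_tail_oracle(a, b), rel=1e-9)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test([1], [1], [10.0], [10.0], -0.1)

    def test_null_pvalues_superuniform(self):
        """Type-I control: at phi = 0.2 the null rejection fraction at 0.05
        stays within Monte-Carlo reach of nominal."""
        rng = np.random.default_rng(42)
        phi = 0.2
        n = 10_000
        mu = 50.0
        lam = rng.gamma(1 / phi, phi * mu, size=(n, 6))
        counts = rng.poisson(lam)
        libs = np.full(3, 1000.0)
        ps = np.array(
            [nb_exact_test(c[:3], c[3:], libs, libs, phi) for c in counts]
        )
        assert (ps < 0.05).mean() <= 0.07


class TestDispersion:
    GROUPS = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}

    def counts(self, rng, phi, n=2000, mu_lo=30, mu_hi=300):
        mu = rng.uniform(mu_lo, mu_hi, n)[:, None] * np.ones(6)
        if phi == 0:
            x = rng.poisson(mu)
        else:
            x = rng.poisson(rng.gamma(1 / phi, phi * mu))
        return pd.DataFrame(x, columns=list(self.GROUPS))

    def test_poisson_counts_near_zero(self):
        c = self.counts(np.random.default_rng(1), 0.0)
        phi = estimate_dispersion(c, c.sum(axis=0), self.GROUPS, "common")
        assert phi.iloc[0] < 0.02

    def test_nb_dispersion_recovered(self):
        c = self.counts(np.random.default_rng(2), 0.4)
        phi = estimate_dispersion(c, c.sum(axis=0), self.GROUPS, "common")
        assert 0.3 <= phi.iloc[0] <= 0.5

    def test_identical_replicates_floored_at_zero(self):
        c = pd.DataFrame(np.tile([[10], [50]], (1, 6)), columns=list(self.GROUPS))
        phi = estimate_dispersion(c, c.sum(axis=0), self.GROUPS, "common")
        assert (phi == 0).all()

    def test_trended_tracks_common_on_homogeneous_data(self):
        c = self.counts(np.random.default_rng(3), 0.2)
        common = estimate_dispersion(c, c.sum(axis=0), self.GROUPS, "common").iloc[0]
        trended = estimate_dispersion(c, c.sum(axis=0), self.GROUPS, "trended")
        assert trended.median() == pytest.approx(common, rel=0.5)

    def test_single_samples_rejected(self):
        c = pd.DataFrame({"s0": [1, 2]})
        with pytest.raises(ValueError):
            estimate_dispersion(c, c.sum(axis=0), {"s0": "a"}, "common")


class TestBH:
    def test_hand_computed_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_brute_force_equivalence(self):
        """Step-up definition computed directly: adj_i = min over j>=i (by
        sorted p) of p_(j) * m / j, capped at 1."""
        rng = np.random.default_rng(8)
        for n in (1, 7, 100, 1000):
            p = rng.random(n)
            got = bh_adjust(p)
            order = np.argsort(p)
            m = len(p)
            adj_sorted = [p[order[i]] * m / (i + 1) for i in range(m)]
            for i in range(m - 2, -1, -1):
                adj_sorted[i] = min(adj_sorted[i], adj_sorted[i + 1])
            expected = np.empty(m)
            expected[order] = np.minimum(adj_sorted, 1.0)
            assert np.allclose(got, expected)


class TestDEGCalling:
    def test_threshold_logic(self):
        de = pd.DataFrame(
            {"log2fc": [2.5, 2.5, 1.9, 3.0], "fdr": [0.005, 0.02, 0.001, 0.009]},
            index=["a", "b", "c", "d"],
        )
        assert call_degs(de) == {"a", "d"}

    def test_spiked_genes_recovered(self, bundle):
        de = differential_expression(bundle.count_matrix)
        degs = call_degs(de)
        truth = bundle.truth.deg_gene_ids
        assert len(degs & truth) / len(truth) >= 0.8
        assert len(degs - truth) / max(1, len(degs)) <= 0.05
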