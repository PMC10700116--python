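"""Developmental-stage expression analysis.

The pipeline mirrors a standard count-based RNA-seq workflow for a 4-stage
(egg, veliger, larva, juvenile) x 3-replicate design:

1. length-scaled TPM: within-sample TPM re-weighted by each gene's average
   effective transcript length and re-normalized, giving abundances whose
   count-scale counterpart respects library size;
2. a minimum-expression filter (average length-scaled TPM >= 1 in at least
   one stage) defining the tested universe;
3. TMM (trimmed mean of M-values) normalization factors correcting
   between-sample composition bias;
4. a conditional negative-binomial exact test comparing the fed (juvenile)
   group against the pooled unfed group, using a moment-based common or
   trended dispersion and a double-tail rejection region;
5. Benjamini–Hochberg FDR and DEG calling at log2FC > 2, FDR < 0.01.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "CountMatrix",
    "length_scaled_tpm",
    "length_scaled_counts",
    "stage_expression",
    "expression_intersections",
    "tmm_factors",
    "nb_exact_test",
    "estimate_dispersion",
    "bh_adjust",
    "differential_expression",
    "call_degs",
]

STAGES = ("egg", "veliger", "larva", "juvenile")
_CMP = {">=": operator.ge, ">": operator.gt}


@dataclass
class CountMatrix:
    """Gene-level counts with effective lengths and a sample->stage map."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    eff_lengths: pd.DataFrame  # genes x samples, positive reals (bp)
    stage_of_sample: dict[str, str]

    def __post_init__(self):
        if not self.counts.columns.equals(self.eff_lengths.columns) or not self.counts.index.equals(
            self.eff_lengths.index
        ):
            raise ValueError("counts and eff_lengths must share genes and samples")
        unmapped = [s for s in self.counts.columns if s not in self.stage_of_sample]
        if unmapped:
            raise ValueError(f"samples without stage label: {unmapped}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if (self.eff_lengths.to_numpy() <= 0).any():
            raise ValueError("non-positive effective length")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def stages(self) -> pd.Series:
        return pd.Series({s: self.stage_of_sample[s] for s in self.counts.columns})

    def samples_of_stage(self, stage: str) -> list[str]:
        return [s for s in self.counts.columns if self.stage_of_sample[s] == stage]


def _tpm(counts: pd.DataFrame, eff_lengths: pd.DataFrame) -> pd.DataFrame:
    rate = counts / eff_lengths
    colsum = rate.sum(axis=0)
    # all-zero columns stay all-zero rather than dividing by zero
    safe = colsum.replace(0, np.nan)
    return (rate / safe * 1e6).fillna(0.0)


def length_scaled_tpm(counts: pd.DataFrame, eff_lengths: pd.DataFrame) -> pd.DataFrame:
    """Length-scaled TPM matrix (each nonzero column sums to 1e6).

    Plain TPM is re-weighted by the per-gene average effective length over
    samples and each column re-normalized to per-million scale, so genes are
    on a common length basis across samples.
    """
    if (eff_lengths.to_numpy() <= 0).any():
        raise ValueError("effective lengths must be positive")
    tpm = _tpm(counts, eff_lengths)
    lbar = eff_lengths.mean(axis=1)
    weighted = tpm.mul(lbar, axis=0)
    colsum = weighted.sum(axis=0).replace(0, np.nan)
    return (weighted / colsum * 1e6).fillna(0.0)


def length_scaled_counts(counts: pd.DataFrame, eff_lengths: pd.DataFrame) -> pd.DataFrame:
    """Count-scale counterpart: length-scaled TPM rescaled so that each
    column sums to the sample's observed library size."""
    lstpm = length_scaled_tpm(counts, eff_lengths)
    return lstpm.mul(counts.sum(axis=0) / 1e6, axis=1)


def stage_expression(
    tpm: pd.DataFrame,
    stage_of_sample: dict[str, str],
    threshold: float = 1.0,
    comparator: str = ">=",
) -> pd.DataFrame:
    """Per-stage mean TPM and the expressed flag (mean {comparator} threshold).

    Returns a frame indexed by gene with one ``mean_<stage>`` and one
    ``expressed_<stage>`` column per stage.
    """
    cmp = _CMP[comparator]
    unmapped = [s for s in tpm.columns if s not in stage_of_sample]
    if unmapped:
        raise ValueError(f"samples without stage label: {unmapped}")
    out = pd.DataFrame(index=tpm.index)
    stages = sorted(set(stage_of_sample[s] for s in tpm.columns), key=_stage_order)
    for stage in stages:
        cols = [s for s in tpm.columns if stage_of_sample[s] == stage]
        mean = tpm[cols].mean(axis=1)
        out[f"mean_{stage}"] = mean
        out[f"expressed_{stage}"] = cmp(mean, threshold)
    return out


def _stage_order(stage: str):
    return (STAGES.index(stage), stage) if stage in STAGES else (len(STAGES), stage)


def expression_intersections(stage_expr: pd.DataFrame) -> pd.Series:
    """UpSet-style partition: gene counts per exact expressed-stage subset.

    Every gene lands in exactly one subset (keyed by the sorted tuple of
    stages it is expressed in, the empty tuple for unexpressed genes), so the
    counts sum to the number of genes.
    """
    flag_cols = [c for c in stage_expr.columns if c.startswith("expressed_")]
    stages = [c.removeprefix("expressed_") for c in flag_cols]
    keys = stage_expr[flag_cols].apply(
        lambda row: tuple(st for st, v in zip(stages, row) if v), axis=1
    )
    counts = keys.value_counts()
    counts.index.name = "stage_subset"
    return counts.sort_index()


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.3, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors (geometric mean 1).

    The reference sample is the column whose upper quartile of nonzero
    library-size-scaled counts is closest to the mean upper quartile. For each
    sample, genes zero in either it or the reference are excluded, log2 ratios
    (M) and average log2 abundances (A) are doubly trimmed (``trim_m`` from
    each M tail, ``trim_a`` from each A tail), and the factor is the
    exponentiated precision-weighted mean M.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("all-zero column in count matrix")

    def upper_quartile(col: pd.Series, n: float) -> float:
        nz = col[col > 0].to_numpy(dtype=float)
        return float(np.quantile(nz / n, 0.75)) if nz.size else 0.0

    uq = np.array([upper_quartile(counts[s], lib[s]) for s in counts.columns])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = counts.columns[ref_idx]
    cr = counts[ref].to_numpy(dtype=float)
    nr = lib[ref]

    factors = {}
    for s in counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        cs = counts[s].to_numpy(dtype=float)
        ns = lib[s]
        keep = (cs > 0) & (cr > 0)
        if keep.sum() == 0:
            factors[s] = 1.0
            continue
        ps, pr = cs[keep] / ns, cr[keep] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        w = (ns - cs[keep]) / (ns * cs[keep]) + (nr - cr[keep]) / (nr * cr[keep])
        n = m.size
        rm = sps.rankdata(m)
        ra = sps.rankdata(a)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        kept = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not kept.any() or w[kept].sum() == 0:
            factors[s] = 1.0
        else:
            factors[s] = float(2 ** (np.sum(m[kept] / w[kept]) / np.sum(1.0 / w[kept])))

    f = pd.Series(factors)[counts.columns]
    return f / np.exp(np.mean(np.log(f)))


def _equalize(counts: np.ndarray, libsizes: np.ndarray, common: float) -> float:
    """Deterministically rescale counts to a common library size and sum."""
    return float(np.sum(counts * (common / libsizes)))


def nb_exact_test(
    counts_a,
    counts_b,
    libsizes_a,
    libsizes_b,
    dispersion: float,
    tail: str = "2min",
) -> float:
    """Conditional NB exact test between two replicate groups for one gene.

    Counts are deterministically rescaled to the geometric-mean effective
    library size and summed per group; under the null the group sums, given
    their total, follow the conditional distribution of two negative
    binomials (a binomial when dispersion = 0). ``tail='2min'`` returns
    min(1, 2*min(lower, upper)) with the observed outcome in both tails;
    ``tail='smallp'`` sums the probability of all outcomes at most as likely
    as the observed one.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if tail not in ("2min", "smallp"):
        raise ValueError(f"unknown tail rule {tail!r}")
    ca = np.asarray(counts_a, dtype=float)
    cb = np.asarray(counts_b, dtype=float)
    la = np.asarray(libsizes_a, dtype=float)
    lb = np.asarray(libsizes_b, dtype=float)
    if (ca < 0).any() or (cb < 0).any():
        raise ValueError("counts must be non-negative")
    common = float(np.exp(np.mean(np.log(np.concatenate([la, lb])))))
    sa = int(round(_equalize(ca, la, common)))
    sb = int(round(_equalize(cb, lb, common)))
    t = sa + sb
    na, nb = len(ca), len(cb)
    if t == 0:
        return 1.0

    if dispersion == 0:
        prob = na / (na + nb)
        lower = float(sps.binom.cdf(sa, t, prob))
        upper = float(sps.binom.sf(sa - 1, t, prob))
        if tail == "2min":
            return min(1.0, 2 * min(lower, upper))
        pmf = sps.binom.pmf(np.arange(t + 1), t, prob)
    else:
        mu = t / (na + nb)  # per-library null mean on the common scale
        s = np.arange(t + 1)
        ra_, rb_ = na / dispersion, nb / dispersion
        log_a = sps.nbinom.logpmf(s, ra_, ra_ / (ra_ + na * mu))
        log_b = sps.nbinom.logpmf(s, rb_, rb_ / (rb_ + nb * mu))
        joint = np.exp(log_a + log_b[::-1])
        total = joint.sum()
        if total == 0 or not np.isfinite(total):
            return 1.0
        pmf = joint / total
        lower = float(pmf[: sa + 1].sum())
        upper = float(pmf[sa:].sum())
        if tail == "2min":
            return min(1.0, 2 * min(lower, upper))
    # smallp: total probability of outcomes no more likely than the observed
    return float(min(1.0, pmf[pmf <= pmf[sa] * (1 + 1e-12)].sum()))


def estimate_dispersion(
    counts: pd.DataFrame,
    libsizes: pd.Series,
    groups: dict[str, str],
    mode: str = "common",
    n_bins: int = 10,
) -> pd.Series:
    """Moment-based NB dispersion, pooled ("common") or abundance-binned
    ("trended") with linear interpolation on log2 mean abundance.

    Counts are first rescaled to the geometric-mean library size; within each
    replicate group the method-of-moments identity var = mu + phi*mu^2 is
    inverted and pooled over genes (weighted by residual degrees of freedom),
    flooring negative estimates at zero.
    """
    if mode not in ("common", "trended"):
        raise ValueError(f"unknown mode {mode!r}")
    libs = libsizes[counts.columns].astype(float)
    common_lib = float(np.exp(np.mean(np.log(libs))))
    z = counts * (common_lib / libs)

    group_cols = {}
    for s, g in groups.items():
        if s in counts.columns:
            group_cols.setdefault(g, []).append(s)
    rep_groups = {g: cols for g, cols in group_cols.items() if len(cols) >= 2}
    if not rep_groups:
        raise ValueError("dispersion estimation needs >= 2 replicates in >= 1 group")

    num = pd.Series(0.0, index=counts.index)
    den = pd.Series(0.0, index=counts.index)
    for cols in rep_groups.values():
        sub = z[cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        df = len(cols) - 1
        num += df * (v - m)
        den += df * m**2

    def pooled(mask: pd.Series) -> float:
        d = den[mask].sum()
        return max(0.0, float(num[mask].sum() / d)) if d > 0 else 0.0

    overall_mean = z.mean(axis=1)
    if mode == "common":
        phi = pooled(pd.Series(True, index=counts.index))
        return pd.Series(phi, index=counts.index)

    pos = overall_mean > 0
    log_ab = np.log2(overall_mean[pos])
    order = log_ab.sort_values().index
    n_bins = max(1, min(n_bins, len(order)))
    bins = np.array_split(np.arange(len(order)), n_bins)
    xs, ys = [], []
    for b in bins:
        if len(b) == 0:
            continue
        members = order[b]
        mask = pd.Series(False, index=counts.index)
        mask[members] = True
        xs.append(float(log_ab[members].mean()))
        ys.append(pooled(mask))
    phi_per_gene = pd.Series(pooled(pd.Series(True, index=counts.index)), index=counts.index)
    if xs:
        phi_per_gene[pos] = np.interp(log_ab.to_numpy(), np.array(xs), np.array(ys))
    return phi_per_gene.clip(lower=0.0)


def differential_expression(
    cm: CountMatrix,
    fed_stage: str = "juvenile",
    tpm_threshold: float = 1.0,
    comparator: str = ">=",
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.01,
    dispersion_mode: str = "trended",
    tail: str = "2min",
) -> pd.DataFrame:
    """Fed-vs-unfed differential expression, start to finish.

    Filters to genes passing the stage-mean TPM threshold, TMM-normalizes,
    estimates dispersion within stages, runs the exact test of the fed stage
    against the pooled unfed stages, BH-adjusts, and reports log2 fold change
    (0.5 pseudo-count, reporting only), p, FDR and the DEG call per gene.
    """
    lstpm = length_scaled_tpm(cm.counts, cm.eff_lengths)
    sexpr = stage_expression(lstpm, cm.stage_of_sample, tpm_threshold, comparator)
    flag_cols = [c for c in sexpr.columns if c.startswith("expressed_")]
    tested = sexpr.index[sexpr[flag_cols].any(axis=1)]
    counts = cm.counts.loc[tested]

    lib = counts.sum(axis=0).astype(float)
    eff_lib = lib * tmm_factors(counts)

    disp = estimate_dispersion(counts, eff_lib, cm.stage_of_sample, mode=dispersion_mode)

    fed = cm.samples_of_stage(fed_stage)
    unfed = [s for s in counts.columns if s not in fed]
    if not fed or not unfed:
        raise ValueError(f"need samples on both sides of the {fed_stage} contrast")

    common = float(np.exp(np.mean(np.log(eff_lib))))
    z = counts * (common / eff_lib)
    mean_fed = z[fed].mean(axis=1)
    mean_unfed = z[unfed].mean(axis=1)
    log2fc = np.log2((mean_fed + 0.5) / (mean_unfed + 0.5))

    la = eff_lib[fed].to_numpy()
    lb = eff_lib[unfed].to_numpy()
    pvals = np.array(
        [
            nb_exact_test(
                counts.loc[g, fed].to_numpy(),
                counts.loc[g, unfed].to_numpy(),
                la,
                lb,
                float(disp[g]),
                tail=tail,
            )
            for g in counts.index
        ]
    )
    fdr = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "is_deg": (log2fc > fc_threshold) & (fdr < fdr_threshold),
        },
        index=counts.index,
    )
    out.index.name = "gene_id"
    return out


def call_degs(de_table: pd.DataFrame, fc_threshold: float = 2.0, fdr_threshold: float = 0.01) -> set[str]:
    """DEG gene ids: log2FC above and FDR below their thresholds."""
    mask = (de_table["log2fc"] > fc_threshold) & (de_table["fdr"] < fdr_threshold)
    return set(de_table.index[mask])
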