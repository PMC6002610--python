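"""TMM normalisation and threshold-based differential expression calling.

The calling rule follows the study design this package targets: a gene is
differentially expressed between enriched (EE) and barren (B) groups when its
between-group fold change exceeds +/-1.2 AND its gene-wise p-value is below
0.02, with no multiple-testing correction (the thresholds themselves are the
conservatism). Normalisation is the trimmed mean of M-values (TMM) scheme:
scaling factors from a doubly-trimmed, precision-weighted mean of gene-wise
log ratios against a reference sample.

The gene-wise test is deliberately simple and documented rather than an
attempt at bit-compatibility with any particular Bioconductor release:
Welch's t on log2(CPM + prior) by default, or an exact-style negative
binomial test with a method-of-moments common dispersion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SampleTable

log = logging.getLogger(__name__)


@dataclass
class DEConfig:
    fc_threshold: float = 1.2
    p_threshold: float = 0.02
    prior_count: float = 0.5
    test: str = "welch_logcpm"  # or "nb_exact_mom"

    def __post_init__(self) -> None:
        if not self.fc_threshold > 1:
            raise ValueError("fc_threshold must exceed 1")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.prior_count < 0:
            raise ValueError("prior_count must be non-negative")
        if self.test not in ("welch_logcpm", "nb_exact_mom"):
            raise ValueError(f"unknown test {self.test!r}")


# ---------------------------------------------------------------------------
# TMM normalisation


def _tmm_pair(obs: np.ndarray, ref: np.ndarray,
              lib_obs: float, lib_ref: float,
              logratio_trim: float = 0.3, sum_trim: float = 0.05,
              a_cutoff: float = -1e10) -> float:
    """Scaling factor of one sample against the reference (unlogged)."""
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok], ref[ok]
    if obs.size == 0:
        return 1.0
    p_obs = obs / lib_obs
    p_ref = ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    keep = a > a_cutoff
    m, a, w = m[keep], a[keep], w[keep]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0 ** f)


def tmm_factors(counts: ExpressionMatrix,
                logratio_trim: float = 0.3, sum_trim: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, one per sample.

    The reference sample is the one whose 75th percentile of library-scaled
    counts is closest to the mean such percentile. M-values (log2 relative
    expression ratios) are trimmed by 30% at each end and A-values (log2
    average abundance) by 5%, the surviving M-values averaged with inverse
    asymptotic binomial-variance weights, and the resulting factors centred
    so their log-mean is 0 (product of factors = 1).
    """
    x = counts.values.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = x.sum(axis=0)
    if (lib == 0).any():
        bad = [counts.sample_ids[i] for i in np.flatnonzero(lib == 0)]
        raise ValueError(f"all-zero sample(s): {bad}")
    q75 = np.quantile(x / lib, 0.75, axis=0)
    ref_j = int(np.argmin(np.abs(q75 - q75.mean())))
    fac = np.array([
        1.0 if j == ref_j else _tmm_pair(x[:, j], x[:, ref_j], lib[j], lib[ref_j],
                                         logratio_trim, sum_trim)
        for j in range(x.shape[1])
    ])
    fac = fac / np.exp(np.mean(np.log(fac)))
    return pd.Series(fac, index=counts.sample_ids, name="tmm_factor")


def cpm(counts: ExpressionMatrix, factors: pd.Series | None = None
        ) -> ExpressionMatrix:
    """Counts per million over TMM-effective library sizes.

    CPM_gj = count_gj / (libsize_j * factor_j) * 1e6; identity factors give
    plain library-size CPM whose columns sum to 1e6.
    """
    lib = counts.values.sum(axis=0)
    if factors is not None:
        lib = lib * factors.reindex(counts.values.columns)
    if (lib <= 0).any():
        raise ValueError("non-positive effective library size")
    out = counts.values.div(lib, axis=1) * 1e6
    return ExpressionMatrix(out, "CPM")


# ---------------------------------------------------------------------------
# Fold changes and gene-wise tests


def fold_changes(cpm_mat: ExpressionMatrix, group_a: Sequence[str],
                 group_b: Sequence[str], prior_count: float = 0.5) -> pd.Series:
    """Per-gene log2 fold change, group A over group B, prior-damped.

    log2fc = log2((mean_A + prior) / (mean_B + prior)); the prior keeps the
    value finite at zero counts. Group A is conventionally EE, B barren, so
    positive values mean higher in EE.
    """
    if not len(group_a) or not len(group_b):
        raise ValueError("both groups must be nonempty")
    mean_a = cpm_mat.values[list(group_a)].mean(axis=1)
    mean_b = cpm_mat.values[list(group_b)].mean(axis=1)
    lfc = np.log2(mean_a + prior_count) - np.log2(mean_b + prior_count)
    return pd.Series(lfc, index=cpm_mat.values.index, name="log2fc")


def _welch_logcpm(cpm_mat: ExpressionMatrix, group_a: Sequence[str],
                  group_b: Sequence[str], prior_count: float) -> np.ndarray:
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("welch_logcpm needs >=2 samples per group; "
                         "use test='nb_exact_mom' for smaller groups")
    la = np.log2(cpm_mat.values[list(group_a)].to_numpy() + prior_count)
    lb = np.log2(cpm_mat.values[list(group_b)].to_numpy() + prior_count)
    res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate zero-variance genes: identical groups are null (p=1),
    # perfectly separated ones maximally significant
    nan = ~np.isfinite(p)
    if nan.any():
        equal = np.isclose(la[nan].mean(axis=1), lb[nan].mean(axis=1))
        p[nan] = np.where(equal, 1.0, 0.0)
    return p


def _nb_exact_pvalue(ya: float, yb: float, na: int, nb_: int, phi: float,
                     max_total: int = 200_000) -> float:
    """Two-sided exact-style NB test conditional on the two group sums."""
    total = int(round(ya + yb))
    if total == 0:
        return 1.0
    if total > max_total:
        # normal approximation on the conditional distribution
        mu = total * na / (na + nb_)
        var = mu * (nb_ / (na + nb_)) * (1 + phi * total / (na + nb_))
        z = (ya - mu) / np.sqrt(max(var, 1e-12))
        return float(min(1.0, 2 * stats.norm.sf(abs(z))))
    mu_hat = total / (na + nb_)
    size_a, size_b = na / phi, nb_ / phi
    pa = size_a / (size_a + na * mu_hat)
    pb = size_b / (size_b + nb_ * mu_hat)
    support = np.arange(total + 1)
    lp = (stats.nbinom.logpmf(support, size_a, pa)
          + stats.nbinom.logpmf(support[::-1], size_b, pb))
    lp -= lp.max()
    prob = np.exp(lp)
    prob /= prob.sum()
    obs = prob[int(round(ya))]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def _nb_exact_mom(counts: ExpressionMatrix, group_a: Sequence[str],
                  group_b: Sequence[str]) -> np.ndarray:
    """Exact-style NB test with a common method-of-moments dispersion.

    Counts are scaled to a common effective library size (pseudo-counts);
    the dispersion is the median across genes of the pooled within-group
    moment estimate (floored at 1e-4); per gene, the split of the combined
    total between groups is compared with its conditional null distribution.
    """
    lib = counts.values.sum(axis=0)
    fac = tmm_factors(counts) if counts.shape[1] >= 2 else pd.Series(1.0, index=counts.sample_ids)
    eff = lib * fac
    common = float(np.exp(np.log(eff).mean()))
    pseudo = counts.values.div(eff, axis=1) * common

    groups = [list(group_a), list(group_b)]
    disp = []
    for ids in groups:
        sub = pseudo[ids].to_numpy()
        if sub.shape[1] >= 2:
            mu = sub.mean(axis=1)
            v = sub.var(axis=1, ddof=1)
            ok = mu > 0
            disp.append((v[ok] - mu[ok]) / mu[ok] ** 2)
    phi = float(np.median(np.concatenate(disp))) if disp else 0.1
    phi = max(phi, 1e-4)

    ya = pseudo[groups[0]].sum(axis=1).round().to_numpy()
    yb = pseudo[groups[1]].sum(axis=1).round().to_numpy()
    na, nb_ = len(groups[0]), len(groups[1])
    return np.array([_nb_exact_pvalue(a, b, na, nb_, phi) for a, b in zip(ya, yb)])


def gene_test(counts: ExpressionMatrix, group_a: Sequence[str],
              group_b: Sequence[str], config: DEConfig,
              factors: pd.Series | None = None) -> pd.Series:
    """Two-sided per-gene p-values for group A vs group B."""
    if config.test == "welch_logcpm":
        p = _welch_logcpm(cpm(counts, factors), group_a, group_b,
                          config.prior_count)
    else:
        p = _nb_exact_mom(counts, group_a, group_b)
    return pd.Series(np.clip(p, 0.0, 1.0), index=counts.values.index,
                     name="p_value")


def call_de(log2fc: pd.Series, p_values: pd.Series, config: DEConfig
            ) -> tuple[pd.DataFrame, dict]:
    """Apply the double-threshold rule and tally calls per direction.

    up: log2fc >= log2(fc_threshold) and p < p_threshold; down symmetric;
    everything else none. Returns the per-gene table and a summary dict.
    """
    if not log2fc.index.equals(p_values.index):
        raise ValueError("log2fc and p_values must share the same gene index")
    lfc_cut = np.log2(config.fc_threshold)
    sig = p_values < config.p_threshold
    call = np.where(sig & (log2fc >= lfc_cut), "up",
                    np.where(sig & (log2fc <= -lfc_cut), "down", "none"))
    table = pd.DataFrame({"log2fc": log2fc, "p_value": p_values, "call": call})
    summary = {"n_up": int((call == "up").sum()),
               "n_down": int((call == "down").sum())}
    return table, summary


# ---------------------------------------------------------------------------
# Model / Results front end


class DifferentialExpression:
    """Two-group differential expression model over raw counts.

    Parameters
    ----------
    counts : ExpressionMatrix (unit counts)
    samples : SampleTable
    group_a, group_b : sequences of sample ids, or ``(treatment, timepoint)``
        selectors where the timepoint may be None for "all"; group A is the
        numerator of the fold change (EE by convention).
    config : DEConfig

    ``fit()`` computes TMM factors over the union of the two groups, CPM,
    prior-damped log2 fold changes, gene-wise p-values and threshold calls,
    returning a :class:`DEResults`.
    """

    def __init__(self, counts: ExpressionMatrix, samples: SampleTable,
                 group_a, group_b, config: DEConfig | None = None):
        self.config = config or DEConfig()
        self.samples = samples
        self.group_a = self._resolve(samples, group_a)
        self.group_b = self._resolve(samples, group_b)
        if not self.group_a or not self.group_b:
            raise ValueError("empty comparison group")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("comparison groups overlap")
        self.counts = counts.subset_samples(self.group_a + self.group_b)

    @staticmethod
    def _resolve(samples: SampleTable, group) -> list[str]:
        if isinstance(group, tuple) and len(group) == 2:
            return samples.select(treatment=group[0], timepoint=group[1])
        return list(group)

    def fit(self) -> "DEResults":
        factors = tmm_factors(self.counts)
        cpm_mat = cpm(self.counts, factors)
        lfc = fold_changes(cpm_mat, self.group_a, self.group_b,
                           self.config.prior_count)
        p = gene_test(self.counts, self.group_a, self.group_b, self.config,
                      factors=factors)
        table, summary = call_de(lfc, p, self.config)
        return DEResults(table, summary, factors, self.config,
                         self.group_a, self.group_b)


class DEResults:
    """Fitted differential-expression results.

    Attributes: ``table`` (gene_id, log2fc, p_value, call), ``n_up``,
    ``n_down``, ``tmm_factors``.
    """

    def __init__(self, table: pd.DataFrame, summary: dict,
                 factors: pd.Series, config: DEConfig,
                 group_a: list[str], group_b: list[str]):
        self.table = table
        self.n_up = summary["n_up"]
        self.n_down = summary["n_down"]
        self.tmm_factors = factors
        self.config = config
        self.group_a = group_a
        self.group_b = group_b

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def p_values(self) -> pd.Series:
        return self.table["p_value"]

    def de_genes(self) -> list[str]:
        return list(self.table.index[self.table["call"] != "none"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id",
                          float_format="%.6g")

    def summary(self) -> str:
        lines = [
            "Differential expression (threshold calling)",
            "=" * 45,
            f"group A (n={len(self.group_a)}): {', '.join(self.group_a)}",
            f"group B (n={len(self.group_b)}): {', '.join(self.group_b)}",
            f"test: {self.config.test}   |FC| >= {self.config.fc_threshold}, "
            f"p < {self.config.p_threshold}",
            f"genes tested: {len(self.table)}",
            f"up in A:   {self.n_up}",
            f"down in A: {self.n_down}",
        ]
        return "\n".join(lines)
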