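"""Consensus differential-presence-of-exons (DPE) testing.

Two NB-GLM tests are run per comparison: a likelihood-ratio test (deviance
difference against chi-square, tagwise dispersions) and a quasi-likelihood
F-test (deviance-based quasi-dispersions squeezed toward their abundance
trend by empirical Bayes, trended dispersions).  Exons passing the BH-FDR
threshold under BOTH tests form the consensus DPE set; intersecting the
consensus sets of several comparisons yields the cross-comparison exonic
signature.

Comparisons follow the study design on groups M (metastatic), N
(non-metastatic), H (healthy) and U (unclassifiable, never fitted):
M_vs_N, C_vs_H with C = M u N, and M_vs_H.  Positive log2 fold-changes
mean over-representation in the first-named group.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess

from .dispersion import DispersionEstimates, average_log_cpm
from .glm import fit_nb_glm
from .types import CountMatrix, SampleInfo

COMPARISONS = ("M_vs_N", "C_vs_H", "M_vs_H")

_COMPARISON_GROUPS = {
    "M_vs_N": ({"M"}, {"N"}),
    "C_vs_H": ({"M", "N"}, {"H"}),
    "M_vs_H": ({"M"}, {"H"}),
}

LOGFC_PRIOR = 0.125  # stabilizes reported log fold-changes only


@dataclass
class DesignMatrix:
    matrix: np.ndarray            # samples x coefficients
    coef_names: list[str]
    contrast_index: int
    sample_indices: np.ndarray    # positions in the original sample list
    sample_ids: list[str]
    contrast_group: str           # first-named group of the comparison
    baseline_group: str


@dataclass
class TestResult:
    method: str                   # "LRT" or "QLF"
    comparison: str
    exon_ids: list[str]
    logfc: np.ndarray
    avg_log_cpm: np.ndarray
    statistic: np.ndarray
    p_value: np.ndarray
    fdr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exon_id": self.exon_ids,
                "logFC": self.logfc,
                "avgLogCPM": self.avg_log_cpm,
                "stat": self.statistic,
                "p": self.p_value,
                "fdr": self.fdr,
            }
        )


@dataclass
class DpeCallSet:
    comparison: str
    exon_ids: list[str]                  # called consensus exons
    direction: dict[str, str]            # exon -> over-represented group
    fdr_threshold: float
    universe: list[str]

    @property
    def called(self) -> set[str]:
        return set(self.exon_ids)

    def direction_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.direction.values():
            out[g] = out.get(g, 0) + 1
        return out


def build_design(samples: list[SampleInfo], comparison: str) -> DesignMatrix:
    """Intercept + group-indicator design for one of the study comparisons.

    Returns the retained sample subset (U samples are always excluded; for
    C_vs_H the cancer group pools M and N).
    """
    if comparison not in _COMPARISON_GROUPS:
        raise ValueError(f"unknown comparison {comparison!r}; expected one of {COMPARISONS}")
    contrast_codes, baseline_codes = _COMPARISON_GROUPS[comparison]
    idx, indicator, ids = [], [], []
    for i, s in enumerate(samples):
        if s.group in contrast_codes:
            idx.append(i)
            indicator.append(1.0)
            ids.append(s.sample_id)
        elif s.group in baseline_codes:
            idx.append(i)
            indicator.append(0.0)
            ids.append(s.sample_id)
    indicator = np.asarray(indicator)
    contrast_name = comparison.split("_vs_")[0]
    baseline_name = comparison.split("_vs_")[1]
    if indicator.sum() == 0 or (len(indicator) - indicator.sum()) == 0:
        raise ValueError(f"comparison {comparison}: one of the groups is empty")
    X = np.column_stack([np.ones_like(indicator), indicator])
    return DesignMatrix(
        matrix=X,
        coef_names=["intercept", contrast_name],
        contrast_index=1,
        sample_indices=np.asarray(idx),
        sample_ids=ids,
        contrast_group=contrast_name,
        baseline_group=baseline_name,
    )


def _offsets(matrix: CountMatrix, factors: np.ndarray | None) -> np.ndarray:
    f = np.ones(matrix.n_samples) if factors is None else np.asarray(factors, dtype=float)
    return np.log(matrix.lib_sizes * f)


def _reported_logfc(matrix: CountMatrix, design: DesignMatrix, factors, dispersions) -> np.ndarray:
    """log2 FC of contrast over baseline from a prior-count-stabilized fit."""
    y = matrix.counts + LOGFC_PRIOR
    fit = fit_nb_glm(y, design.matrix, _offsets(matrix, factors), dispersions)
    return fit.coef[:, design.contrast_index] / np.log(2.0)


def lrt_test(
    matrix: CountMatrix,
    design: DesignMatrix,
    factors: np.ndarray | None,
    dispersions: np.ndarray,
    comparison: str | None = None,
) -> TestResult:
    """NB-GLM likelihood-ratio test on the contrast coefficient (df = 1)."""
    offsets = _offsets(matrix, factors)
    phi = np.asarray(dispersions, dtype=float)
    full = fit_nb_glm(matrix.counts, design.matrix, offsets, phi)
    reduced_X = np.delete(design.matrix, design.contrast_index, axis=1)
    reduced = fit_nb_glm(matrix.counts, reduced_X, offsets, phi)
    stat = np.maximum(reduced.deviance - full.deviance, 0.0)
    p = stats.chi2.sf(stat, df=1)
    fdr = bh_adjust(p)
    return TestResult(
        method="LRT",
        comparison=comparison or "",
        exon_ids=list(matrix.exon_ids),
        logfc=_reported_logfc(matrix, design, factors, phi),
        avg_log_cpm=average_log_cpm(matrix.counts, matrix.lib_sizes),
        statistic=stat,
        p_value=p,
        fdr=fdr,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def squeeze_quasi_dispersions(
    s2: np.ndarray, df: int, abundance: np.ndarray, span: float = 0.5
) -> tuple[np.ndarray, float, np.ndarray]:
    """Empirical-Bayes squeeze of quasi-dispersions toward an abundance trend.

    Models s2 ~ s0^2(abundance) * F(df, prior_df); the prior df comes from
    moment matching on log s2 (the excess variance of log s2 over the
    trigamma(df/2) sampling noise determines trigamma(prior_df/2)).
    Returns (squeezed s2, prior_df, trend s0^2).
    """
    ok = s2 > 0
    z = np.log(np.where(ok, s2, np.nan))
    if ok.sum() >= 10:
        sm = lowess(z[ok], abundance[ok], frac=span, return_sorted=True)
        zt = np.interp(abundance, sm[:, 0], sm[:, 1])
    else:
        zt = np.full_like(s2, np.nanmean(z) if ok.any() else 0.0)
    e = z - zt
    evar = float(np.nanvar(e, ddof=1)) if ok.sum() > 1 else 0.0
    excess = evar - polygamma(1, df / 2.0)
    prior_df = 2.0 * _trigamma_inverse(excess) if excess > 1e-8 else np.inf
    # bias correction: E[log F(df, d0)] term
    bias = digamma(df / 2.0) - np.log(df / 2.0)
    if np.isfinite(prior_df):
        bias -= digamma(prior_df / 2.0) - np.log(prior_df / 2.0)
    s0_sq = np.exp(zt + np.nanmean(e) - bias)
    if np.isfinite(prior_df):
        squeezed = (prior_df * s0_sq + df * np.where(ok, s2, 0.0)) / (prior_df + df)
    else:
        squeezed = s0_sq.copy()
    return squeezed, prior_df, s0_sq


def qlf_test(
    matrix: CountMatrix,
    design: DesignMatrix,
    factors: np.ndarray | None,
    dispersions: np.ndarray,
    comparison: str | None = None,
) -> TestResult:
    """Quasi-likelihood F-test with empirical-Bayes moderated dispersions.

    Fits with trended NB dispersions, estimates a raw quasi-dispersion
    s2 = residual deviance / residual df per exon, squeezes it toward the
    abundance trend, and tests the deviance difference of the contrast
    against F(1, residual df + prior df).
    """
    offsets = _offsets(matrix, factors)
    phi = np.asarray(dispersions, dtype=float)
    full = fit_nb_glm(matrix.counts, design.matrix, offsets, phi)
    df_res = full.df_residual
    if df_res < 1:
        raise ValueError("quasi-likelihood test needs >= 1 residual df")
    reduced_X = np.delete(design.matrix, design.contrast_index, axis=1)
    reduced = fit_nb_glm(matrix.counts, reduced_X, offsets, phi)
    dev_diff = np.maximum(reduced.deviance - full.deviance, 0.0)
    abund = average_log_cpm(matrix.counts, matrix.lib_sizes)
    s2 = full.deviance / df_res
    s2_post, prior_df, _ = squeeze_quasi_dispersions(s2, df_res, abund)
    f_stat = dev_diff / np.maximum(s2_post, 1e-12)
    df2 = df_res + prior_df
    if np.isfinite(df2):
        p = stats.f.sf(f_stat, 1, df2)
    else:
        p = stats.chi2.sf(f_stat, df=1)
    fdr = bh_adjust(p)
    return TestResult(
        method="QLF",
        comparison=comparison or "",
        exon_ids=list(matrix.exon_ids),
        logfc=_reported_logfc(matrix, design, factors, phi),
        avg_log_cpm=abund,
        statistic=f_stat,
        p_value=p,
        fdr=fdr,
    )


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def call_dpe(
    lrt: TestResult, qlf: TestResult, fdr_threshold: float = 0.001
) -> DpeCallSet:
    """Consensus DPE calls: exons significant under BOTH tests at the threshold."""
    if lrt.exon_ids != qlf.exon_ids:
        raise ValueError("LRT and QLF results cover different exon universes")
    sig = (lrt.fdr <= fdr_threshold) & (qlf.fdr <= fdr_threshold)
    called = [e for e, s in zip(lrt.exon_ids, sig) if s]
    comparison = lrt.comparison or qlf.comparison
    contrast, baseline = (comparison.split("_vs_") + ["", ""])[:2] if comparison else ("up", "down")
    direction = {
        e: (contrast if lf > 0 else baseline)
        for e, lf, s in zip(lrt.exon_ids, lrt.logfc, sig)
        if s
    }
    return DpeCallSet(
        comparison=comparison,
        exon_ids=called,
        direction=direction,
        fdr_threshold=fdr_threshold,
        universe=list(lrt.exon_ids),
    )


def intersect_signature(callsets: list[DpeCallSet]) -> tuple[set[str], dict[str, int]]:
    """Intersection of consensus sets across comparisons, plus Venn region counts."""
    if len(callsets) < 2:
        raise ValueError("need at least 2 call sets to intersect")
    sets = {cs.comparison or str(i): cs.called for i, cs in enumerate(callsets)}
    signature = set.intersection(*sets.values())
    venn: dict[str, int] = {}
    names = list(sets)
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            venn["&".join(combo)] = len(inside - outside)
    return signature, venn


def ma_plot_data(result: TestResult, called: DpeCallSet) -> pd.DataFrame:
    """Table of (avgLogCPM, logFC, is_dpe) for MA-plot rendering."""
    if set(result.exon_ids) != set(called.universe):
        raise ValueError("result and call set cover different exon universes")
    flag = np.isin(result.exon_ids, list(called.called))
    return pd.DataFrame(
        {
            "exon_id": result.exon_ids,
            "avgLogCPM": result.avg_log_cpm,
            "logFC": result.logfc,
            "is_dpe": flag,
        }
    )


def dpe_table(lrt: TestResult, qlf: TestResult, calls: DpeCallSet) -> pd.DataFrame:
    """Combined per-exon output table for one comparison."""
    df = pd.DataFrame(
        {
            "exon_id": lrt.exon_ids,
            "logFC": lrt.logfc,
            "avgLogCPM": lrt.avg_log_cpm,
            "stat_lrt": lrt.statistic,
            "p_lrt": lrt.p_value,
            "fdr_lrt": lrt.fdr,
            "stat_qlf": qlf.statistic,
            "p_qlf": qlf.p_value,
            "fdr_qlf": qlf.fdr,
        }
    )
    df["is_dpe"] = df["exon_id"].isin(calls.called)
    df["direction"] = df["exon_id"].map(calls.direction).fillna("")
    return df
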