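"""Dispersion estimation for the NB GLM: common, trended and tagwise.

The common dispersion maximizes the summed Cox-Reid adjusted profile
likelihood (APL) over a log-scale grid refined by golden-section search.
The trend is a lowess fit (span 0.5) through per-bin APL maximizers, with
exons binned by average log-CPM (about 100 exons per bin).  Tagwise values
shrink each exon's own APL maximizer toward the trend through a quadratic
penalty on log-dispersion whose weight is ``prior_df``: as prior_df grows
the tagwise estimates collapse onto the trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .glm import adjusted_profile_loglik

PHI_MIN, PHI_MAX = 1e-4, 4.0


@dataclass
class DispersionEstimates:
    common: float
    trended: np.ndarray   # per exon
    tagwise: np.ndarray   # per exon
    prior_df: float
    avg_log_cpm: np.ndarray


def average_log_cpm(counts: np.ndarray, lib_sizes: np.ndarray, prior: float = 0.5) -> np.ndarray:
    cpm = (counts + prior) / (lib_sizes + 2 * prior) * 1e6
    return np.log2(cpm).mean(axis=1)


def _golden_max(f, lo: float, hi: float, tol: float = 1e-3, max_iter: int = 40) -> float:
    """Golden-section maximization of f over log-dispersion [lo, hi]."""
    invphi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if abs(b - a) < tol:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2


def _maximize_summed_apl(counts, design, offsets, rows=None) -> float:
    """Dispersion maximizing sum of APL over the given rows."""
    y = counts if rows is None else counts[rows]

    def total(log_phi: float) -> float:
        return float(adjusted_profile_loglik(y, design, offsets, np.exp(log_phi)).sum())

    grid = np.log(np.geomspace(PHI_MIN, PHI_MAX, 9))
    vals = [total(g) for g in grid]
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if k == 0 and vals[0] >= vals[1]:
        return PHI_MIN
    return float(np.exp(_golden_max(total, lo, hi)))


def estimate_dispersions(
    counts: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray,
    lib_sizes: np.ndarray,
    prior_df: float = 10.0,
    bin_size: int = 100,
    span: float = 0.5,
) -> DispersionEstimates:
    """Estimate common, trended and tagwise NB dispersions.

    Requires at least 2 residual degrees of freedom; rows that are all zero
    inherit the trend (their own likelihood is flat in the dispersion).
    """
    y = np.asarray(counts, dtype=float)
    G, S = y.shape
    P = np.asarray(design).shape[1]
    if S - P < 2:
        raise ValueError("need >= 2 residual degrees of freedom to estimate dispersion")

    common = _maximize_summed_apl(y, design, offsets)

    abund = average_log_cpm(y, lib_sizes)
    order = np.argsort(abund, kind="stable")
    n_bins = max(1, G // bin_size)
    bins = np.array_split(order, n_bins)
    if n_bins >= 3:
        bin_x = np.array([abund[b].mean() for b in bins])
        bin_phi = np.array([_maximize_summed_apl(y, design, offsets, rows=b) for b in bins])
        sm = lowess(np.log(bin_phi), bin_x, frac=span, return_sorted=True)
        trended = np.exp(np.interp(abund, sm[:, 0], sm[:, 1]))
    else:
        trended = np.full(G, common)
    trended = np.clip(trended, PHI_MIN, PHI_MAX)

    # tagwise: per-exon APL plus a prior_df-weighted quadratic pull to the trend,
    # evaluated on a shared grid of ratios to the trend and refined parabolically
    ratios = np.geomspace(2.0 ** -6, 2.0 ** 6, 25)
    log_r = np.log(ratios)
    obj = np.empty((G, ratios.size))
    for k, r in enumerate(ratios):
        phi_k = np.clip(trended * r, PHI_MIN, PHI_MAX)
        apl = adjusted_profile_loglik(y, design, offsets, phi_k)
        obj[:, k] = apl - 0.5 * prior_df * np.log(phi_k / trended) ** 2
    best = np.argmax(obj, axis=1)
    # parabolic refinement on log-ratio around the grid maximum
    log_best = log_r[best]
    interior = (best > 0) & (best < ratios.size - 1)
    if np.any(interior):
        i = best[interior]
        g = np.where(interior)[0]
        y0, y1, y2 = obj[g, i - 1], obj[g, i], obj[g, i + 1]
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        step = log_r[1] - log_r[0]
        log_best[interior] = log_r[i] + np.clip(shift, -1, 1) * step
    tagwise = np.clip(trended * np.exp(log_best), PHI_MIN, PHI_MAX)
    allzero = y.sum(axis=1) == 0
    tagwise[allzero] = trended[allzero]
    return DispersionEstimates(
        common=common,
        trended=trended,
        tagwise=tagwise,
        prior_df=prior_df,
        avg_log_cpm=abund,
    )
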