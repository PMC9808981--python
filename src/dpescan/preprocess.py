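"""Count-matrix preprocessing: sex-exon removal, CPM filter, TMM, log-CPM.

The default pipeline order is: remove X/Y exons, recompute library sizes,
apply the low-presence CPM filter (library sizes kept), then estimate TMM
normalization factors.  The CPM filter follows the literal rule "remove an
exon with CPM below the cutoff in at least ``min_samples`` samples"; the
more common keep-if-expressed convention is available via
``convention="keep-if-expressed"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import CountMatrix, ExonCatalog

SEX_CHROMS = {"X", "Y"}


@dataclass
class FilterConfig:
    min_cpm: float = 1.0
    min_samples: int = 20
    remove_sex_exons: bool = True
    convention: str = "remove-if-low"  # or "keep-if-expressed"

    def __post_init__(self) -> None:
        if self.min_cpm < 0:
            raise ValueError("min_cpm must be >= 0")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.convention not in {"remove-if-low", "keep-if-expressed"}:
            raise ValueError(f"unknown filter convention {self.convention!r}")


def _is_sex_chrom(chrom: str) -> bool:
    c = chrom.lower()
    if c.startswith("chr"):
        c = c[3:]
    return c.upper() in SEX_CHROMS


def remove_sex_exons(matrix: CountMatrix, catalog: ExonCatalog) -> CountMatrix:
    """Drop exons on X/Y chromosomes and recompute library sizes."""
    missing = [e for e in matrix.exon_ids if e not in catalog]
    if missing:
        raise KeyError(f"exon ids missing from catalog: {sorted(missing)[:10]}")
    keep = [i for i, e in enumerate(matrix.exon_ids) if not _is_sex_chrom(catalog.get(e).chrom)]
    sub = matrix.counts[keep]
    return CountMatrix(
        counts=sub,
        exon_ids=[matrix.exon_ids[i] for i in keep],
        sample_ids=list(matrix.sample_ids),
        lib_sizes=sub.sum(axis=0).astype(float),
    )


def compute_cpm(matrix: CountMatrix) -> np.ndarray:
    """Counts per million: counts / lib_size * 1e6."""
    if np.any(matrix.lib_sizes <= 0):
        bad = [matrix.sample_ids[i] for i in np.where(matrix.lib_sizes <= 0)[0]]
        raise ValueError(f"zero library size for samples: {bad}")
    return matrix.counts / matrix.lib_sizes * 1e6


def filter_low_presence(matrix: CountMatrix, config: FilterConfig) -> CountMatrix:
    """Remove exons scarcely present across the cohort.

    Default convention removes exon g iff CPM[g,s] < min_cpm in at least
    min_samples samples.  Library sizes are NOT recomputed: they keep
    reflecting the pre-filter assay depth.
    """
    if config.min_samples > matrix.n_samples:
        raise ValueError(
            f"min_samples={config.min_samples} exceeds sample count {matrix.n_samples}"
        )
    cpm = compute_cpm(matrix)
    n_low = (cpm < config.min_cpm).sum(axis=1)
    if config.convention == "remove-if-low":
        keep = n_low < config.min_samples
    else:  # keep-if-expressed: keep iff >= min_cpm in >= min_samples samples
        keep = (matrix.n_samples - n_low) >= config.min_samples
    idx = np.where(keep)[0]
    return CountMatrix(
        counts=matrix.counts[idx],
        exon_ids=[matrix.exon_ids[i] for i in idx],
        sample_ids=list(matrix.sample_ids),
        lib_sizes=matrix.lib_sizes.copy(),
    )


def tmm_factors(
    matrix: CountMatrix,
    ref_sample: str | None = None,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed mean of M-values normalization factors (geometric mean 1).

    Per sample, the factor is 2**(weighted trimmed mean of per-exon
    log2-ratios vs the reference sample), where exons with a zero in either
    sample are excluded, the top/bottom ``logratio_trim`` of M-values and
    ``abundance_trim`` of A-values are trimmed, and weights are inverse
    asymptotic binomial variances.  The reference is the sample whose
    upper-quartile CPM is closest to the mean upper quartile.
    """
    if matrix.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    counts = matrix.counts.astype(float)
    if np.any(counts.sum(axis=0) == 0):
        bad = [matrix.sample_ids[i] for i in np.where(counts.sum(axis=0) == 0)[0]]
        raise ValueError(f"all-zero samples: {bad}")
    lib = matrix.lib_sizes
    cpm = counts / lib * 1e6
    uq = np.quantile(cpm, 0.75, axis=0)
    if ref_sample is not None:
        ref = matrix.sample_ids.index(ref_sample)
    else:
        ref = int(np.argmin(np.abs(uq - uq.mean())))
    log_factors = np.zeros(matrix.n_samples)
    for j in range(matrix.n_samples):
        if j == ref:
            continue
        log_factors[j] = _tmm_pair(
            counts[:, j], counts[:, ref], lib[j], lib[ref], logratio_trim, abundance_trim
        )
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return factors


def _tmm_pair(obs, ref, n_obs, n_ref, logratio_trim, abundance_trim) -> float:
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok], ref[ok]
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # inverse asymptotic variance of M under binomial sampling
    w = 1.0 / ((n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref))
    if np.max(np.abs(m)) < 1e-6:  # identical relative profiles
        return 0.0
    n = m.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
    lo_a, hi_a = np.floor(n * abundance_trim) + 1, n + 1 - (np.floor(n * abundance_trim) + 1)
    rank_m = _rank(m)
    rank_a = _rank(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep):
        return 0.0
    f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    return float(f) if np.isfinite(f) else 0.0


def _rank(x: np.ndarray) -> np.ndarray:
    """Average ranks, 1-based."""
    from scipy.stats import rankdata

    return rankdata(x)


def log_cpm(
    matrix: CountMatrix, factors: np.ndarray | None = None, prior_count: float = 0.5
) -> np.ndarray:
    """log2 CPM with effective library sizes and a prior count.

    log2((count + prior) / (lib_size * factor + 2 * prior) * 1e6); always
    finite.
    """
    if prior_count <= 0:
        raise ValueError("prior_count must be > 0")
    if factors is None:
        factors = np.ones(matrix.n_samples)
    eff_lib = matrix.lib_sizes * np.asarray(factors, dtype=float)
    return np.log2((matrix.counts + prior_count) / (eff_lib + 2 * prior_count) * 1e6)
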