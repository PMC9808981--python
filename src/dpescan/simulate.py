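"""Synthetic cfDNA cohort generator with known ground truth.

Counts are negative-binomial: exon g in sample s has mean
cpm[g, s] / 1e6 * lib_size[s] and dispersion phi_g = a / mu_g + b, the
usual decreasing mean-dispersion trend of count data.  Baseline exon
abundances are log2-CPM ~ Normal(4, 2) truncated at 0; library sizes are
log-normal around 3e7 fragments (sd 0.3 on the log scale), emulating a
shallow whole-exome cfDNA assay.

Differential exons come from two mechanisms:

* metastasis-specific exons — the M group mean is shifted by
  +-logfc_magnitude (log2), so they differ in M_vs_N and M_vs_H;
* cancer-wide exons — both M and N means are shifted relative to healthy,
  so they differ in C_vs_H and M_vs_H (only generated when H samples exist).

Unclassifiable (U) samples draw each exon's mean from M or N with equal
probability, placing them between the two groups.  A configurable fraction
of exons sits on chrX/chrY with male/female presence asymmetry, so the
sex-removal filter has something to remove.

The default cohort sizes mirror the study population: 17 M, 68 N, 11 U and
63 H samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CountMatrix, ExonCatalog, ExonRecord, SampleInfo

COMPARISONS = ("M_vs_N", "C_vs_H", "M_vs_H")


@dataclass
class SimConfig:
    n_exons: int = 5000
    n_m: int = 17
    n_n: int = 68
    n_h: int = 63
    n_u: int = 11
    baseline_log2cpm_mean: float = 4.0
    baseline_log2cpm_sd: float = 2.0
    dispersion_a: float = 2.0
    dispersion_b: float = 0.1
    fraction_dpe: float = 0.1
    logfc_magnitude: float = 2.0
    lib_size_log_mean: float = float(np.log(3e7))
    lib_size_log_sd: float = 0.3
    sex_exon_fraction: float = 0.02
    exons_per_gene: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fraction_dpe <= 1):
            raise ValueError("fraction_dpe must lie in [0, 1]")
        if not (0 <= self.sex_exon_fraction <= 1):
            raise ValueError("sex_exon_fraction must lie in [0, 1]")
        if min(self.n_exons, self.n_m, self.n_n) < 0 or min(self.n_h, self.n_u) < 0:
            raise ValueError("sizes must be non-negative")


@dataclass
class SimTruth:
    exon_ids: list[str]
    is_dpe: dict[str, np.ndarray]        # comparison -> bool per exon
    true_logfc: dict[str, np.ndarray]    # comparison -> log2 FC per exon
    dispersion: np.ndarray
    baseline_cpm: np.ndarray
    sample_groups: dict[str, str]
    sample_sex: dict[str, str]
    lib_sizes: dict[str, float]

    def true_set(self, comparison: str) -> set[str]:
        mask = self.is_dpe[comparison]
        return {e for e, m in zip(self.exon_ids, mask) if m}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"exon_id": self.exon_ids, "dispersion": self.dispersion,
                           "baseline_cpm": self.baseline_cpm})
        for cmp_ in self.is_dpe:
            df[f"is_dpe_{cmp_}"] = self.is_dpe[cmp_]
            df[f"logfc_{cmp_}"] = self.true_logfc[cmp_]
        return df


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mu, phi) with Var = mu + phi mu^2; Poisson rows where phi ~ 0."""
    mu = np.maximum(mu, 1e-12)
    phi = np.broadcast_to(np.asarray(phi, dtype=float).reshape(-1, 1), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi.max(axis=1) < 1e-12
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mu[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def _synthetic_catalog(n_exons: int, sex_idx: np.ndarray, rng: np.random.Generator,
                       exons_per_gene: int) -> ExonCatalog:
    sexset = set(sex_idx.tolist())
    records = []
    pos = {c: 1000 for c in [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]}
    for g in range(n_exons):
        if g in sexset:
            chrom = "chrX" if rng.random() < 0.7 else "chrY"
        else:
            chrom = f"chr{g % 22 + 1}"
        length = int(rng.integers(80, 300))
        start = pos[chrom]
        pos[chrom] = start + length + int(rng.integers(50, 500))
        records.append(ExonRecord(
            exon_id=f"E{g:06d}",
            gene_id=f"G{g // exons_per_gene:05d}",
            chrom=chrom,
            start=start,
            end=start + length,
            strand="+" if g % 2 == 0 else "-",
        ))
    return ExonCatalog(records)


def simulate_cohort(config: SimConfig) -> tuple[CountMatrix, ExonCatalog, list[SampleInfo], SimTruth]:
    """Simulate a full cohort: counts, catalog, sample sheet, ground truth."""
    rng = np.random.default_rng(config.seed)
    G = config.n_exons
    n_m, n_n, n_h, n_u = config.n_m, config.n_n, config.n_h, config.n_u
    if n_m < 1 or n_n < 1:
        raise ValueError("need at least one M and one N sample")

    base_log2 = np.maximum(
        rng.normal(config.baseline_log2cpm_mean, config.baseline_log2cpm_sd, G), 0.0
    )
    base_cpm = 2.0 ** base_log2

    n_dpe = int(round(config.fraction_dpe * G))
    n_mech = 2 if n_h > 0 else 1
    perm = rng.permutation(G)
    set_meta = perm[:n_dpe]                       # M shifted vs N and H
    set_cancer = perm[n_dpe:2 * n_dpe] if n_mech == 2 else np.array([], dtype=int)

    # per-group log2 offsets from the shared baseline
    delta = {g: np.zeros(G) for g in ("M", "N", "H")}
    signs_meta = rng.choice([-1.0, 1.0], size=set_meta.size)
    delta["M"][set_meta] = signs_meta * config.logfc_magnitude
    if set_cancer.size:
        signs_cancer = rng.choice([-1.0, 1.0], size=set_cancer.size)
        delta["M"][set_cancer] = signs_cancer * config.logfc_magnitude
        delta["N"][set_cancer] = signs_cancer * config.logfc_magnitude

    # sex exons: chrX doubled in females, chrY near-absent in females
    n_sex = int(round(config.sex_exon_fraction * G))
    nonsig = perm[2 * n_dpe:] if n_mech == 2 else perm[n_dpe:]
    sex_idx = nonsig[:n_sex]
    catalog = _synthetic_catalog(G, sex_idx, rng, config.exons_per_gene)
    chroms = np.array([r.chrom for r in catalog])

    groups = ["M"] * n_m + ["N"] * n_n + ["H"] * n_h + ["U"] * n_u
    S = len(groups)
    sexes = ["male" if rng.random() < 0.5 else "female" for _ in range(S)]
    sample_ids = [f"{g}{i + 1:03d}" for g, i in zip(groups, _running_index(groups))]
    lib_sizes = rng.lognormal(config.lib_size_log_mean, config.lib_size_log_sd, S)

    cpm_group = {g: base_cpm * 2.0 ** delta[g] for g in ("M", "N", "H")}
    cpm = np.empty((G, S))
    for j, g in enumerate(groups):
        if g == "U":  # per-exon coin flip between the M and N means
            pick_m = rng.random(G) < 0.5
            cpm[:, j] = np.where(pick_m, cpm_group["M"], cpm_group["N"])
        else:
            cpm[:, j] = cpm_group[g]
    # sex asymmetry
    is_x = chroms == "chrX"
    is_y = chroms == "chrY"
    for j, sex in enumerate(sexes):
        if sex == "female":
            cpm[is_x, j] *= 2.0
            cpm[is_y, j] *= 0.01
    mu = cpm / 1e6 * lib_sizes
    mu_bar = np.maximum(mu[:, :S - n_u if n_u else S].mean(axis=1), 1e-6)
    phi = config.dispersion_a / mu_bar + config.dispersion_b
    counts = _nb_draw(rng, mu, phi)

    samples = [SampleInfo(sid, g, sx) for sid, g, sx in zip(sample_ids, groups, sexes)]
    matrix = CountMatrix(counts, catalog.exon_ids, sample_ids)

    # exact per-comparison truth from the group offsets
    lfc = {
        "M_vs_N": delta["M"] - delta["N"],
        "M_vs_H": delta["M"] - delta["H"],
        "C_vs_H": np.log2(
            (n_m * 2.0 ** delta["M"] + n_n * 2.0 ** delta["N"]) / (n_m + n_n)
        ) - delta["H"],
    }
    truth = SimTruth(
        exon_ids=catalog.exon_ids,
        is_dpe={c: np.abs(v) > 1e-9 for c, v in lfc.items()},
        true_logfc=lfc,
        dispersion=phi,
        baseline_cpm=base_cpm,
        sample_groups=dict(zip(sample_ids, groups)),
        sample_sex=dict(zip(sample_ids, sexes)),
        lib_sizes=dict(zip(sample_ids, lib_sizes)),
    )
    return matrix, catalog, samples, truth


def _running_index(groups: list[str]) -> list[int]:
    seen: dict[str, int] = {}
    out = []
    for g in groups:
        out.append(seen.get(g, 0))
        seen[g] = out[-1] + 1
    return out


def simulate_null(
    n_exons: int, n_samples: int, dispersion: float = 0.2, seed: int = 0
) -> CountMatrix:
    """Single-population NB counts with no group structure (null cohorts)."""
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    base_cpm = 2.0 ** np.maximum(rng.normal(4.0, 2.0, n_exons), 0.0)
    lib_sizes = rng.lognormal(np.log(3e7), 0.3, n_samples)
    mu = base_cpm[:, None] / 1e6 * lib_sizes
    counts = _nb_draw(rng, mu, np.full(n_exons, float(dispersion)))
    return CountMatrix(counts, [f"E{g:06d}" for g in range(n_exons)],
                       [f"S{j + 1:03d}" for j in range(n_samples)])


def truth_eval(called: set[str], true_set: set[str]) -> tuple[float, float]:
    """(sensitivity, empirical FDR) of a call set against the simulated truth."""
    sens = len(called & true_set) / len(true_set) if true_set else 0.0
    efdr = len(called - true_set) / max(1, len(called))
    return sens, efdr
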