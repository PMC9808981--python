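"""End-to-end orchestration of the DPE study design.

``run_comparison`` executes one two-group contrast: design construction,
dispersion estimation, LRT and QLF testing, BH adjustment and consensus
calling.  ``run_full_study`` runs the three study comparisons (M_vs_N,
C_vs_H, M_vs_H), intersects their consensus sets into the exonic signature,
and derives the unsupervised (Ward/PCA/MDS) and supervised (random forest)
views plus optional gene-set over-representation.

All randomness flows from one root seed through named substreams so that a
fixed seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import RfConfig, RfReport, build_feature_matrix, classify_unknowns, train_eval_split
from .dispersion import estimate_dispersions
from .dpe_stats import (
    COMPARISONS,
    DpeCallSet,
    TestResult,
    build_design,
    call_dpe,
    dpe_table,
    intersect_signature,
    lrt_test,
    qlf_test,
)
from .enrich import map_exons_to_genes, ora_test
from .explore import classical_mds, leading_logfc_distance, pca, ward_cluster
from .preprocess import FilterConfig, filter_low_presence, log_cpm, remove_sex_exons, tmm_factors
from .types import CountMatrix, ExonCatalog, GeneSet, SampleInfo

logger = logging.getLogger("dpescan")


def derive_seed(root_seed: int, stream: str) -> int:
    """Deterministic named substream seed below 2**31."""
    h = int(root_seed)
    for ch in stream:
        h = (h * 1000003 + ord(ch)) & 0xFFFFFFFFFFFF
    return h % (2 ** 31 - 1)


@dataclass
class ComparisonResult:
    comparison: str
    lrt: TestResult
    qlf: TestResult
    calls: DpeCallSet

    def table(self) -> pd.DataFrame:
        return dpe_table(self.lrt, self.qlf, self.calls)


def preprocess_matrix(
    matrix: CountMatrix,
    catalog: ExonCatalog | None,
    config: FilterConfig | None = None,
) -> tuple[CountMatrix, np.ndarray]:
    """Sex-exon removal, low-presence filter and TMM factors."""
    config = config or FilterConfig()
    if config.remove_sex_exons:
        if catalog is None:
            raise ValueError("sex-exon removal requires an exon catalog")
        matrix = remove_sex_exons(matrix, catalog)
    min_samples = min(config.min_samples, matrix.n_samples)
    filtered = filter_low_presence(
        matrix,
        FilterConfig(config.min_cpm, min_samples, config.remove_sex_exons, config.convention),
    )
    factors = tmm_factors(filtered)
    return filtered, factors


def run_comparison(
    matrix: CountMatrix,
    samples: list[SampleInfo],
    comparison: str,
    factors: np.ndarray | None = None,
    fdr_threshold: float = 0.001,
    prior_df: float = 10.0,
) -> ComparisonResult:
    """One two-group contrast on an already-filtered matrix."""
    by_id = {s.sample_id: s for s in samples}
    ordered = [by_id[sid] for sid in matrix.sample_ids]
    design = build_design(ordered, comparison)
    sub = matrix.subset_samples(design.sample_indices)
    f = None if factors is None else np.asarray(factors)[design.sample_indices]
    offsets = np.log(sub.lib_sizes * (np.ones(sub.n_samples) if f is None else f))
    disp = estimate_dispersions(
        sub.counts, design.matrix, offsets, sub.lib_sizes, prior_df=prior_df
    )
    lrt = lrt_test(sub, design, f, disp.tagwise, comparison=comparison)
    qlf = qlf_test(sub, design, f, disp.trended, comparison=comparison)
    calls = call_dpe(lrt, qlf, fdr_threshold)
    assert calls.called <= {e for e, q in zip(lrt.exon_ids, lrt.fdr) if q <= fdr_threshold}
    assert calls.called <= {e for e, q in zip(qlf.exon_ids, qlf.fdr) if q <= fdr_threshold}
    logger.info("%s: %d consensus DPE at FDR<=%g", comparison, len(calls.exon_ids), fdr_threshold)
    return ComparisonResult(comparison, lrt, qlf, calls)


@dataclass
class StudyResult:
    comparisons: dict[str, ComparisonResult]
    signature: set[str]
    venn: dict[str, int]
    genes: set[str] | None
    logcpm: np.ndarray
    filtered: CountMatrix
    factors: np.ndarray
    linkage: object
    pca_scores: pd.DataFrame
    mds_coords: pd.DataFrame
    rf_report: RfReport | None
    unknown_assignments: pd.DataFrame | None
    enrichment: pd.DataFrame | None
    summary: dict = field(default_factory=dict)


def run_full_study(
    matrix: CountMatrix,
    samples: list[SampleInfo],
    catalog: ExonCatalog | None = None,
    filter_config: FilterConfig | None = None,
    fdr_threshold: float = 0.001,
    comparisons: tuple[str, ...] = COMPARISONS,
    rf_config: RfConfig | None = None,
    gene_sets: list[GeneSet] | None = None,
    seed: int = 0,
    mds_top_k: int = 500,
) -> StudyResult:
    """The full study: preprocess, three contrasts, signature, exploration,
    classification and optional enrichment."""
    filtered, factors = preprocess_matrix(matrix, catalog, filter_config)
    results: dict[str, ComparisonResult] = {}
    for cmp_ in comparisons:
        try:
            results[cmp_] = run_comparison(
                filtered, samples, cmp_, factors, fdr_threshold=fdr_threshold
            )
        except ValueError as exc:
            logger.warning("comparison %s skipped: %s", cmp_, exc)
    if len(results) >= 2:
        signature, venn = intersect_signature([r.calls for r in results.values()])
    elif results:
        only = next(iter(results.values())).calls
        signature, venn = only.called, {only.comparison: len(only.called)}
    else:
        raise ValueError("no comparison could be run on this sample sheet")

    lc = log_cpm(filtered, factors)
    sig_idx = [i for i, e in enumerate(filtered.exon_ids) if e in signature]
    explore_idx = sig_idx if sig_idx else list(range(min(500, filtered.n_exons)))
    sub_lc = lc[explore_idx]

    by_id = {s.sample_id: s for s in samples}
    ordered = [by_id[sid] for sid in filtered.sample_ids]
    known = [j for j, s in enumerate(ordered) if s.group != "U"]
    unknown = [j for j, s in enumerate(ordered) if s.group == "U"]

    tree = ward_cluster(sub_lc[:, known], [filtered.sample_ids[j] for j in known])
    pca_fit = pca(sub_lc[:, known], n_components=2)
    rows = [
        {"sample_id": filtered.sample_ids[j], "group": ordered[j].group,
         "PC1": sc[0], "PC2": sc[1], "projected": False}
        for j, sc in zip(known, pca_fit.scores)
    ]
    if unknown:  # U samples are projected onto the fitted axes, never refit
        proj = pca_fit.project(sub_lc[:, unknown])
        rows += [
            {"sample_id": filtered.sample_ids[j], "group": "U",
             "PC1": sc[0], "PC2": sc[1], "projected": True}
            for j, sc in zip(unknown, proj)
        ]
    pca_scores = pd.DataFrame(rows)

    D = leading_logfc_distance(lc, top_k=min(mds_top_k, lc.shape[0]))
    coords = classical_mds(D)
    mds_coords = pd.DataFrame(
        {"sample_id": filtered.sample_ids, "group": [s.group for s in ordered],
         "dim1": coords[:, 0], "dim2": coords[:, 1]}
    )

    rf_report = None
    unknown_df = None
    if rf_config is not None and signature:
        feats, labels, known_ids, u_feats, u_ids, dropped, missing = build_feature_matrix(
            lc, filtered.exon_ids, signature, ordered
        )
        if len(set(labels)) >= 2:
            rf_report = train_eval_split(feats, labels, rf_config)
            rf_report.dropped_samples = dropped
            rf_report.missing_features = missing
            if len(u_ids):
                probs, classes, assigned, near_tie = classify_unknowns(
                    feats, labels, u_feats, rf_config
                )
                unknown_df = pd.DataFrame(probs, columns=[f"P_{c}" for c in classes])
                unknown_df.insert(0, "sample_id", u_ids)
                unknown_df["assigned"] = assigned
                unknown_df["near_tie"] = near_tie

    genes = None
    enrichment = None
    if catalog is not None and signature:
        genes = map_exons_to_genes(signature, catalog)
        if gene_sets:
            universe = catalog.genes_of(filtered.exon_ids)
            enrichment = ora_test(genes & universe, gene_sets, universe)

    summary = {
        "version": __version__,
        "seed": seed,
        "fdr_threshold": fdr_threshold,
        "n_exons_input": matrix.n_exons,
        "n_exons_tested": filtered.n_exons,
        "n_samples": matrix.n_samples,
        "comparisons": {
            c: {
                "n_dpe": len(r.calls.exon_ids),
                "direction_counts": r.calls.direction_counts(),
            }
            for c, r in results.items()
        },
        "signature_size": len(signature),
        "n_signature_genes": len(genes) if genes is not None else None,
        "venn": venn,
    }
    if rf_report is not None:
        summary["random_forest"] = {
            "oob_error": rf_report.oob_error,
            "test_accuracy": rf_report.test_accuracy,
        }
    return StudyResult(
        comparisons=results,
        signature=signature,
        venn=venn,
        genes=genes,
        logcpm=lc,
        filtered=filtered,
        factors=factors,
        linkage=tree,
        pca_scores=pca_scores,
        mds_coords=mds_coords,
        rf_report=rf_report,
        unknown_assignments=unknown_df,
        enrichment=enrichment,
        summary=summary,
    )


def write_study_outputs(result: StudyResult, out_dir: str | Path) -> list[Path]:
    """Write all study artifacts as TSV/JSON files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(path: Path) -> Path:
        written.append(path)
        return path

    for cmp_, res in result.comparisons.items():
        res.table().to_csv(_w(out / f"dpe_{cmp_}.tsv"), sep="\t", index=False,
                           float_format="%.10g")
    (_w(out / "signature.txt")).write_text("\n".join(sorted(result.signature)) + "\n")
    pd.DataFrame(
        sorted(result.venn.items()), columns=["region", "n_exons"]
    ).to_csv(_w(out / "venn_counts.tsv"), sep="\t", index=False)
    lk = pd.DataFrame(result.linkage.merges, columns=["node_a", "node_b", "height", "size"])
    lk.to_csv(_w(out / "linkage.tsv"), sep="\t", index=False, float_format="%.10g")
    result.pca_scores.to_csv(_w(out / "pca_scores.tsv"), sep="\t", index=False,
                             float_format="%.10g")
    result.mds_coords.to_csv(_w(out / "mds.tsv"), sep="\t", index=False, float_format="%.10g")
    if result.genes is not None:
        (_w(out / "signature_genes.txt")).write_text("\n".join(sorted(result.genes)) + "\n")
    if result.rf_report is not None:
        rf = result.rf_report.to_dict()
        if result.unknown_assignments is not None:
            rf["unknown_assignments"] = result.unknown_assignments.round(6).to_dict("records")
        (_w(out / "rf_report.json")).write_text(json.dumps(rf, indent=2, default=_jsonable) + "\n")
    if result.enrichment is not None:
        result.enrichment.to_csv(_w(out / "enrich.tsv"), sep="\t", index=False,
                                 float_format="%.10g")
    (_w(out / "summary.json")).write_text(
        json.dumps(result.summary, indent=2, default=_jsonable, sort_keys=True) + "\n"
    )
    return written


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
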