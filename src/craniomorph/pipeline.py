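"""End-to-end orchestration of the two cranial-shape analyses.

* **affinity** — fossils only: impute missing landmarks, symmetrize, GPA,
  outlier screen, PCA, retain 15 PCs, between-group PCA (3 merged groups
  and 5 regional groups) with leave-one-out cross-validation, pairwise
  Mahalanobis / Procrustes / Euclidean distance tables with permutation
  p-values, allometry scan, centroid-size summary.
* **variance** — MUP + LUP fossils plus four extant comparison groups
  (EUP excluded: n = 4): GPA, PCA, retain 6 PCs, pairwise covariance
  proportionality tests and generalized-variance ratios, with and without
  a configured outlier exclusion.

Both analyses share the imputation/alignment/ordination code paths.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .dataset import Dataset
from .geometry import impute_missing
from .group_stats import (allometry_scan, mean_shape_deviation,
                          no_significant_allometry, permutation_test)
from .io import read_dataset, sex_ratio
from .ordination import bgpca, bgpca_cv, confidence_ellipse, pca, retain_components
from .scheme import EXTANT_GROUPS, FOSSIL_GROUPS
from .superimpose import gpa, screen_outliers, symmetrize_dataset
from .vcv import variance_comparison_table

DEFAULT_MERGES = {"MUPswf": "MUP", "MUPmor": "MUP",
                  "LUPswf": "LUP", "LUPita": "LUP"}


@dataclass
class RunConfig:
    """Configuration of a pipeline run; every under-specified methodological
    switch is an explicit key with its default."""
    analysis: str = "both"              # affinity | variance | both
    input_path: Optional[str] = None    # None -> synthetic replay of the design
    merges: dict = field(default_factory=lambda: dict(DEFAULT_MERGES))
    exclude_outlier: str = "DV3"        # variance analysis re-run without it
    exclude_groups_variance: tuple = ("EUP",)
    n_permutations: int = 10000
    affinity_pcs: int = 15
    variance_pcs: int = 6
    seed: int = 42
    max_missing: float = 0.5
    tangent_projection: bool = True
    bgpca_weighted: bool = True
    covariance_ddof: int = 1
    symmetrize: bool = True
    output_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "merges" in raw and raw["merges"] is not None:
            raw["merges"] = dict(raw["merges"])
        if "exclude_groups_variance" in raw:
            raw["exclude_groups_variance"] = tuple(raw["exclude_groups_variance"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_input(config: RunConfig) -> Dataset:
    if config.input_path is None:
        from .simulate import replay_study_design
        dataset, _ = replay_study_design(seed=config.seed)
        return dataset
    path = Path(config.input_path)
    fmt = {".csv": "csv", ".tps": "tps", ".xlsx": "xlsx"}.get(path.suffix.lower(), "csv")
    return read_dataset(path, format=fmt)


def _prepare(dataset: Dataset, config: RunConfig):
    """Shared impute -> symmetrize -> GPA front end."""
    completed = impute_missing(dataset, max_missing=config.max_missing)
    if config.symmetrize:
        completed = symmetrize_dataset(completed)
    return gpa(completed, tangent=config.tangent_projection)


def run_affinity(config: RunConfig, dataset: Optional[Dataset] = None) -> dict:
    """Run the fossil morphological-affinity analysis; returns a report dict."""
    dataset = (dataset or _load_input(config)).subset(groups=FOSSIL_GROUPS)
    aligned = _prepare(dataset, config)
    labels5 = aligned.labels
    merged = np.array([config.merges.get(g, g) for g in labels5])

    report: dict = {"kind": "affinity", "n": aligned.n}
    report["sex_ratio_pct"] = sex_ratio(dataset)
    report["outliers_whole"] = screen_outliers(aligned, "whole-sample")
    report["outliers_per_group"] = screen_outliers(aligned, "per-group")
    # per merged group screen (the published check is within MUP)
    mup_idx = merged == "MUP"
    report["mup_outlier_ranking"] = None
    if mup_idx.sum() >= 3:
        import dataclasses
        sub = dataclasses.replace(
            aligned, shapes=aligned.shapes[mup_idx],
            centroid_sizes=aligned.centroid_sizes[mup_idx],
            consensus=aligned.shapes[mup_idx].mean(axis=0),
            labels=merged[mup_idx],
            specimen_ids=[s for s, m in zip(aligned.specimen_ids, mup_idx) if m])
        scr = screen_outliers(sub, "whole-sample")
        report["mup_outlier_ranking"] = scr.sort_values("distance", ascending=False)

    ordination = pca(aligned)
    report["pca_variance_fractions"] = ordination.variance_fractions
    report["pc12_share_pct"] = float(ordination.variance_fractions[:2].sum() * 100)
    report["pc123_share_pct"] = float(ordination.variance_fractions[:3].sum() * 100)
    kept = retain_components(ordination, min(config.affinity_pcs,
                                             ordination.n_components))
    report["retained_share_pct"] = float(kept.retained_fraction * 100)

    for tag, labels in (("3group", merged), ("5group", labels5)):
        bg = bgpca(kept.scores, labels, weighted=config.bgpca_weighted)
        report[f"bgpca_{tag}"] = bg
        report[f"bgpca_{tag}_fractions_pct"] = bg.variance_fractions * 100
        report[f"bgpca_{tag}_cv"] = bgpca_cv(kept.scores, labels,
                                             weighted=config.bgpca_weighted)
        if bg.n_components >= 2:
            report[f"bgpca_{tag}_ellipses"] = confidence_ellipse(
                bg.scores[:, :2], labels, level=0.90)

    seeds = iter(np.random.SeedSequence(config.seed).generate_state(12).tolist())
    for tag, labels in (("3group", merged), ("5group", labels5)):
        order = [g for g in dict.fromkeys(labels)]
        report[f"mahalanobis_{tag}"] = permutation_test(
            kept.scores, labels, "mahalanobis",
            n_rounds=config.n_permutations, seed=next(seeds), groups=order)
        report[f"procrustes_{tag}"] = permutation_test(
            aligned.shapes, labels, "procrustes",
            n_rounds=config.n_permutations, seed=next(seeds), groups=order)
        report[f"euclidean_{tag}"] = permutation_test(
            kept.scores, labels, "euclidean", pc_count=kept.n_components,
            n_rounds=config.n_permutations, seed=next(seeds), groups=order)

    fits = allometry_scan(kept.scores, aligned.centroid_sizes,
                          sex_labels=aligned.sexes, strata=True)
    report["allometry"] = fits
    report["no_significant_allometry"] = no_significant_allometry(fits)

    cs = pd.DataFrame({"group": labels5, "centroid_size": aligned.centroid_sizes})
    report["centroid_size_summary"] = cs.groupby("group")["centroid_size"].describe()

    # per-landmark deviation fields: each merged group mean vs overall mean
    grand = aligned.consensus
    fields = {}
    for g in dict.fromkeys(merged):
        gm = aligned.shapes[merged == g].mean(axis=0)
        vec, mag = mean_shape_deviation(grand, gm)
        fields[g] = mag
    report["mean_shape_deviation_magnitudes"] = pd.DataFrame(fields)
    report["aligned"] = aligned
    report["manifest"] = _manifest(config)
    return report


def run_variance(config: RunConfig, dataset: Optional[Dataset] = None) -> dict:
    """Run the within-group variance analysis; returns a report dict."""
    dataset = dataset or _load_input(config)
    keep_groups = [g for g in FOSSIL_GROUPS + EXTANT_GROUPS
                   if g not in config.exclude_groups_variance]
    dataset = dataset.subset(groups=keep_groups)
    aligned = _prepare(dataset, config)
    merged = np.array([config.merges.get(g, g) for g in aligned.labels])

    report: dict = {"kind": "variance", "n": aligned.n}
    ordination = pca(aligned)
    report["pc123_share_pct"] = float(ordination.variance_fractions[:3].sum() * 100)
    kept = retain_components(ordination, min(config.variance_pcs,
                                             ordination.n_components))
    report["retained_share_pct"] = float(kept.retained_fraction * 100)

    fits = allometry_scan(kept.scores, aligned.centroid_sizes)
    report["no_significant_allometry"] = no_significant_allometry(fits)

    order = [g for g in ("AmNat", "EuS", "Inuit", "OcPap", "MUP", "LUP")
             if g in set(merged)]
    report["vcv_full"] = variance_comparison_table(
        kept.scores, merged, specimen_ids=aligned.specimen_ids,
        groups=order, ddof=config.covariance_ddof)
    if config.exclude_outlier and config.exclude_outlier in aligned.specimen_ids:
        report["vcv_excluded"] = variance_comparison_table(
            kept.scores, merged, specimen_ids=aligned.specimen_ids,
            exclude=[config.exclude_outlier], groups=order,
            ddof=config.covariance_ddof)
    else:
        report["vcv_excluded"] = None
    report["outliers_per_group"] = screen_outliers(aligned, "per-group")
    report["aligned"] = aligned
    report["manifest"] = _manifest(config)
    return report


def run(config: RunConfig) -> dict:
    """Run the configured analysis (or both); optionally write tables."""
    dataset = _load_input(config)
    reports = {}
    if config.analysis in ("affinity", "both"):
        reports["affinity"] = run_affinity(config, dataset)
    if config.analysis in ("variance", "both"):
        reports["variance"] = run_variance(config, dataset)
    if config.output_dir:
        write_reports(reports, config.output_dir)
    return reports


def _manifest(config: RunConfig) -> dict:
    return {"config": asdict(config), "config_hash": config.digest(),
            "seed": config.seed,
            "decisions": {
                "procrustes_distance": "partial (unit-size, no pairwise rescale)",
                "rotation": "proper only (det +1)",
                "semilandmark_sliding": "none",
                "bgpca_weighting": "by group size" if config.bgpca_weighted else "unweighted",
                "mahalanobis": "pooled covariance, Moore-Penrose pseudo-inverse",
                "covariance_denominator": f"n-{config.covariance_ddof}",
                "tangent_projection": config.tangent_projection,
            }}


def write_reports(reports: dict, output_dir) -> None:
    """Emit TSV tables and a JSON manifest; same config + seed gives
    bit-identical files."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for kind, rep in reports.items():
        for key, val in rep.items():
            if key in ("aligned", "manifest"):
                continue
            path = out / f"{kind}_{key}.tsv"
            if isinstance(val, pd.DataFrame):
                val.to_csv(path, sep="\t", float_format="%.10g")
            elif hasattr(val, "frame"):  # DistanceTable
                val.frame().to_csv(path, sep="\t", float_format="%.10g")
                pf = val.p_frame()
                if pf is not None:
                    pf.to_csv(out / f"{kind}_{key}_p.tsv", sep="\t",
                              float_format="%.10g")
            elif hasattr(val, "ratio_frame"):  # VarianceComparisonTable
                val.prop_p_frame().to_csv(out / f"{kind}_{key}_proptest.tsv",
                                          sep="\t", float_format="%.10g")
                val.ratio_frame().to_csv(out / f"{kind}_{key}_ratios.tsv",
                                         sep="\t", float_format="%.10g")
        (out / f"{kind}_manifest.json").write_text(
            json.dumps(rep["manifest"], indent=2, sort_keys=True, default=str))
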