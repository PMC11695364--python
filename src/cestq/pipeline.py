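"""End-to-end orchestration: simulate → preprocess → fit → metrics → stats.

One seeded configuration drives a full synthetic-cohort analysis: phantom
slices per subject, the 4-step quantification chain per voxel, tumor-ROI
histogram features per subject, and the group-comparison / ROC / combined-
model workflow across subjects. Every run directory carries provenance
(config hash, package versions, seed).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .core import normalize_to_zspectrum
from .lorentzian import FitOptions, MetricMaps, fit_voxelwise_pipeline
from .metrics import extract_histogram_features, features_to_records, mtr_asym, ph_weighted_map
from .phantom import CohortConfig, PhantomConfig, PhantomResult, SubjectData, generate_cohort
from .preprocess import apply_b0_correction, denoise_mlsvd, estimate_b0_spline_minimum, estimate_b0_two_pool, register_subpixel
from .stats import compare_feature, fit_combined_model, format_roc_row, roc_analysis

__all__ = ["PipelineConfig", "process_subject", "subject_feature_table",
           "cohort_analysis", "run_pipeline"]

METRIC_NAMES = ("amide", "amine", "noe", "mt", "ds", "mtr35", "ph_weighted")
FEATURE_COLS = ("mean", "median", "p10", "p25", "p75", "p90")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated top-level configuration (unknown keys rejected)."""

    seed: int = 0
    phantom: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    register: bool = False
    denoise: bool = True
    b0_method: str = "two_pool"
    fit_method: str = "sequential"
    roi_label: str = "tumor"
    alpha: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if d.get("b0_method", "two_pool") not in ("two_pool", "spline"):
            raise ValueError("b0_method must be 'two_pool' or 'spline'")
        return cls(**d)


def _nested_phantom(cfg: PipelineConfig, seed: int) -> PhantomConfig:
    return PhantomConfig(**{**cfg.phantom, "seed": seed})


def process_subject(phantom: PhantomResult,
                    fit_options: FitOptions | None = None,
                    register: bool = False,
                    denoise: bool = True,
                    b0_method: str = "two_pool",
                    fit_method: str = "sequential",
                    ) -> tuple[MetricMaps, dict[str, np.ndarray]]:
    """The 4-step quantification chain for one subject.

    (1) optional motion correction and MLSVD denoising of the raw stack,
    (2) normalization and 2-pool B0 estimation + correction, (3)–(4)
    voxelwise background / Lorentzian-difference / 3-pool fits. Returns the
    fit result and the seven metric maps (pool amplitudes, MTR_3.5,
    pH-weighted), with non-converged voxels set to NaN everywhere.
    """
    stack = phantom.stack
    if register:
        stack, _ = register_subpixel(stack, phantom.schedule.reference_index)
    if denoise:
        stack = denoise_mlsvd(stack)
    zspec = normalize_to_zspectrum(stack, None, phantom.schedule,
                                   mask=phantom.mask)
    if b0_method == "two_pool":
        b0 = estimate_b0_two_pool(zspec, fit_options)
    elif b0_method == "spline":
        b0 = estimate_b0_spline_minimum(zspec)
    else:
        raise ValueError(f"unknown b0_method {b0_method!r}")
    corrected = apply_b0_correction(zspec, b0)
    result = fit_voxelwise_pipeline(corrected, fit_options, method=fit_method)
    valid = result.valid_mask()
    maps = dict(result.maps)
    maps["mtr35"] = mtr_asym(corrected, 3.5)
    maps["ph_weighted"] = ph_weighted_map(corrected)
    for k in maps:
        m = maps[k].copy()
        m[~valid] = np.nan
        maps[k] = m
    return result, maps


def subject_feature_table(subjects: list[SubjectData],
                          cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Run the quantification chain per subject and tabulate ROI features."""
    cfg = cfg or PipelineConfig()
    rows: list[dict] = []
    for s in subjects:
        if s.phantom is None:
            raise ValueError("subject has no image data (images=False cohort)")
        _, maps = process_subject(s.phantom, register=cfg.register,
                                  denoise=cfg.denoise, b0_method=cfg.b0_method,
                                  fit_method=cfg.fit_method)
        roi = s.phantom.masks[cfg.roi_label]
        feats = [extract_histogram_features(maps[m], roi, metric=m)
                 for m in METRIC_NAMES]
        rows += features_to_records(s.subject_id, s.group, feats)
    return pd.DataFrame(rows)


def _wide(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    wide = table.pivot_table(index=["subject_id", "group"], columns="metric",
                             values=list(FEATURE_COLS))
    wide.columns = [f"{m}_{f}" for f, m in wide.columns]
    wide = wide.reset_index()
    return wide.drop(columns=["subject_id", "group"]), wide["group"]


def cohort_analysis(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """The grading/genotyping statistical workflow on a feature table.

    Per feature column: normality-dependent two-group comparison. Features
    significant at ``alpha`` are ranked by ROC AUC; the best feature per
    metric enters the collinearity screen and the combined logistic model,
    whose apparent ROC is reported alongside the per-feature rows.
    """
    X, groups = _wide(table)
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValueError("cohort analysis needs exactly two groups")
    y = (groups == names[1]).astype(int).to_numpy()
    comparisons, roc_rows = [], {}
    for col in X.columns:
        a = X[col][y == 0].to_numpy()
        b = X[col][y == 1].to_numpy()
        cmp_ = compare_feature(a, b, feature=col)
        comparisons.append({"feature": col, "test": cmp_.test,
                            "p_value": cmp_.p_value,
                            names[0]: cmp_.summary_a, names[1]: cmp_.summary_b})
        if cmp_.p_value < alpha:
            roc_rows[col] = roc_analysis(X[col].to_numpy(), y)
    comp_df = pd.DataFrame(comparisons)

    best_per_metric: dict[str, str] = {}
    for col, roc in roc_rows.items():
        metric = col.rsplit("_", 1)[0]
        if metric not in best_per_metric or \
                roc.auc > roc_rows[best_per_metric[metric]].auc:
            best_per_metric[metric] = col
    selected = sorted(best_per_metric.values())
    out = {
        "groups": names,
        "comparisons": comp_df,
        "roc": pd.DataFrame([format_roc_row(c, roc_rows[c]) for c in roc_rows]),
        "selected_features": selected,
        "combined": None,
        "combined_auc": None,
    }
    if len(selected) >= 1 and len(y) > len(selected) + 1:
        model, roc = fit_combined_model(X[selected], y)
        out["combined"] = {"retained": model.features,
                           "coefficients": model.coefficients.tolist(),
                           "intercept": model.intercept,
                           "fallback": model.separation_fallback,
                           **format_roc_row("combination", roc)}
        out["combined_auc"] = roc.auc
    return out


def run_pipeline(config: PipelineConfig | dict, out_dir) -> dict:
    """Full seeded run; writes features, stats tables and provenance.

    Deterministic given the config (which includes the seed). Stage
    failures leave partial outputs in place and re-raise.
    """
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(asdict(config), sort_keys=True)
    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]

    cohort_cfg = CohortConfig(**{**config.cohort, "seed": config.seed})
    phantom_cfg = _nested_phantom(config, config.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        subjects = generate_cohort(cohort_cfg, phantom_cfg)
        table = subject_feature_table(subjects, config)
        table.to_csv(out / "features.csv", index=False)
        analysis = cohort_analysis(table, alpha=config.alpha)
    analysis["comparisons"].to_csv(out / "comparisons.csv", index=False)
    analysis["roc"].to_csv(out / "roc.csv", index=False)

    import cestq
    results = {
        "seed": config.seed,
        "config_hash": cfg_hash,
        "version": cestq.__version__,
        "n_subjects": len(subjects),
        "groups": analysis["groups"],
        "selected_features": analysis["selected_features"],
        "combined": analysis["combined"],
        "combined_auc": analysis["combined_auc"],
        "outputs": {},
    }
    for f in ("features.csv", "comparisons.csv", "roc.csv"):
        results["outputs"][f] = hashlib.sha256((out / f).read_bytes()).hexdigest()[:16]
    (out / "results.json").write_text(json.dumps(results, indent=1))
    return results
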