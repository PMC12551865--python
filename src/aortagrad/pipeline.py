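"""End-to-end orchestration: masks -> centerline -> profile -> statistics.

``run_imaging`` processes a batch of patients (real NIfTI volume/mask
triples or phantom specifications), writing per-patient intermediates
(landmarks JSON, centerline CSV, profile CSV and plot) and one parameter
row per patient.  Failures are isolated: a patient that cannot be
processed is logged and skipped, the batch continues.

``run_stats`` joins the imaging parameters with a cohort table and runs
the full statistical analysis: confounder scan, per-outcome Firth forward
selection with BH-FDR over the selected predictors, diagnostic metrics of
the gradient model against the binary clinical markers, nested PLR
comparisons and ROC points.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, profile as prof, stats, synthetic
from .synthetic import CONFOUNDER_NAMES, OUTCOME_NAMES, PARAMETER_NAMES
from .volume import load_mask, load_volume

__all__ = ["RunConfig", "run_imaging", "run_stats", "analyze_patient"]

logger = logging.getLogger("aortagrad")


@dataclass
class RunConfig:
    roi_fraction: float = 0.5
    step_mm: float = 1.0
    plane_halfwidth_mm: float = 20.0
    min_area_mm2: float = 25.0
    alpha_entry: float = 0.05
    rescale_units: float = 10.0
    cutoff: float = 0.5
    seed: int = 0
    outcomes: list[str] = field(default_factory=lambda: list(OUTCOME_NAMES))

    def validate(self) -> None:
        if not 0 < self.roi_fraction <= 1:
            raise ValueError("roi_fraction must lie in (0, 1]")
        if self.step_mm <= 0 or self.plane_halfwidth_mm <= 0:
            raise ValueError("step_mm and plane_halfwidth_mm must be positive")
        if not 0 < self.alpha_entry <= 1:
            raise ValueError("alpha_entry must lie in (0, 1]")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = cls(**json.load(fh))
        cfg.validate()
        return cfg


def analyze_patient(volume, aorta_mask, lung_mask, config: RunConfig | None = None):
    """Full imaging chain for one patient.

    Returns (AortaParameters, dict of intermediates: landmarks, centerline,
    dimensions, stack, profile).
    """
    config = config or RunConfig()
    thoracic, landmarks = geometry.detect_landmarks(
        aorta_mask, lung_mask, min_area_mm2=config.min_area_mm2
    )
    centerline = geometry.extract_centerline(thoracic, landmarks, step_mm=config.step_mm)
    dims = geometry.measure_dimensions(thoracic, lung_mask, centerline)
    stack = prof.straighten(
        volume, centerline, plane_halfwidth_mm=config.plane_halfwidth_mm, mask=thoracic
    )
    intensity_profile = prof.profile_from_stack(stack, roi_fraction=config.roi_fraction)
    params = prof.fit_parameters(intensity_profile)
    return params, {
        "landmarks": landmarks,
        "centerline": centerline,
        "dimensions": dims,
        "stack": stack,
        "profile": intensity_profile,
    }


def _load_case(entry: dict):
    """A manifest entry is either file paths or an inline phantom spec."""
    if "phantom" in entry:
        spec = synthetic.PhantomSpec(**entry["phantom"])
        volume, aorta, lung, _ = synthetic.generate_phantom(spec)
        return volume, aorta, lung
    return (
        load_volume(entry["volume"]),
        load_mask(entry["aorta_mask"]),
        load_mask(entry["lung_mask"]),
    )


def _plot_profile(intensity_profile, params, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    s = intensity_profile.s_pct
    ax.plot(s, intensity_profile.intensity_hu, lw=0.8, label="ROI mean")
    ax.plot(
        s,
        params.proximal_intensity_hu + params.contrast_gradient_hu_per_pct * s,
        "r--",
        label=(
            f"fit: {params.proximal_intensity_hu:.0f} "
            f"{params.contrast_gradient_hu_per_pct:+.2f}*s"
        ),
    )
    ax.set_xlabel("position along thoracic aorta (%)")
    ax.set_ylabel("intensity (HU)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_imaging(manifest: list[dict], out_dir, config: RunConfig | None = None) -> pd.DataFrame:
    """Process a batch of patients and write the parameters table.

    ``manifest`` holds one dict per patient with a ``patient_id`` and either
    NIfTI paths (``volume``, ``aorta_mask``, ``lung_mask``) or an inline
    ``phantom`` spec.  Returns the parameters DataFrame (also written to
    ``parameters.csv``); failed patients appear in ``failures.json``.
    """
    if not manifest:
        raise ValueError("empty manifest")
    config = config or RunConfig()
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, failures = [], {}
    for entry in manifest:
        pid = str(entry["patient_id"])
        pdir = out_dir / pid
        try:
            volume, aorta, lung = _load_case(entry)
            params, inter = analyze_patient(volume, aorta, lung, config)
            pdir.mkdir(exist_ok=True)
            inter["landmarks"].to_json(pdir / "landmarks.json")
            inter["centerline"].to_csv(pdir / "centerline.csv")
            inter["profile"].to_csv(pdir / "profile.csv")
            inter["dimensions"].to_json(pdir / "dimensions.json")
            _plot_profile(inter["profile"], params, pdir / "profile.png")
            dims = inter["dimensions"]
            rows.append(
                {
                    "patient_id": pid,
                    "mean_intensity": params.mean_intensity_hu,
                    "proximal_intensity": params.proximal_intensity_hu,
                    "contrast_gradient": params.contrast_gradient_hu_per_pct,
                    "contrast_gradient_per10": params.contrast_gradient_per10,
                    "aorta_length_mm": dims.length_mm,
                    "aorta_volume_ml": dims.volume_ml,
                    "aorta_diameter_mm": dims.mean_diameter_mm,
                    "lung_volume_l": dims.lung_volume_l,
                }
            )
        except Exception as exc:  # noqa: BLE001 - batch isolation by design
            logger.warning("patient %s failed: %s", pid, exc)
            failures[pid] = str(exc)
    columns = [
        "patient_id",
        "mean_intensity",
        "proximal_intensity",
        "contrast_gradient",
        "contrast_gradient_per10",
        "aorta_length_mm",
        "aorta_volume_ml",
        "aorta_diameter_mm",
        "lung_volume_l",
    ]
    table = pd.DataFrame(rows, columns=columns)
    table.to_csv(out_dir / "parameters.csv", index=False, float_format="%.6f")
    with open(out_dir / "failures.json", "w") as fh:
        json.dump(failures, fh, indent=1)
    return table


def run_stats(
    parameters: pd.DataFrame,
    cohort: pd.DataFrame,
    out_dir,
    config: RunConfig | None = None,
) -> dict:
    """Full statistical analysis; writes the report bundle and returns it.

    The tables mirror the conventional reporting layout: a confounder
    regression table, a per-outcome model table (beta, OR with CI, Wald p,
    FDR-adjusted p, model chi-square), a diagnostic-metrics table comparing
    the gradient model with hemodynamic instability and RV/LV > 1, nested
    PLR comparisons of gradient vs RV/LV models, ROC points, and logistic
    regressions of each binary marker on the gradient.
    """
    config = config or RunConfig()
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if "patient_id" in parameters.columns and "patient_id" in cohort.columns:
        overlap = [
            c for c in parameters.columns if c != "patient_id" and c in cohort.columns
        ]
        merged = parameters.merge(
            cohort.drop(columns=overlap), on="patient_id", how="inner"
        )
    else:
        merged = cohort.copy()
    if len(merged) == 0:
        raise ValueError("join of parameters and cohort produced 0 rows")

    confounders = [c for c in CONFOUNDER_NAMES if c in merged.columns]
    scan = stats.confounder_scan(merged, PARAMETER_NAMES, confounders)
    scan.to_csv(out_dir / "confounder_table.csv", index=False)
    covariates = stats.flagged_confounders(scan)

    outcomes = [o for o in config.outcomes if o in merged.columns]
    selections: dict[str, stats.SelectionResult] = {}
    skipped: dict[str, str] = {}
    for outcome in outcomes:
        y = merged[outcome].dropna()
        if len(y) == 0 or y.nunique() < 2:
            skipped[outcome] = "outcome missing or constant after list-wise exclusion"
            continue
        selections[outcome] = stats.forward_select(
            merged, outcome, PARAMETER_NAMES + covariates, alpha_entry=config.alpha_entry
        )

    # BH FDR across the family of selected-predictor Wald p-values of this run
    family = [
        (outcome, term, p)
        for outcome, sel in selections.items()
        for term, p in sel.selected_wald_p().items()
    ]
    if family:
        adjusted = stats.bh_fdr([p for _, _, p in family])
        for (outcome, term, _), q in zip(family, adjusted):
            selections[outcome].fdr_adjusted_p[term] = float(q)

    model_rows = []
    for outcome, sel in selections.items():
        table = stats.or_from_beta(sel.final_fit)
        for _, row in table.iterrows():
            rescale = config.rescale_units if row["term"] == "contrast_gradient" else 1.0
            rr = stats.or_from_beta(sel.final_fit, rescale).set_index("term").loc[row["term"]]
            model_rows.append(
                {
                    "outcome": outcome,
                    "n": sel.n_used,
                    "term": row["term"],
                    "beta": rr["beta_rescaled"],
                    "or": rr["or"],
                    "or_ci_low": rr["or_ci_low"],
                    "or_ci_high": rr["or_ci_high"],
                    "p": rr["p_wald"],
                    "p_adjusted": sel.fdr_adjusted_p.get(row["term"], np.nan),
                    "model_chi2": sel.model_chi2,
                    "model_p": sel.model_p,
                }
            )
        for cand, p in sel.excluded_entry_p.items():
            model_rows.append(
                {
                    "outcome": outcome,
                    "n": sel.n_used,
                    "term": f"{cand} (not selected)",
                    "beta": np.nan,
                    "or": np.nan,
                    "or_ci_low": np.nan,
                    "or_ci_high": np.nan,
                    "p": p,
                    "p_adjusted": np.nan,
                    "model_chi2": sel.model_chi2,
                    "model_p": sel.model_p,
                }
            )
    model_table = pd.DataFrame(model_rows)
    model_table.to_csv(out_dir / "model_table.csv", index=False)

    # Diagnostic metrics: gradient model at the probability cutoff vs the
    # binary clinical markers, for outcomes where the gradient was selected.
    metric_rows, plr_rows, roc_store = [], [], {}
    markers = [m for m in ("hemodynamic_instability", "rvlv_gt1") if m in merged.columns]
    for outcome, sel in selections.items():
        if "contrast_gradient" not in sel.selected:
            continue
        sub = merged[[outcome, "contrast_gradient"] + markers].dropna()
        y = sub[outcome].to_numpy(float)
        fit_g = stats.firth_fit(
            sub[["contrast_gradient"]].to_numpy(), y, names=["contrast_gradient"]
        )
        dm = stats.model_metrics_at_cutoff(fit_g, cutoff=config.cutoff)
        metric_rows.append(
            {"outcome": outcome, "predictor": "contrast_gradient", **dm.__dict__}
        )
        roc_store[outcome] = stats.roc_points(fit_g)
        for marker in markers:
            if sub[marker].nunique() < 2:
                continue
            dm = stats.crosstab_metrics(sub[marker].to_numpy(), y)
            metric_rows.append({"outcome": outcome, "predictor": marker, **dm.__dict__})
        if "rvlv_gt1" in sub.columns and sub["rvlv_gt1"].nunique() > 1:
            fit_r = stats.firth_fit(sub[["rvlv_gt1"]].to_numpy(), y, names=["rvlv_gt1"])
            fit_b = stats.firth_fit(
                sub[["contrast_gradient", "rvlv_gt1"]].to_numpy(),
                y,
                names=["contrast_gradient", "rvlv_gt1"],
            )
            for label, full, reduced in (
                ("both_vs_rvlv_only", fit_b, fit_r),
                ("both_vs_gradient_only", fit_b, fit_g),
            ):
                stat, p = stats.plr_test(full, reduced)
                plr_rows.append(
                    {"outcome": outcome, "comparison": label, "chi2": stat, "p": p}
                )

    pd.DataFrame(metric_rows).to_csv(out_dir / "metrics_table.csv", index=False)
    pd.DataFrame(plr_rows).to_csv(out_dir / "plr_comparisons.csv", index=False)
    for outcome, pts in roc_store.items():
        pd.DataFrame(pts, columns=["fpr", "sensitivity"]).to_csv(
            out_dir / f"roc_{outcome}.csv", index=False
        )

    # Marker-versus-gradient logistic regressions.
    marker_rows = []
    for marker in markers:
        sub = merged[[marker, "contrast_gradient"]].dropna()
        if sub[marker].nunique() < 2:
            continue
        fit = stats.firth_fit(
            sub[["contrast_gradient"]].to_numpy(),
            sub[marker].to_numpy(float),
            names=["contrast_gradient"],
        )
        row = stats.or_from_beta(fit, config.rescale_units).set_index("term").loc[
            "contrast_gradient"
        ]
        marker_rows.append({"marker": marker, **row.to_dict()})
    pd.DataFrame(marker_rows).to_csv(out_dir / "marker_regressions.csv", index=False)

    trace = {
        outcome: {
            "n_used": sel.n_used,
            "selected": sel.selected,
            "entry_trace": sel.entry_trace,
            "excluded_entry_p": sel.excluded_entry_p,
            "model_chi2": sel.model_chi2,
            "model_p": sel.model_p,
            "fdr_adjusted_p": sel.fdr_adjusted_p,
        }
        for outcome, sel in selections.items()
    }
    trace["_skipped"] = skipped
    trace["_covariates"] = covariates
    with open(out_dir / "selection_trace.json", "w") as fh:
        json.dump(trace, fh, indent=1, default=float)

    return {
        "confounder_table": scan,
        "model_table": model_table,
        "metrics_table": pd.DataFrame(metric_rows),
        "plr_comparisons": pd.DataFrame(plr_rows),
        "selections": selections,
        "covariates": covariates,
        "skipped": skipped,
    }
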