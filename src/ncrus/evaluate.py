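"""Prediction aggregation, regression metrics and model comparisons.

Predictions are produced per interpolated sample (seven per physical
measurement); averaging the seven versions yields one value per acquired
measurement. Goodness of fit is summarized by the global RMSE, Pearson's
linear correlation R between predictions and annotated RWC, and the
least-squares line of predictions on true RWC. Model families are compared
by a two-sided paired t-test on per-leaf RMSE, and the seven interpolation
methods by a repeated-measures ANOVA with Bonferroni and Tukey-Kramer
multiple-comparison follow-ups (the expectation being that no method differs:
the augmentation perturbs, it does not bias).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "EvalReport",
    "aggregate_versions",
    "compute_metrics",
    "per_leaf_rmse",
    "compare_models",
    "interpolation_anova",
    "build_report",
    "write_report",
    "plot_report",
]


@dataclass
class EvalReport:
    """Per-sample and per-measurement evaluation summary for one model family."""

    model_tag: str
    per_sample: pd.DataFrame
    per_measurement: pd.DataFrame
    global_rmse: float
    global_pearson_r: float
    regression_line: tuple[float, float]
    per_measurement_rmse: float
    per_measurement_pearson_r: float
    per_leaf_rmse: pd.Series


def aggregate_versions(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Mean prediction over the interpolated versions of each measurement.

    ``per_sample`` needs columns leaf_id, measurement_idx, true_rwc,
    predicted_rwc (and optionally method); returns one row per
    (leaf_id, measurement_idx).
    """
    if per_sample.empty:
        raise ConfigurationError("no predictions to aggregate")
    grouped = (
        per_sample.groupby(["leaf_id", "measurement_idx"], sort=True)
        .agg(true_rwc=("true_rwc", "first"), predicted_rwc=("predicted_rwc", "mean"))
        .reset_index()
    )
    return grouped


def compute_metrics(true: np.ndarray, predicted: np.ndarray
                    ) -> tuple[float, float, float, float]:
    """Global metrics: ``(rmse, pearson_r, slope, intercept)``.

    The regression line is the least-squares fit of predictions on true RWC
    (prediction = slope * RWC + intercept). With a constant truth vector R and
    the line are undefined and returned as NaN.
    """
    t = np.asarray(true, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if t.shape != p.shape or t.size < 3:
        raise ConfigurationError("need equal-length vectors with at least 3 entries")
    rmse = float(np.sqrt(np.mean((p - t) ** 2)))
    if np.all(t == t[0]):
        return rmse, float("nan"), float("nan"), float("nan")
    r = float(stats.pearsonr(t, p).statistic)
    slope, intercept = np.polyfit(t, p, 1)
    return rmse, r, float(slope), float(intercept)


def per_leaf_rmse(per_measurement: pd.DataFrame) -> pd.Series:
    """RMSE computed separately within each leaf."""
    return per_measurement.groupby("leaf_id").apply(
        lambda g: float(np.sqrt(np.mean((g["predicted_rwc"] - g["true_rwc"]) ** 2))),
        include_groups=False,
    )


def compare_models(per_leaf_rmse_a: Sequence[float], per_leaf_rmse_b: Sequence[float]
                   ) -> dict:
    """Two-sided paired t-test on per-leaf RMSE of two model families.

    Returns ``{"t": ..., "p": ..., "mean_difference": ..., "degenerate": ...}``.
    Identical sequences give t = 0, p = 1; a nonzero constant difference has
    zero variance, which makes the statistic undefined — flagged degenerate.
    """
    a = np.asarray(per_leaf_rmse_a, dtype=float)
    b = np.asarray(per_leaf_rmse_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ConfigurationError("need equal-length paired sequences with n >= 3")
    d = a - b
    if np.all(d == 0):
        return {"t": 0.0, "p": 1.0, "mean_difference": 0.0, "degenerate": False}
    # constant nonzero difference: zero variance up to float cancellation
    if np.ptp(d) <= 1e-12 * max(1.0, float(np.max(np.abs(d)))):
        return {"t": float("nan"), "p": float("nan"),
                "mean_difference": float(d.mean()), "degenerate": True}
    res = stats.ttest_rel(a, b)
    return {"t": float(res.statistic), "p": float(res.pvalue),
            "mean_difference": float(d.mean()), "degenerate": False}


def interpolation_anova(errors: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Repeated-measures ANOVA of prediction errors across interpolation methods.

    ``errors`` is a complete matrix: one row per measurement (subject), one
    column per interpolation method, entries the (absolute) prediction errors.
    Performs a one-way repeated-measures ANOVA plus pairwise follow-ups with
    Bonferroni-corrected paired t-tests and a Tukey-Kramer comparison, and
    reports whether any method differs at level ``alpha``.
    """
    if errors.isna().any().any():
        raise ConfigurationError("per-method error matrix must be complete")
    methods = list(errors.columns)
    k = len(methods)
    if k < 2 or len(errors) < 2:
        raise ConfigurationError("need >= 2 methods and >= 2 subjects")

    values = errors.to_numpy(dtype=float)
    if np.allclose(values, values[:, [0]]):
        # all methods agree on every subject: nothing to test
        pairs = [
            {"a": methods[i], "b": methods[j], "p_bonferroni": 1.0, "reject": False}
            for i in range(k) for j in range(i + 1, k)
        ]
        return {"f": 0.0, "p": 1.0, "any_significant": False,
                "bonferroni": pairs, "tukey_reject": [False] * len(pairs)}

    from statsmodels.stats.anova import AnovaRM
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    long = errors.reset_index(names="subject").melt(
        id_vars="subject", var_name="method", value_name="error"
    )
    aov = AnovaRM(long, depvar="error", subject="subject", within=["method"]).fit()
    f = float(aov.anova_table["F Value"].iloc[0])
    p = float(aov.anova_table["Pr > F"].iloc[0])

    n_pairs = k * (k - 1) // 2
    bonferroni = []
    for i in range(k):
        for j in range(i + 1, k):
            res = stats.ttest_rel(values[:, i], values[:, j])
            p_adj = min(1.0, float(res.pvalue) * n_pairs)
            bonferroni.append(
                {"a": methods[i], "b": methods[j], "p_bonferroni": p_adj,
                 "reject": p_adj < alpha}
            )
    tukey = pairwise_tukeyhsd(long["error"], long["method"], alpha=alpha)
    tukey_reject = [bool(r) for r in tukey.reject]
    any_sig = (p < alpha) and (
        any(b["reject"] for b in bonferroni) or any(tukey_reject)
    )
    return {"f": f, "p": p, "any_significant": any_sig,
            "bonferroni": bonferroni, "tukey_reject": tukey_reject}


def build_report(per_sample: pd.DataFrame, model_tag: str) -> EvalReport:
    """Full evaluation of one model family's per-sample predictions."""
    per_meas = aggregate_versions(per_sample)
    rmse, r, slope, intercept = compute_metrics(
        per_sample["true_rwc"].to_numpy(), per_sample["predicted_rwc"].to_numpy()
    )
    m_rmse, m_r, _, _ = compute_metrics(
        per_meas["true_rwc"].to_numpy(), per_meas["predicted_rwc"].to_numpy()
    )
    return EvalReport(
        model_tag=model_tag,
        per_sample=per_sample,
        per_measurement=per_meas,
        global_rmse=rmse,
        global_pearson_r=r,
        regression_line=(slope, intercept),
        per_measurement_rmse=m_rmse,
        per_measurement_pearson_r=m_r,
        per_leaf_rmse=per_leaf_rmse(per_meas),
    )


def write_report(report: EvalReport, out_dir: str | Path) -> None:
    """Serialize an EvalReport to JSON (summary) + CSV (predictions)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = report.model_tag
    report.per_sample.to_csv(out / f"{tag}_per_sample.csv", index=False)
    report.per_measurement.to_csv(out / f"{tag}_per_measurement.csv", index=False)
    summary = {
        "model_tag": tag,
        "global_rmse": report.global_rmse,
        "global_pearson_r": report.global_pearson_r,
        "regression_line": list(report.regression_line),
        "per_measurement_rmse": report.per_measurement_rmse,
        "per_measurement_pearson_r": report.per_measurement_pearson_r,
        "per_leaf_rmse": {str(k): v for k, v in report.per_leaf_rmse.items()},
        "n_samples": int(len(report.per_sample)),
        "n_measurements": int(len(report.per_measurement)),
    }
    (out / f"{tag}_summary.json").write_text(json.dumps(summary, indent=2))


def plot_report(report: EvalReport, out_dir: str | Path) -> None:
    """Scatter of predictions vs truth with the fitted line, plus error histogram."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = report.per_sample["true_rwc"].to_numpy()
    p = report.per_sample["predicted_rwc"].to_numpy()
    slope, intercept = report.regression_line
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(5, 8))
    ax1.plot(t, p, ".", ms=3, alpha=0.4)
    xs = np.linspace(t.min(), t.max(), 10)
    ax1.plot(xs, slope * xs + intercept, "r-",
             label=f"pred = {slope:.4f} RWC + {intercept:.4f}")
    ax1.plot(xs, xs, "k--", label="perfect regression")
    ax1.set_xlabel("measured RWC")
    ax1.set_ylabel("predicted RWC")
    ax1.set_title(f"{report.model_tag}: R = {report.global_pearson_r:.4f}, "
                  f"RMSE = {report.global_rmse:.4f}")
    ax1.legend(fontsize=8)
    ax2.hist(p - t, bins=40)
    ax2.set_xlabel("prediction error")
    ax2.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(out / f"{report.model_tag}_scatter.png", dpi=120)
    plt.close(fig)
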