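"""Postoperative validation: prediction errors and cohort summaries.

The error convention is ``actual − predicted``: a negative error means the
preoperative prediction overestimated the insertion depth.  Summaries follow
the clinical-reporting convention of averaging absolute errors (mean and
sample SD of |error|), with signed means kept alongside so systematic over-
or underestimation stays visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .electrode import ElectrodeSpec, InsertionPrediction
from .models import CochlearGeometry, ModelParams, forward_model, invert_model

__all__ = [
    "ObservedInsertion",
    "ErrorRecord",
    "prediction_error",
    "summarize_errors",
    "cohort_angle_summary",
    "exceedance_report",
]


@dataclass(frozen=True)
class ObservedInsertion:
    """One postoperative angular reading at a named reference point."""

    subject_id: str
    observer: int
    angular_actual: float
    reference: str = "c1"  # 'c1' or 'tip'
    observation: int = 1

    def __post_init__(self) -> None:
        if self.reference not in ("c1", "tip"):
            raise ValueError(f"reference must be 'c1' or 'tip', got {self.reference!r}")
        if not (0 < self.angular_actual <= 900):
            raise ValueError(
                f"angular depth {self.angular_actual} deg outside (0, 900]"
            )


@dataclass(frozen=True)
class ErrorRecord:
    """Per-subject prediction error (actual − predicted), angular and linear."""

    subject_id: str
    model: str
    angular_error: float
    linear_error: float
    angular_actual: float
    angular_predicted: float
    linear_actual: float
    linear_predicted: float


def prediction_error(
    pred: InsertionPrediction,
    obs: ObservedInsertion,
    geom: CochlearGeometry,
    spec: ElectrodeSpec,
    params: ModelParams = ModelParams(),
    at: str = "c1",
) -> ErrorRecord:
    """Error record at reference point ``at`` ('c1' or 'tip').

    The observed angle is converted to a linear depth through the same
    model's forward evaluation on the subject's own geometry; if the observed
    reference point differs from ``at``, the conversion goes through the
    linear tip offset (tip = C1 + tip_to_c1) and the model inversion.
    """
    if at not in ("c1", "tip"):
        raise ValueError(f"reference must be 'c1' or 'tip', got {at!r}")
    actual_linear = float(forward_model(geom, obs.angular_actual, pred.model, params))
    actual_angle = obs.angular_actual
    if obs.reference != at:
        if geom is None:
            raise ValueError(
                "observed reference differs from requested reference and no "
                "geometry is available for conversion"
            )
        shift = spec.tip_to_c1 if at == "tip" else -spec.tip_to_c1
        actual_linear = actual_linear + shift
        actual_angle = invert_model(geom, actual_linear, pred.model, params)
    pred_linear = pred.linear_c1 if at == "c1" else pred.linear_tip
    pred_angle = pred.angular_c1 if at == "c1" else pred.angular_tip
    return ErrorRecord(
        subject_id=obs.subject_id,
        model=pred.model,
        angular_error=actual_angle - pred_angle,
        linear_error=actual_linear - pred_linear,
        angular_actual=actual_angle,
        angular_predicted=pred_angle,
        linear_actual=actual_linear,
        linear_predicted=pred_linear,
    )


def summarize_errors(
    errors: pd.DataFrame, by: tuple[str, ...] = ("model", "observer")
) -> pd.DataFrame:
    """Group error records and summarise absolute and signed errors.

    Expects columns ``angular_error_deg`` and ``linear_error_mm`` plus the
    grouping keys.  Returns, per group: ``n``, mean and sample SD (ddof=1) of
    the absolute errors, and signed means.  A single-record group has SD NaN.
    """
    required = set(by) | {"angular_error_deg", "linear_error_mm"}
    missing = required - set(errors.columns)
    if missing:
        raise ValueError(f"error table missing columns: {sorted(missing)}")
    if errors.empty:
        raise ValueError("no error records to summarise")

    def agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n": len(g),
                "mean_abs_angular_deg": g["angular_error_deg"].abs().mean(),
                "sd_abs_angular_deg": g["angular_error_deg"].abs().std(ddof=1),
                "mean_abs_linear_mm": g["linear_error_mm"].abs().mean(),
                "sd_abs_linear_mm": g["linear_error_mm"].abs().std(ddof=1),
                "mean_signed_angular_deg": g["angular_error_deg"].mean(),
                "mean_signed_linear_mm": g["linear_error_mm"].mean(),
            }
        )

    out = errors.groupby(list(by), sort=True).apply(agg, include_groups=False)
    out["n"] = out["n"].astype(int)
    return out.reset_index()


def cohort_angle_summary(angles_deg) -> dict:
    """Mean angular depth of a cohort, in degrees and in turns (360° = 1)."""
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle list")
    mean = float(angles.mean())
    return {"mean_deg": mean, "mean_turns": mean / 360.0, "n": int(angles.size)}


def exceedance_report(linear_errors_mm, bound_mm: float = 2.38) -> dict:
    """How often the actual insertion exceeds the prediction.

    Positive signed error = actual deeper than predicted.  Reports empirical
    fractions of errors above 0 and above ``bound_mm``, and — under a normal
    model fitted to the signed errors (sample SD) — the corresponding tail
    probabilities, plus the generic one- and two-SD one-sided normal tails
    (the reading under which "16 %" and "2.5 %" exceedance rates arise).
    """
    e = np.asarray(linear_errors_mm, dtype=float)
    if e.size == 0:
        raise ValueError("empty error list")
    mu = float(e.mean())
    sd = float(e.std(ddof=1)) if e.size > 1 else 0.0
    out = {
        "n": int(e.size),
        "mean_mm": mu,
        "sd_mm": sd,
        "empirical_frac_above_0": float((e > 0).mean()),
        "empirical_frac_above_bound": float((e > bound_mm).mean()),
        "bound_mm": float(bound_mm),
        "normal_one_sd_tail": float(stats.norm.sf(1.0)),
        "normal_two_sd_tail": float(stats.norm.sf(2.0)),
    }
    if sd > 0:
        out["normal_frac_above_0"] = float(stats.norm.sf(0.0, loc=mu, scale=sd))
        out["normal_frac_above_bound"] = float(stats.norm.sf(bound_mm, loc=mu, scale=sd))
    else:
        warnings.warn("zero error variance; normal tail probabilities undefined")
        out["normal_frac_above_0"] = float("nan")
        out["normal_frac_above_bound"] = float("nan")
    return out
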