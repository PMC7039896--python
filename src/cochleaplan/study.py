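"""Cohort-level insertion-depth study: model object and fitted results.

``InsertionStudy`` is built from a preoperative measurement table and a
postoperative observation table (the two CSV schemas in :mod:`cochleaplan.io`)
and, on ``fit()``, runs the full pipeline: per-measurement insertion-depth
prediction under each requested cochlear model, per-subject prediction errors
against the postoperative readings, Table-style error summaries per
observer and model, and the intra-/inter-observer agreement analysis
(Bland–Altman, ICC, and the paired Wilcoxon comparison of the two models'
observer disagreement).  ``InsertionStudyResults.summary()`` renders an
aligned-text report.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as cio
from .agreement import (
    AgreementReport,
    bland_altman,
    compare_method_variability,
    icc,
)
from .electrode import (
    ElectrodeSpec,
    FullInsertionError,
    actual_tip_from_c1,
    flex28_spec,
    predict_insertion,
)
from .models import (
    MODEL_NAMES,
    CochlearGeometry,
    ModelParams,
    forward_model,
    invert_model,
)
from .validation import cohort_angle_summary, exceedance_report, summarize_errors

__all__ = ["InsertionStudy", "InsertionStudyResults"]

logger = logging.getLogger(__name__)


def _params_hash(params: ModelParams, electrode: ElectrodeSpec, models) -> str:
    blob = repr((params, electrode, tuple(models))).encode()
    return hashlib.sha1(blob).hexdigest()[:10]


class InsertionStudy:
    """Insertion-depth prediction study over a measured cohort.

    Parameters
    ----------
    measurements : DataFrame
        Preoperative basal-turn measurements (schema:
        ``io.MEASUREMENT_COLUMNS``); validated on construction.
    observations : DataFrame or None
        Postoperative angular readings (schema: ``io.OBSERVATION_COLUMNS``).
        Without them only predictions and preoperative agreement are fitted.
    electrode : ElectrodeSpec
        Defaults to the FLEX28 array.
    models : sequence of {'escude', 'eca'}
    params : ModelParams
    icc_form : str
        Shrout–Fleiss ICC form used for the inter-observer analysis.
    """

    def __init__(
        self,
        measurements: pd.DataFrame,
        observations: pd.DataFrame | None = None,
        electrode: ElectrodeSpec | None = None,
        models=MODEL_NAMES,
        params: ModelParams | None = None,
        icc_form: str = "icc2",
    ):
        self.measurements = cio.validate_measurements(measurements)
        self.observations = (
            cio.validate_observations(observations) if observations is not None else None
        )
        self.electrode = electrode if electrode is not None else flex28_spec()
        self.models = tuple(models)
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown models {sorted(unknown)}")
        self.params = params if params is not None else ModelParams()
        self.icc_form = icc_form

    @classmethod
    def from_csv(cls, measurements_path, observations_path=None, **kwargs):
        meas = cio.read_measurements(measurements_path)
        obs = cio.read_observations(observations_path) if observations_path else None
        return cls(meas, obs, **kwargs)

    @classmethod
    def from_cohort(cls, cohort, **kwargs):
        """Build a study directly from a :class:`SyntheticCohort`."""
        return cls(cohort.measurements, cohort.observations, **kwargs)

    # ------------------------------------------------------------------ fit

    def fit(self) -> "InsertionStudyResults":
        run_hash = _params_hash(self.params, self.electrode, self.models)
        predictions, excluded = self._predict(run_hash)
        errors = error_summary = None
        cohort_angles = exceedance = None
        if self.observations is not None and not predictions.empty:
            errors = self._errors(predictions, run_hash)
            if not errors.empty:
                error_summary = summarize_errors(errors, by=("model", "observer"))
                cohort_angles = {
                    m: cohort_angle_summary(
                        errors.loc[errors["model"] == m, "actual_tip_deg"].dropna()
                    )
                    for m in self.models
                    if (errors["model"] == m).any()
                }
                exceedance = {
                    m: exceedance_report(
                        errors.loc[errors["model"] == m, "linear_error_mm"].dropna()
                    )
                    for m in self.models
                    if (errors["model"] == m).any()
                }
        agreement = self._agreement(predictions)
        return InsertionStudyResults(
            study=self,
            run_hash=run_hash,
            predictions=predictions,
            excluded=excluded,
            errors=errors,
            error_summary=error_summary,
            agreement=agreement,
            cohort_angles=cohort_angles,
            exceedance=exceedance,
        )

    def _predict(self, run_hash: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        rows, skipped = [], []
        for _, r in self.measurements.iterrows():
            for model in self.models:
                if model == "eca" and pd.isna(r["B_mm"]):
                    logger.warning(
                        "subject %s observer %s: B missing (%s row); ECA skipped",
                        r["subject_id"], r["observer"], r["method"],
                    )
                    skipped.append(
                        {**_key(r), "model": model, "reason": "B_mm missing"}
                    )
                    continue
                geom = CochlearGeometry(
                    A=float(r["A_mm"]),
                    B=float(r["B_mm"]) if not pd.isna(r["B_mm"]) else None,
                )
                try:
                    pred = predict_insertion(geom, self.electrode, model, self.params)
                except (FullInsertionError, ValueError) as exc:
                    logger.warning("prediction failed for %s/%s: %s",
                                   r["subject_id"], model, exc)
                    skipped.append({**_key(r), "model": model, "reason": str(exc)})
                    continue
                rows.append(
                    {
                        **_key(r),
                        "model": model,
                        "A_mm": float(r["A_mm"]),
                        "B_mm": float(r["B_mm"]) if not pd.isna(r["B_mm"]) else np.nan,
                        "linear_c1_mm": pred.linear_c1,
                        "angular_c1_deg": pred.angular_c1,
                        "linear_tip_mm": pred.linear_tip,
                        "angular_tip_deg": pred.angular_tip,
                        "params_hash": run_hash,
                    }
                )
        if skipped:
            logger.warning("%d prediction rows skipped/excluded", len(skipped))
        return pd.DataFrame(rows), pd.DataFrame(skipped)

    def _errors(self, predictions: pd.DataFrame, run_hash: str) -> pd.DataFrame:
        """Per-(subject, observer, observation, model) error records at C1."""
        obs = self.observations
        c1 = obs[obs["reference"] == "c1"][["subject_id", "observer", "actual_deg"]]
        tip_only = obs[obs["reference"] == "tip"]
        rows = []
        for _, p in predictions.iterrows():
            match = c1[(c1["subject_id"] == p["subject_id"])
                       & (c1["observer"] == p["observer"])]
            geom = CochlearGeometry(
                A=float(p["A_mm"]),
                B=float(p["B_mm"]) if not pd.isna(p["B_mm"]) else None,
            )
            if match.empty:
                # fall back to a tip reading, converted to C1 through the model
                tmatch = tip_only[(tip_only["subject_id"] == p["subject_id"])
                                  & (tip_only["observer"] == p["observer"])]
                if tmatch.empty:
                    continue
                tip_deg = float(tmatch["actual_deg"].iloc[0])
                tip_mm = float(forward_model(geom, tip_deg, p["model"], self.params))
                actual_c1_mm = tip_mm - self.electrode.tip_to_c1
                actual_c1_deg = invert_model(geom, actual_c1_mm, p["model"], self.params)
            else:
                actual_c1_deg = float(match["actual_deg"].iloc[0])
                actual_c1_mm = float(
                    forward_model(geom, actual_c1_deg, p["model"], self.params)
                )
            actual_tip_mm = actual_tip_from_c1(actual_c1_mm, self.electrode)
            try:
                actual_tip_deg = invert_model(geom, actual_tip_mm, p["model"], self.params)
            except ValueError:
                actual_tip_deg = np.nan
            rows.append(
                {
                    "subject_id": p["subject_id"],
                    "observer": p["observer"],
                    "observation": p["observation"],
                    "model": p["model"],
                    "reference": "c1",
                    "predicted_deg": p["angular_c1_deg"],
                    "actual_deg": actual_c1_deg,
                    "predicted_mm": p["linear_c1_mm"],
                    "actual_mm": actual_c1_mm,
                    "angular_error_deg": actual_c1_deg - p["angular_c1_deg"],
                    "linear_error_mm": actual_c1_mm - p["linear_c1_mm"],
                    "actual_tip_deg": actual_tip_deg,
                    "actual_tip_mm": actual_tip_mm,
                    "params_hash": run_hash,
                }
            )
        return pd.DataFrame(rows)

    def _agreement(self, predictions: pd.DataFrame) -> pd.DataFrame:
        """Intra-/inter-observer Bland–Altman (+ICC, Wilcoxon) table."""
        rows = []
        meas = self.measurements[self.measurements["method"] == "software-3d"]

        def _pivot(df, value, index, columns):
            return df.pivot_table(index=index, columns=columns, values=value,
                                  aggfunc="first").dropna()

        # intra-observer: observation 1 vs 2, per observer, for A, B and
        # each model's predicted angle at C1
        for observer in sorted(meas["observer"].dropna().unique()):
            sub = meas[meas["observer"] == observer]
            for value, unit in (("A_mm", "mm"), ("B_mm", "mm")):
                wide = _pivot(sub, value, "subject_id", "observation")
                if wide.shape[1] == 2 and len(wide) >= 2:
                    rep = bland_altman((wide[1].to_numpy(), wide[2].to_numpy()))
                    rows.append(_arow("intra-observer", value, unit, observer, None, rep))
            psub = predictions[(predictions["observer"] == observer)
                               & (predictions["method"] == "software-3d")]
            for model in self.models:
                wide = _pivot(psub[psub["model"] == model], "angular_c1_deg",
                              "subject_id", "observation")
                if wide.shape[1] == 2 and len(wide) >= 2:
                    rep = bland_altman((wide[1].to_numpy(), wide[2].to_numpy()))
                    rows.append(_arow("intra-observer", "angular_c1_deg", "deg",
                                      observer, model, rep))

        # inter-observer: observer 1 vs 2 at observation 1
        first = meas[meas["observation"] == 1]
        for value, unit in (("A_mm", "mm"), ("B_mm", "mm")):
            wide = _pivot(first, value, "subject_id", "observer")
            if wide.shape[1] == 2 and len(wide) >= 3:
                rep = bland_altman((wide[1].to_numpy(), wide[2].to_numpy()))
                val, label = icc((wide[1].to_numpy(), wide[2].to_numpy()),
                                 form=self.icc_form)
                rep.icc, rep.icc_label, rep.icc_form = val, label, self.icc_form
                rows.append(_arow("inter-observer", value, unit, None, None, rep))
        pfirst = predictions[(predictions["observation"] == 1)
                             & (predictions["method"] == "software-3d")]
        inter_abs: dict[str, pd.Series] = {}
        for model in self.models:
            wide = _pivot(pfirst[pfirst["model"] == model], "angular_c1_deg",
                          "subject_id", "observer")
            if wide.shape[1] == 2 and len(wide) >= 3:
                rep = bland_altman((wide[1].to_numpy(), wide[2].to_numpy()))
                val, label = icc((wide[1].to_numpy(), wide[2].to_numpy()),
                                 form=self.icc_form)
                rep.icc, rep.icc_label, rep.icc_form = val, label, self.icc_form
                rows.append(_arow("inter-observer", "angular_c1_deg", "deg",
                                  None, model, rep))
                inter_abs[model] = (wide[1] - wide[2]).abs()

        out = pd.DataFrame(rows)
        # paired comparison of the two models' per-subject observer disagreement
        if {"escude", "eca"} <= inter_abs.keys():
            joined = pd.concat([inter_abs["escude"].rename("escude"),
                                inter_abs["eca"].rename("eca")], axis=1).dropna()
            if len(joined) >= 5:
                p = compare_method_variability(joined["escude"], joined["eca"])
                out.attrs["wilcoxon_escude_vs_eca_p"] = p
        return out


def _key(r) -> dict:
    return {
        "subject_id": r["subject_id"],
        "observer": int(r["observer"]),
        "observation": int(r["observation"]),
        "method": r["method"],
    }


def _arow(kind, quantity, unit, observer, model, rep: AgreementReport) -> dict:
    return {
        "kind": kind,
        "quantity": quantity,
        "unit": unit,
        "observer": observer,
        "model": model,
        "n": rep.n,
        "mean_diff": rep.mean_diff,
        "sd_diff": rep.sd_diff,
        "loa_low": rep.loa_low,
        "loa_high": rep.loa_high,
        "icc": rep.icc,
        "icc_label": rep.icc_label,
        "icc_form": rep.icc_form,
    }


@dataclass
class InsertionStudyResults:
    """Fitted study outputs.

    Attributes
    ----------
    predictions : per-measurement predictions under each model
    excluded : skipped prediction rows with reasons
    errors : per-subject error records at C1 (actual − predicted)
    error_summary : per (model, observer) absolute/signed error summary
    agreement : Bland–Altman/ICC table (Wilcoxon p in ``.attrs``)
    cohort_angles : mean actual tip angle per model (deg and turns)
    exceedance : per-model exceedance report of signed linear errors
    """

    study: InsertionStudy
    run_hash: str
    predictions: pd.DataFrame
    excluded: pd.DataFrame
    errors: pd.DataFrame | None = None
    error_summary: pd.DataFrame | None = None
    agreement: pd.DataFrame | None = None
    cohort_angles: dict | None = None
    exceedance: dict | None = None

    @property
    def wilcoxon_p(self) -> float | None:
        if self.agreement is None:
            return None
        return self.agreement.attrs.get("wilcoxon_escude_vs_eca_p")

    def pooled_mean_abs_linear_error(self, model: str) -> float:
        """Mean |linear error| (mm) pooled over observers and observations."""
        if self.errors is None:
            raise ValueError("no postoperative observations were fitted")
        e = self.errors.loc[self.errors["model"] == model, "linear_error_mm"]
        if e.empty:
            raise ValueError(f"no error records for model {model!r}")
        return float(e.abs().mean())

    def pooled_mean_abs_angular_error(self, model: str) -> float:
        """Mean |angular error| (deg) pooled over observers and observations."""
        if self.errors is None:
            raise ValueError("no postoperative observations were fitted")
        e = self.errors.loc[self.errors["model"] == model, "angular_error_deg"]
        if e.empty:
            raise ValueError(f"no error records for model {model!r}")
        return float(e.abs().mean())

    def inter_observer_icc(self, model: str) -> float | None:
        if self.agreement is None:
            return None
        sel = self.agreement[
            (self.agreement["kind"] == "inter-observer")
            & (self.agreement["model"] == model)
            & (self.agreement["quantity"] == "angular_c1_deg")
        ]
        return float(sel["icc"].iloc[0]) if len(sel) else None

    def summary(self) -> str:
        """Aligned-text report of the fitted study."""
        s = self.study
        lines = [
            "Insertion-depth study summary",
            "=" * 64,
            f"electrode: {s.electrode.name}  (C1->stopper {s.electrode.c1_to_stopper} mm, "
            f"tip->C1 {s.electrode.tip_to_c1} mm)",
            f"models: {', '.join(s.models)}   offsets: escude {s.params.escude_offset} mm, "
            f"eca {s.params.eca_offset} mm",
            f"ICC form: {s.icc_form} (two-way random, absolute agreement, single"
            " measures)" if s.icc_form == "icc2" else f"ICC form: {s.icc_form}",
            f"parameter-set hash: {self.run_hash}",
            f"predictions: {len(self.predictions)} rows; "
            f"excluded/skipped: {len(self.excluded)}",
        ]
        if self.error_summary is not None:
            lines += ["", "Prediction errors at C1 (actual - predicted; |.| = absolute)",
                      "-" * 64]
            es = self.error_summary
            hdr = (f"{'model':8s}{'obs':>4s}{'n':>5s}{'mean|ang|':>11s}{'sd':>8s}"
                   f"{'mean|lin|':>11s}{'sd':>8s}{'signed ang':>12s}")
            lines.append(hdr)
            for _, r in es.iterrows():
                lines.append(
                    f"{r['model']:8s}{int(r['observer']):>4d}{int(r['n']):>5d}"
                    f"{r['mean_abs_angular_deg']:>11.2f}{r['sd_abs_angular_deg']:>8.2f}"
                    f"{r['mean_abs_linear_mm']:>11.2f}{r['sd_abs_linear_mm']:>8.2f}"
                    f"{r['mean_signed_angular_deg']:>12.2f}"
                )
        if self.cohort_angles:
            lines += ["", "Mean actual angular insertion depth at tip", "-" * 64]
            for m, c in self.cohort_angles.items():
                lines.append(
                    f"{m:8s}{c['mean_deg']:>9.1f} deg  ({c['mean_turns']:.2f} turns, "
                    f"n={c['n']})"
                )
        if self.agreement is not None and len(self.agreement):
            lines += ["", "Observer agreement (differences; limits at mean +/- 2 SD)",
                      "-" * 64]
            for _, r in self.agreement.iterrows():
                who = f"observer {int(r['observer'])}" if pd.notna(r["observer"]) else "obs1 vs obs2"
                model = f" [{r['model']}]" if pd.notna(r["model"]) else ""
                icc_txt = (f"  ICC={r['icc']:.2f} ({r['icc_label']})"
                           if pd.notna(r["icc"]) else "")
                lines.append(
                    f"{r['kind']:15s}{r['quantity']:16s}{who:14s}{model:10s}"
                    f" mean {r['mean_diff']:+7.2f} sd {r['sd_diff']:6.2f} {r['unit']}"
                    f"{icc_txt}"
                )
            if self.wilcoxon_p is not None:
                lines.append(
                    f"paired Wilcoxon, |inter-observer disagreement| escude vs eca: "
                    f"p = {self.wilcoxon_p:.4g}"
                )
        return "\n".join(lines)


def run_pipeline(
    measurements: pd.DataFrame,
    observations: pd.DataFrame | None = None,
    **kwargs,
) -> InsertionStudyResults:
    """One-call pipeline: validate, predict, evaluate errors and agreement."""
    return InsertionStudy(measurements, observations, **kwargs).fit()
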