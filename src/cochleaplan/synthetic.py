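"""Synthetic cohorts with the statistical structure of a two-observer CT study.

Each cohort has per-subject true basal-turn geometry, repeated noisy
measurements by two observers (two observations each, at least nominally a
week apart in the emulated design), and postoperative "actual" insertion
angles generated under one named cochlear model with a nonnegative insertion
shortfall — the stopper never quite reaches the round window, so actual
insertions fall systematically short of the nominal electrode length and
predictions systematically overestimate.

What this generator does *not* emulate: CT resolution limits, contact-picking
anatomy, otosclerotic ossification, electrode bending or partial insertions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .electrode import ElectrodeSpec, actual_tip_from_c1, flex28_spec
from .models import CochlearGeometry, ModelParams, MODEL_NAMES, invert_model

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "default_study_config"]

_REJECTION_CAP = 1000


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort (lengths mm, angles deg).

    ``sigma_A``/``sigma_B`` are per-measurement observer noise SDs, one entry
    per observer.  ``bias_A``/``bias_B`` are added to observer 2's
    measurements (a positive bias makes observer 1 − observer 2 negative).
    ``insertion_shortfall_*`` parameterise the truncated-at-zero normal
    shortfall of the actual linear depth at C1 below the nominal
    C1-to-stopper length.
    """

    n_subjects: int = 46
    A_mean: float = 9.1
    A_sd: float = 0.4
    B_mean: float = 6.8
    B_sd: float = 0.4
    AB_correlation: float = 0.5
    A_range: tuple[float, float] = (7.0, 11.0)
    B_range: tuple[float, float] = (5.0, 8.0)
    sigma_A: tuple[float, float] = (0.47 / math.sqrt(2), 0.53 / math.sqrt(2))
    sigma_B: tuple[float, float] = (0.40 / math.sqrt(2), 0.44 / math.sqrt(2))
    bias_A: float = 0.12
    bias_B: float = 0.10
    insertion_shortfall_mean: float = 0.58
    insertion_shortfall_sd: float = 0.5
    actual_angle_noise_sd: float = 10.0
    generating_model: str = "eca"
    n_observers: int = 2
    n_observations: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not -1.0 <= self.AB_correlation <= 1.0:
            raise ValueError("AB_correlation must lie in [-1, 1]")
        sds = (self.A_sd, self.B_sd, *self.sigma_A, *self.sigma_B,
               self.insertion_shortfall_sd, self.actual_angle_noise_sd)
        if any(s < 0 for s in sds):
            raise ValueError("all SDs must be nonnegative")
        if self.generating_model not in MODEL_NAMES:
            raise ValueError(f"generating_model must be one of {MODEL_NAMES}")

    def noise_free(self) -> "CohortConfig":
        """A copy with every noise source and the shortfall set to zero."""
        return replace(
            self,
            sigma_A=(0.0, 0.0),
            sigma_B=(0.0, 0.0),
            bias_A=0.0,
            bias_B=0.0,
            insertion_shortfall_mean=0.0,
            insertion_shortfall_sd=0.0,
            actual_angle_noise_sd=0.0,
        )


@dataclass
class SyntheticCohort:
    """Generated cohort: ground truth plus the observable tables.

    ``truth`` — per subject: true (A, B), shortfall, actual linear depth at
    C1 and the noise-free actual angles at C1 and tip under the generating
    model.  ``measurements`` and ``observations`` are the tables the analysis
    pipeline consumes (observer-noisy).
    """

    config: CohortConfig
    truth: pd.DataFrame
    measurements: pd.DataFrame
    observations: pd.DataFrame

    def write(self, directory) -> dict:
        """Write truth/measurements/observations CSVs; returns the paths."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("truth", "measurements", "observations"):
            p = d / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False, float_format="%.10g")
            paths[name] = p
        return paths


def _truncated_bivariate(rng: np.random.Generator, cfg: CohortConfig) -> np.ndarray:
    """Rejection-sample (A, B) from the truncated, A>B-constrained normal."""
    cov = np.array(
        [
            [cfg.A_sd**2, cfg.AB_correlation * cfg.A_sd * cfg.B_sd],
            [cfg.AB_correlation * cfg.A_sd * cfg.B_sd, cfg.B_sd**2],
        ]
    )
    mean = np.array([cfg.A_mean, cfg.B_mean])
    out = np.empty((cfg.n_subjects, 2))
    for i in range(cfg.n_subjects):
        for attempt in range(_REJECTION_CAP):
            a, b = rng.multivariate_normal(mean, cov, method="cholesky")
            if (cfg.A_range[0] <= a <= cfg.A_range[1]
                    and cfg.B_range[0] <= b <= cfg.B_range[1] and a > b):
                out[i] = (a, b)
                break
        else:
            raise ValueError(
                "rejection sampling failed: truncation region "
                f"A∈{cfg.A_range}, B∈{cfg.B_range}, A>B is (near-)empty for "
                f"the configured anatomical distribution"
            )
    return out


def _truncated_shortfall(rng: np.random.Generator, cfg: CohortConfig) -> np.ndarray:
    if cfg.insertion_shortfall_sd == 0:
        return np.full(cfg.n_subjects, max(cfg.insertion_shortfall_mean, 0.0))
    out = np.empty(cfg.n_subjects)
    for i in range(cfg.n_subjects):
        for attempt in range(_REJECTION_CAP):
            s = rng.normal(cfg.insertion_shortfall_mean, cfg.insertion_shortfall_sd)
            if s >= 0:
                out[i] = s
                break
        else:
            raise ValueError("rejection sampling failed for the insertion shortfall")
    return out


def generate_cohort(
    config: CohortConfig, electrode: ElectrodeSpec | None = None
) -> SyntheticCohort:
    """Generate a reproducible synthetic cohort from one seeded generator.

    Actual angles are produced by inverting the generating model on the
    subject's *true* geometry at the shortfall-reduced linear depth, then
    adding per-observer angular reading noise at C1; the tip angle follows
    from the noisy C1 reading through the generating model (linear +1.2 mm
    offset, same geometry), mirroring how a postoperative reading at C1 is
    propagated to the tip.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    spec = electrode if electrode is not None else flex28_spec()

    ab = _truncated_bivariate(rng, cfg)
    shortfall = _truncated_shortfall(rng, cfg)
    subj = [f"S{i+1:03d}" for i in range(cfg.n_subjects)]
    ears = np.where(rng.random(cfg.n_subjects) < 0.5, "L", "R")

    actual_lin_c1 = spec.c1_to_stopper - shortfall
    truth_rows = []
    geoms = []
    for i in range(cfg.n_subjects):
        geom = CochlearGeometry(A=ab[i, 0], B=ab[i, 1], strict=True)
        geoms.append(geom)
        ang_c1 = invert_model(geom, actual_lin_c1[i], cfg.generating_model)
        ang_tip = invert_model(
            geom, actual_tip_from_c1(actual_lin_c1[i], spec), cfg.generating_model
        )
        truth_rows.append(
            {
                "subject_id": subj[i],
                "A_true_mm": ab[i, 0],
                "B_true_mm": ab[i, 1],
                "shortfall_mm": shortfall[i],
                "actual_linear_c1_mm": actual_lin_c1[i],
                "actual_angle_c1_deg": ang_c1,
                "actual_angle_tip_deg": ang_tip,
            }
        )
    truth = pd.DataFrame(truth_rows)

    meas_rows = []
    for o in range(cfg.n_observers):
        bias_a = cfg.bias_A if o == 1 else 0.0
        bias_b = cfg.bias_B if o == 1 else 0.0
        for k in range(cfg.n_observations):
            na = rng.normal(0.0, cfg.sigma_A[o], cfg.n_subjects) if cfg.sigma_A[o] > 0 else np.zeros(cfg.n_subjects)
            nb = rng.normal(0.0, cfg.sigma_B[o], cfg.n_subjects) if cfg.sigma_B[o] > 0 else np.zeros(cfg.n_subjects)
            for i in range(cfg.n_subjects):
                meas_rows.append(
                    {
                        "subject_id": subj[i],
                        "ear": ears[i],
                        "observer": o + 1,
                        "observation": k + 1,
                        "method": "software-3d",
                        "A_mm": ab[i, 0] + bias_a + na[i],
                        "B_mm": ab[i, 1] + bias_b + nb[i],
                    }
                )
    measurements = pd.DataFrame(meas_rows)

    obs_rows = []
    for o in range(cfg.n_observers):
        noise = (rng.normal(0.0, cfg.actual_angle_noise_sd, cfg.n_subjects)
                 if cfg.actual_angle_noise_sd > 0 else np.zeros(cfg.n_subjects))
        for i in range(cfg.n_subjects):
            ang_c1_obs = truth.loc[i, "actual_angle_c1_deg"] + noise[i]
            lin_c1_obs = _forward(geoms[i], ang_c1_obs, cfg.generating_model)
            ang_tip_obs = invert_model(
                geoms[i], actual_tip_from_c1(lin_c1_obs, spec), cfg.generating_model
            )
            obs_rows.append(
                {
                    "subject_id": subj[i],
                    "observer": o + 1,
                    "observation": 1,
                    "reference": "c1",
                    "actual_deg": ang_c1_obs,
                }
            )
            obs_rows.append(
                {
                    "subject_id": subj[i],
                    "observer": o + 1,
                    "observation": 1,
                    "reference": "tip",
                    "actual_deg": ang_tip_obs,
                }
            )
    observations = pd.DataFrame(obs_rows)
    return SyntheticCohort(
        config=cfg, truth=truth, measurements=measurements, observations=observations
    )


def _forward(geom: CochlearGeometry, theta: float, model: str) -> float:
    from .models import forward_model

    return float(forward_model(geom, theta, model))


def default_study_config(seed: int = 0) -> CohortConfig:
    """The emulated study design: 46 subjects, 2 observers × 2 observations.

    Per-measurement noise SDs are back-calculated from reported
    intra-observer difference SDs (difference of two independent
    measurements has SD σ·√2, so σ = difference SD / √2): A 0.47/√2 and
    0.53/√2 mm, B 0.40/√2 and 0.44/√2 mm for observers 1 and 2.
    Inter-observer biases 0.12 mm (A) and 0.10 mm (B) on observer 2.  The
    anatomical (A, B) distribution and the 10° postoperative angular reading
    noise are assumptions, not study-reported values.
    """
    return CohortConfig(seed=seed)
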