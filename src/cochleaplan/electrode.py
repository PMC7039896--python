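"""Electrode-array geometry and forward insertion-depth prediction.

The prediction assumes a full insertion with the stopper at the round
window: the first-contact-to-stopper length of the array is projected onto
the modelled duct and inverted to an angle.  Partial insertion is never
represented on the predicted side; it belongs to the observed data.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import CochlearGeometry, ModelParams, forward_model, invert_model

__all__ = [
    "ElectrodeSpec",
    "InsertionPrediction",
    "flex28_spec",
    "predict_insertion",
    "actual_tip_from_c1",
    "FullInsertionError",
]


class FullInsertionError(ValueError):
    """Full insertion is not representable by the model for this geometry.

    Carries ``max_length_mm``, the longest insertion the model can map to an
    angle within its valid range.
    """

    def __init__(self, msg: str, max_length_mm: float):
        super().__init__(msg)
        self.max_length_mm = max_length_mm


@dataclass(frozen=True)
class ElectrodeSpec:
    """Lateral-wall electrode array geometry (all lengths mm).

    ``total_length`` runs from the silicone tip to the stopper;
    ``c1_to_stopper`` from the first (most apical) contact C1 to the stopper;
    ``tip_to_c1`` is the silicone-only tip segment.
    """

    name: str
    total_length: float
    c1_to_stopper: float
    tip_to_c1: float

    def __post_init__(self) -> None:
        if min(self.total_length, self.c1_to_stopper, self.tip_to_c1) <= 0:
            raise ValueError("all electrode lengths must be positive")
        if abs(self.total_length - (self.c1_to_stopper + self.tip_to_c1)) > 1e-9:
            raise ValueError(
                f"total_length ({self.total_length}) must equal c1_to_stopper + "
                f"tip_to_c1 ({self.c1_to_stopper} + {self.tip_to_c1})"
            )


@dataclass(frozen=True)
class InsertionPrediction:
    """Predicted linear (mm) and angular (deg) insertion depth at C1 and tip."""

    model: str
    linear_c1: float
    angular_c1: float
    linear_tip: float
    angular_tip: float


def flex28_spec() -> ElectrodeSpec:
    """The FLEX28 array: 28 mm tip-to-stopper, C1 26.8 mm from the stopper."""
    return ElectrodeSpec(name="FLEX28", total_length=28.0, c1_to_stopper=26.8, tip_to_c1=1.2)


def predict_insertion(
    geom: CochlearGeometry,
    spec: ElectrodeSpec,
    model: str,
    params: ModelParams = ModelParams(),
) -> InsertionPrediction:
    """Predict angular insertion depth at C1 and at the silicone tip.

    The stopper is placed at the round window, so the linear depth at C1 is
    the array's C1-to-stopper length and at the tip its total length; both
    are inverted through the named model to angles.
    """
    try:
        ang_c1 = invert_model(geom, spec.c1_to_stopper, model, params)
        ang_tip = invert_model(geom, spec.total_length, model, params)
    except ValueError as exc:
        max_len = forward_model(geom, params.theta_max, model, params)
        raise FullInsertionError(
            f"full insertion of {spec.name} not modellable by {model} for "
            f"A={geom.A:.2f}, B={geom.B:.2f}: {exc} "
            f"(maximum modellable length {max_len:.3f} mm)",
            max_length_mm=float(max_len),
        ) from exc
    return InsertionPrediction(
        model=model,
        linear_c1=spec.c1_to_stopper,
        angular_c1=ang_c1,
        linear_tip=spec.total_length,
        angular_tip=ang_tip,
    )


def actual_tip_from_c1(actual_linear_c1: float, spec: ElectrodeSpec) -> float:
    """Linear depth at the silicone tip from the linear depth at C1 (mm)."""
    if actual_linear_c1 < 0:
        raise ValueError("actual linear depth at C1 must be nonnegative")
    return actual_linear_c1 + spec.tip_to_c1
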