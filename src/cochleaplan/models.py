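"""Analytical cochlear models mapping insertion angle to duct length.

Two lateral-wall models are provided, both evaluated at the level of a
lateral-wall electrode array (a fixed offset inside the bony lateral wall):

* the adopted Escudé model — a logarithmic spiral whose scale depends only
  on the basal-turn diameter ``A``::

      CDL_i(theta) = p1 * (A - 2*offset) * ln(1 + theta/p2)

  with ``p1 = 2.62``, ``p2 = 235°`` and a 0.5 mm wall offset;

* the Elliptic-Circular Approximation (ECA) — the basal-turn length is
  estimated from both diameter ``A`` and width ``B`` (0.35 mm offset)::

      BTL_i = 1.18 A' + 2.69 B' - sqrt(0.72 A' B'),  X' = X - 2*offset

  and the duct length at angle ``theta`` is a percentage of it given by a
  cubic polynomial ``p_BTL(theta)``.

Angles are degrees, zero at the round window, increasing apically; one full
turn is 360°.  Lengths are millimetres.  The percentage polynomial is an
empirical fit valid on [0, 900]°; note that ``p_BTL(0) = 3.7 %``, so the ECA
length does not vanish at the round window — requests to invert lengths
shorter than ``CDL(0)`` are rejected rather than extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "CochlearGeometry",
    "ModelParams",
    "LengthAngle",
    "escude_cdl",
    "invert_escude",
    "eca_btl",
    "pbtl",
    "eca_cdl",
    "invert_eca",
    "generate_pbtl_table",
    "MODEL_NAMES",
]

MODEL_NAMES = ("escude", "eca")


@dataclass(frozen=True)
class CochlearGeometry:
    """Basal-turn measurements of one cochlea.

    Parameters
    ----------
    A : float
        Basal-turn diameter (round window through the helicotrema to the
        opposite lateral wall), mm.
    B : float or None
        Basal-turn width, perpendicular to ``A`` through the helicotrema, mm.
        May be None for A-only workflows (the Escudé model ignores B); the
        ECA then raises.
    strict : bool
        If True, ``A <= B`` raises; otherwise it only warns (measurement
        noise on real data can transiently violate the anatomical ordering).
    """

    A: float
    B: float | None = None
    strict: bool = False

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError(f"A must be positive, got A={self.A}")
        if self.B is None:
            return
        if not self.B > 0:
            raise ValueError(f"B must be positive, got B={self.B}")
        if self.A <= self.B:
            msg = f"expected diameter A > width B, got A={self.A} <= B={self.B}"
            if self.strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=3)


@dataclass(frozen=True)
class ModelParams:
    """Constants of the two analytical models.

    ``escude_offset`` and ``eca_offset`` are the assumed distances (mm)
    between the lateral wall and the electrode array; exposing both as
    parameters makes the 0.35-mm-offset sensitivity variant of the Escudé
    model a parameter change rather than a code fork.
    """

    p1: float = 2.62
    p2: float = 235.0
    escude_offset: float = 0.5
    eca_offset: float = 0.35
    pbtl_coeffs: tuple[float, float, float, float] = (8.3e-8, -2.4e-4, 3.4e-1, 3.7)
    theta_max: float = 900.0

    def __post_init__(self) -> None:
        if self.p1 <= 0 or self.p2 <= 0:
            raise ValueError("p1 and p2 must be positive")
        if self.escude_offset < 0 or self.eca_offset < 0:
            raise ValueError("offsets must be nonnegative")
        if self.theta_max <= 0:
            raise ValueError("theta_max must be positive")


@dataclass(frozen=True)
class LengthAngle:
    """An (angular depth, linear depth) pair along the electrode path."""

    theta: float
    length: float

    def __post_init__(self) -> None:
        if self.theta < 0 or self.length < 0:
            raise ValueError("theta and length must be nonnegative")


_DEFAULT = ModelParams()


def _check_theta(theta, params: ModelParams) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta > params.theta_max):
        raise ValueError(
            f"angle outside the modelled range [0, {params.theta_max}] deg"
        )
    return theta


def escude_cdl(geom: CochlearGeometry, theta, params: ModelParams = _DEFAULT):
    """Duct length (mm) at angle ``theta`` (deg) under the adopted Escudé model."""
    theta = _check_theta(theta, params)
    eff = geom.A - 2.0 * params.escude_offset
    if eff <= 0:
        raise ValueError(
            f"non-positive effective diameter: A={geom.A} mm with "
            f"offset {params.escude_offset} mm"
        )
    out = params.p1 * eff * np.log1p(theta / params.p2)
    return float(out) if out.ndim == 0 else out


def invert_escude(geom: CochlearGeometry, length, params: ModelParams = _DEFAULT):
    """Angle (deg) at which the Escudé duct length equals ``length`` (mm).

    Closed form: ``theta = p2 * (exp(L / (p1 (A - 2 off))) - 1)``.
    """
    length = np.asarray(length, dtype=float)
    if np.any(length < 0):
        raise ValueError("length must be nonnegative")
    eff = geom.A - 2.0 * params.escude_offset
    if eff <= 0:
        raise ValueError(
            f"non-positive effective diameter: A={geom.A} mm with "
            f"offset {params.escude_offset} mm"
        )
    theta = params.p2 * np.expm1(length / (params.p1 * eff))
    if np.any(theta > params.theta_max):
        raise ValueError(
            f"length {np.max(length):.3f} mm exceeds the modelled duct "
            f"(angle > {params.theta_max} deg); maximum modellable length is "
            f"{escude_cdl(geom, params.theta_max, params):.3f} mm"
        )
    return float(theta) if theta.ndim == 0 else theta


def eca_btl(geom: CochlearGeometry, params: ModelParams = _DEFAULT) -> float:
    """Basal-turn length (mm) at electrode level under the ECA."""
    if geom.B is None:
        raise ValueError("ECA requires the basal-turn width B; geometry has A only")
    a = geom.A - 2.0 * params.eca_offset
    b = geom.B - 2.0 * params.eca_offset
    if a < 0 or b < 0:
        raise ValueError(
            f"offset-corrected axis negative: A'={a:.3f}, B'={b:.3f} mm "
            f"(offset {params.eca_offset} mm)"
        )
    rad = 0.72 * a * b
    return 1.18 * a + 2.69 * b - float(np.sqrt(rad))


def pbtl(theta, params: ModelParams = _DEFAULT):
    """Percentage of the basal-turn length covered at angle ``theta`` (deg).

    Cubic fit, strictly increasing on [0, 900]°; returns percent (``pbtl(0)``
    is 3.7, not 0 — the fit's round-window artefact).
    """
    theta = _check_theta(theta, params)
    c3, c2, c1, c0 = params.pbtl_coeffs
    out = ((c3 * theta + c2) * theta + c1) * theta + c0
    return float(out) if out.ndim == 0 else out


def eca_cdl(geom: CochlearGeometry, theta, params: ModelParams = _DEFAULT):
    """Duct length (mm) at angle ``theta`` (deg) under the ECA.

    The percentage polynomial is divided by 100: the duct length is
    ``(p_BTL/100) * BTL_i``.
    """
    out = pbtl(theta, params) / 100.0 * eca_btl(geom, params)
    return out


def invert_eca(
    geom: CochlearGeometry,
    length: float,
    params: ModelParams = _DEFAULT,
    xtol_mm: float = 1e-9,
) -> float:
    """Angle (deg) at which the ECA duct length equals ``length`` (mm).

    Bracketed root-finding on [0, theta_max]; the target function is strictly
    monotone there.  Lengths below ``eca_cdl(geom, 0)`` (nonzero, because
    p_BTL(0) = 3.7 %) or above ``eca_cdl(geom, theta_max)`` are out of range.
    """
    length = float(length)
    lo = eca_cdl(geom, 0.0, params)
    hi = eca_cdl(geom, params.theta_max, params)
    if length < lo - 1e-12:
        raise ValueError(
            f"length {length:.4f} mm below the minimum representable ECA length "
            f"{lo:.4f} mm (p_BTL(0) = {params.pbtl_coeffs[3]} % of BTL)"
        )
    if length > hi + 1e-12:
        raise ValueError(
            f"length {length:.4f} mm exceeds the modelled duct at "
            f"{params.theta_max} deg ({hi:.4f} mm)"
        )
    btl = eca_btl(geom, params)
    target_pct = length / btl * 100.0
    c3, c2, c1, c0 = params.pbtl_coeffs

    def f(t: float) -> float:
        return ((c3 * t + c2) * t + c1) * t + c0 - target_pct

    # convert the mm tolerance to a percent tolerance before root finding
    theta = brentq(f, 0.0, params.theta_max, xtol=1e-10, rtol=1e-15)
    return float(theta)


def invert_model(
    geom: CochlearGeometry, length: float, model: str, params: ModelParams = _DEFAULT
) -> float:
    """Dispatch length→angle inversion by model name ('escude' or 'eca')."""
    if model == "escude":
        return float(invert_escude(geom, length, params))
    if model == "eca":
        return invert_eca(geom, length, params)
    raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")


def forward_model(
    geom: CochlearGeometry, theta, model: str, params: ModelParams = _DEFAULT
):
    """Dispatch angle→length evaluation by model name ('escude' or 'eca')."""
    if model == "escude":
        return escude_cdl(geom, theta, params)
    if model == "eca":
        return eca_cdl(geom, theta, params)
    raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")


def generate_pbtl_table(params: ModelParams = _DEFAULT) -> pd.DataFrame:
    """Tabulate the basal-turn-length percentage at 1..theta_max deg, 1° steps.

    Returns a DataFrame with columns ``theta_deg`` and ``pbtl_percent``
    (unrounded), one row per integer degree.
    """
    theta = np.arange(1, int(params.theta_max) + 1, dtype=float)
    return pd.DataFrame({"theta_deg": theta, "pbtl_percent": pbtl(theta, params)})


def write_pbtl_table(path, params: ModelParams = _DEFAULT) -> None:
    """Write the percentage table as a two-column CSV with header row."""
    generate_pbtl_table(params).to_csv(path, index=False)
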