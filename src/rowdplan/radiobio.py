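"""Radiobiological models: OER, proton RBE, and hypoxic LQ parameters.

The oxygen enhancement ratio (OER) follows a saturation-form modification of
the Wenzl-Wilkens model fitted to in-vitro proton data. The linear-quadratic
(LQ) radiosensitivity parameters depend on dose-averaged LET (``L``, keV/um)
and partial oxygen pressure (``p``, mmHg)::

    alpha(L, p) = ((a1 + a2*L) * p + (a3 + a4*L) * K) / (p + K)
    beta(p)     = (b1 * p + b2 * K) / (p + K)

and the OER at a survival level ``s`` (default 10%) is the ratio of the doses
needed for that survival at pressure ``p`` versus the aerobic reference
pressure ``p_a``::

    OER(L, p) = [sqrt(alpha(L,p)^2 - 4 beta(p) ln s) - alpha(L,p)]
              / [sqrt(alpha(L,p_a)^2 - 4 beta(p_a) ln s) - alpha(L,p_a)]
              * beta(p_a) / beta(p)

which is exactly D10(p) / D10(p_a) with D10 the LQ iso-survival dose. Voxels
at or above the normoxia threshold (60 mmHg) are treated as fully aerobic
(OER = 1), and by default the OER is floored at 1 so that mild hyperoxia
relative to p_a never *sensitises*.

Aerobic proton RBE parameters come from either a constant RBE of 1.1 or a
phenomenological model (McNamara, or a dose-averaged-LET approximation of the
Rorvik model) in which RBE_max is affine in LETd/(alpha/beta)_x and RBE_min is
affine in sqrt((alpha/beta)_x)*LETd. Hypoxic parameters scale the aerobic ones
by the OER::

    alpha_h = alpha_RBE / OER      beta_h = beta_RBE / OER^2
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "OERModelParams",
    "TissueParams",
    "RBEModelSpec",
    "alpha_oer",
    "beta_oer",
    "oer",
    "rbe_params_aerobic",
    "hypoxic_params",
    "load_rbe_coefficients",
    "RBE_MODEL_KINDS",
]

RBE_MODEL_KINDS = ("constant_1p1", "MCN", "ROR_approx")


@dataclass(frozen=True)
class OERModelParams:
    """Fitted constants of the proton OER model.

    Units: ``a1, a3`` Gy^-1; ``a2, a4`` um/(Gy*keV); ``b1, b2`` Gy^-1 as
    printed (interpreted per ``beta_convention``); pressures in mmHg.
    """

    # b1, b2 are printed in Gy^-1, so dimensionally they parametrise
    # sqrt(beta); the default 'sqrt' convention squares the saturation
    # expression, 'linear' uses it directly as beta.
    a1: float = 0.10
    a2: float = 0.0010
    a3: float = 0.010
    a4: float = 0.0100
    b1: float = 0.765
    b2: float = 0.273
    K: float = 3.0
    p_a: float = 30.0
    survival_level: float = 0.1
    normoxia_threshold: float = 60.0
    beta_convention: str = "sqrt"
    clamp_floor_one: bool = True

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "a3", "a4", "b1", "b2", "K", "p_a"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"OER constant {name} must be > 0")
        if not 0.0 < self.survival_level < 1.0:
            raise ConfigurationError("survival_level must lie in (0, 1)")
        if self.p_a <= self.K:
            raise ConfigurationError("reference pressure p_a must exceed K")
        if self.normoxia_threshold < self.p_a:
            raise ConfigurationError("normoxia_threshold must be >= p_a")
        if self.beta_convention not in ("linear", "sqrt"):
            raise ConfigurationError(
                f"beta_convention must be 'linear' or 'sqrt', got {self.beta_convention!r}"
            )


@dataclass(frozen=True)
class TissueParams:
    """Aerobic photon LQ radiosensitivity of one structure."""

    alpha_x: float = 0.10  # Gy^-1
    beta_x: float = 0.010  # Gy^-2
    label: str = "target"

    def __post_init__(self) -> None:
        if self.alpha_x <= 0 or self.beta_x <= 0:
            raise ConfigurationError("alpha_x and beta_x must be > 0")

    @property
    def alpha_beta_ratio(self) -> float:
        """(alpha/beta)_x in Gy."""
        return self.alpha_x / self.beta_x


# Photon parameter sets used throughout: (alpha/beta)_x = 10 Gy for the target
# and 3 Gy for the OAR. Absolute values are a convention; only ratios are pinned.
TARGET_TISSUE = TissueParams(alpha_x=0.10, beta_x=0.010, label="target")
OAR_TISSUE = TissueParams(alpha_x=0.105, beta_x=0.035, label="oar")


def _default_coefficient_path() -> Path:
    return Path(str(resources.files("rowdplan").joinpath("data/rbe_coefficients.json")))


def load_rbe_coefficients(path: str | Path | None = None) -> dict[str, dict[str, Any]]:
    """Load the named RBE_max/RBE_min coefficient sets from the JSON file."""
    path = Path(path) if path is not None else _default_coefficient_path()
    with open(path) as fh:
        payload = json.load(fh)
    models = {entry["model"]: entry for entry in payload["models"]}
    for name, entry in models.items():
        for key in ("alpha_coeffs", "beta_coeffs"):
            if key not in entry:
                raise ConfigurationError(f"coefficient set {name!r} lacks {key!r}")
    return models


@dataclass(frozen=True)
class RBEModelSpec:
    """Which aerobic proton RBE model supplies alpha_RBE and beta_RBE.

    ``constant_1p1`` needs no coefficients; the phenomenological kinds carry
    an immutable coefficient set loaded from the versioned coefficient file.
    """

    kind: str = "constant_1p1"
    coefficients: Mapping[str, Any] | None = None

    def __post_init__(self) -> None:
        if self.kind not in RBE_MODEL_KINDS:
            raise ConfigurationError(
                f"unknown RBE model kind {self.kind!r}; valid: {RBE_MODEL_KINDS}"
            )
        if self.kind != "constant_1p1" and self.coefficients is None:
            object.__setattr__(self, "coefficients", load_rbe_coefficients()[self.kind])

    @classmethod
    def from_kind(cls, kind: str, coefficient_path: str | Path | None = None) -> "RBEModelSpec":
        if kind == "constant_1p1":
            return cls(kind=kind)
        return cls(kind=kind, coefficients=load_rbe_coefficients(coefficient_path)[kind])


def _check_nonnegative(name: str, value: np.ndarray) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise DomainError(f"{name} must be >= 0")
    return arr


def alpha_oer(L, p, params: OERModelParams = OERModelParams()):
    """LQ linear coefficient alpha(L, p) in Gy^-1 (saturation form)."""
    L = _check_nonnegative("LET", L)
    p = _check_nonnegative("pO2", p)
    out = ((params.a1 + params.a2 * L) * p + (params.a3 + params.a4 * L) * params.K) / (
        p + params.K
    )
    return out if out.ndim else float(out)


def beta_oer(p, params: OERModelParams = OERModelParams()):
    """LQ quadratic coefficient beta(p) in Gy^-2.

    With ``beta_convention='linear'`` the saturation expression is beta
    itself; with ``'sqrt'`` the b-constants parametrise sqrt(beta) and the
    expression is squared.
    """
    p = _check_nonnegative("pO2", p)
    expr = (params.b1 * p + params.b2 * params.K) / (p + params.K)
    out = expr if params.beta_convention == "linear" else expr**2
    return out if out.ndim else float(out)


def _iso_survival_dose(alpha, beta, ln_s: float):
    """LQ dose giving survival exp(ln_s): the positive root of alpha*D + beta*D^2 = -ln_s."""
    return (np.sqrt(alpha**2 - 4.0 * beta * ln_s) - alpha) / (2.0 * beta)


def oer(L, p, params: OERModelParams = OERModelParams()):
    """Oxygen enhancement ratio at the configured survival level.

    Equals D_s(p) / D_s(p_a), the iso-survival dose ratio between pressure
    ``p`` and the aerobic reference ``p_a``. Exactly 1 at p = p_a and for
    p >= normoxia_threshold; floored at 1 when ``clamp_floor_one``.
    """
    L = _check_nonnegative("LET", L)
    p = _check_nonnegative("pO2", p)
    L, p = np.broadcast_arrays(L, p)
    ln_s = math.log(params.survival_level)
    a_h = alpha_oer(L, p, params)
    a_a = alpha_oer(L, np.full_like(p, params.p_a), params)
    b_h = beta_oer(p, params)
    b_a = beta_oer(np.full_like(p, params.p_a), params)
    num = np.sqrt(a_h**2 - 4.0 * b_h * ln_s) - a_h
    den = np.sqrt(a_a**2 - 4.0 * b_a * ln_s) - a_a
    out = num / den * (b_a / b_h)
    if params.clamp_floor_one:
        out = np.maximum(out, 1.0)
    out = np.where(p >= params.normoxia_threshold, 1.0, out)
    return out if out.ndim else float(out)


def rbe_params_aerobic(model: RBEModelSpec, letd, tissue: TissueParams):
    """Aerobic proton LQ parameters (alpha_RBE, beta_RBE) for a model.

    * ``constant_1p1``: (1.1 alpha_x, 1.1^2 beta_x), LET-independent.
    * phenomenological: alpha_RBE = alpha_x * RBE_max(LETd, (a/b)_x) and
      beta_RBE = beta_x * RBE_min(LETd, (a/b)_x)^2, with the affine
      coefficient sets from the model's coefficient file. RBE_min is floored
      at 0 (it only approaches 0 far outside the therapeutic LET range).
    """
    letd = _check_nonnegative("LETd", letd)
    if model.kind == "constant_1p1":
        shape = np.shape(letd)
        a = np.full(shape, 1.1 * tissue.alpha_x) if shape else 1.1 * tissue.alpha_x
        b = np.full(shape, 1.1**2 * tissue.beta_x) if shape else 1.1**2 * tissue.beta_x
        return a, b
    if model.coefficients is None:  # pragma: no cover - guarded in __post_init__
        raise ConfigurationError(f"model {model.kind!r} has no coefficient set loaded")
    ac = model.coefficients["alpha_coeffs"]
    bc = model.coefficients["beta_coeffs"]
    abx = tissue.alpha_beta_ratio
    rbe_max = ac["intercept"] + ac["slope_letd_over_abx"] * letd / abx
    rbe_min = bc["intercept"] + bc["slope_sqrt_abx_letd"] * math.sqrt(abx) * letd
    rbe_min = np.maximum(rbe_min, 0.0)
    a = tissue.alpha_x * rbe_max
    b = tissue.beta_x * rbe_min**2
    if np.ndim(letd):
        return np.asarray(a), np.asarray(b)
    return float(a), float(b)


def hypoxic_params(alpha_rbe, beta_rbe, oer_value):
    """Hypoxic proton LQ parameters (alpha_h, beta_h) = (alpha/OER, beta/OER^2)."""
    oer_value = np.asarray(oer_value, dtype=float)
    if np.any(oer_value <= 0):
        raise DomainError("OER must be > 0")
    alpha_h = np.asarray(alpha_rbe, dtype=float) / oer_value
    beta_h = np.asarray(beta_rbe, dtype=float) / oer_value**2
    if alpha_h.ndim == 0:
        return float(alpha_h), float(beta_h)
    return alpha_h, beta_h
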