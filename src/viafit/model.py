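"""Model equations for avascular tumour-cell viability under treatment.

The cell phase is described by a nondimensional volume fraction
``alpha`` in [0, 1] and the oxygen level by a nondimensional
concentration ``c`` (1 in the surrounding medium).  The local dynamics
are a logistic growth term saturating in oxygen and a death term that
increases with oxygen-dependent cytotoxicity:

    d(alpha)/dt = (1 + s1) * alpha * (1 - alpha) * c / (1 + s1 * c)
                  - (s2 + s3 * c) * alpha / (1 + s4 * c)

Oxygen is consumed at the Michaelis–Menten-like rate
``Q * alpha * c / (1 + Q1 * c)``.

All six parameters are nondimensional and nonnegative; time is measured
in hours.  With oxygen held constant the dynamics reduce to a scalar
logistic-with-death ODE with a closed-form solution, used throughout the
package as a solver oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np

__all__ = [
    "ModelParams",
    "growth_term",
    "death_term",
    "dalpha_dt",
    "consumption_term",
    "closed_form_alpha",
    "steady_state",
]

PARAM_NAMES = ("s1", "s2", "s3", "s4", "Q", "Q1")


@dataclass(frozen=True)
class ModelParams:
    """The six nondimensional model parameters.

    ``s1`` controls proliferation (growth saturation in oxygen);
    ``s2``, ``s3``, ``s4`` control cell death (baseline, oxygen-linked,
    and death saturation respectively); ``Q`` and ``Q1`` set the oxygen
    consumption rate and its saturation.
    """

    s1: float = 0.0
    s2: float = 0.0
    s3: float = 0.0
    s4: float = 0.0
    Q: float = 0.0
    Q1: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise TypeError(f"parameter {f.name} must be a real number, got {v!r}")
            v = float(v)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
            object.__setattr__(self, f.name, v)

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelParams":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))

    def replace(self, **kwargs: float) -> "ModelParams":
        d = self.to_dict()
        d.update(kwargs)
        return ModelParams.from_dict(d)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)


def _validate_state(alpha, c) -> tuple[np.ndarray, np.ndarray]:
    alpha = np.asarray(alpha, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("alpha must lie in [0, 1]")
    if np.any(c < 0):
        raise ValueError("c must be >= 0")
    return alpha, c


def growth_term(alpha, c, p: ModelParams):
    """Proliferation rate (per hour): (1+s1)·α(1−α)·C / (1+s1·C).

    At C = 1 the s1 factors cancel exactly and the term reduces to pure
    logistic growth α(1−α).
    """
    alpha, c = _validate_state(alpha, c)
    # factor order matters: at c = 1 the coefficient is (1+s1)/(1+s1),
    # which cancels exactly in floating point when computed first
    return ((1.0 + p.s1) * c / (1.0 + p.s1 * c)) * alpha * (1.0 - alpha)


def death_term(alpha, c, p: ModelParams):
    """Death rate (per hour): (s2 + s3·C)·α / (1 + s4·C)."""
    alpha, c = _validate_state(alpha, c)
    return (p.s2 + p.s3 * c) * alpha / (1.0 + p.s4 * c)


def dalpha_dt(alpha, c, p: ModelParams):
    """Net rate of change of the cell fraction: growth − death."""
    alpha, c = _validate_state(alpha, c)
    return _dalpha_dt_raw(alpha, c, p)


def _dalpha_dt_raw(alpha, c, p: ModelParams):
    # unvalidated fast path for the time stepper (RK4 stages may leave
    # [0,1] by round-off; the formula itself is well defined there)
    g = ((1.0 + p.s1) * c / (1.0 + p.s1 * c)) * alpha * (1.0 - alpha)
    d = (p.s2 + p.s3 * c) * alpha / (1.0 + p.s4 * c)
    return g - d


def consumption_term(alpha, c, p: ModelParams):
    """Oxygen consumption rate: Q·α·C / (1 + Q1·C)."""
    alpha, c = _validate_state(alpha, c)
    return p.Q * alpha * c / (1.0 + p.Q1 * c)


def _rates(c_const: float, p: ModelParams) -> tuple[float, float]:
    """Effective logistic rate a and death rate b at fixed oxygen."""
    a = (1.0 + p.s1) * c_const / (1.0 + p.s1 * c_const)
    b = (p.s2 + p.s3 * c_const) / (1.0 + p.s4 * c_const)
    return a, b


def closed_form_alpha(alpha0, c_const: float, p: ModelParams, t):
    """Exact solution of dα/dt = (a−b)α − aα² with oxygen frozen.

    a = (1+s1)C/(1+s1·C), b = (s2+s3·C)/(1+s4·C).  For r = a−b ≠ 0,

        α(t) = r·α0·e^{rt} / (r + a·α0·(e^{rt} − 1))

    and for r = 0, α(t) = α0 / (1 + a·α0·t).
    """
    alpha0 = np.asarray(alpha0, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(alpha0 < 0) or np.any(alpha0 > 1):
        raise ValueError("alpha0 must lie in [0, 1]")
    if c_const < 0:
        raise ValueError("c_const must be >= 0")
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    a, b = _rates(float(c_const), p)
    r = a - b
    if r == 0.0:
        out = alpha0 / (1.0 + a * alpha0 * t)
    elif r > 0.0:
        # growth-dominated: write with e^{-rt} so large t cannot overflow
        emrt = np.exp(-r * t)
        out = r * alpha0 / (r * emrt + a * alpha0 * (1.0 - emrt))
    else:
        ert = np.exp(r * t)
        out = r * alpha0 * ert / (r + a * alpha0 * (ert - 1.0))
    return np.clip(out, 0.0, 1.0)


def steady_state(c_const: float, p: ModelParams) -> float:
    """Long-time cell fraction at fixed oxygen: max(0, 1 − b/a).

    Extinction (0) whenever death dominates (a ≤ b, a > 0).  The
    degenerate case a = 0 returns 1 if b = 0 (every point is a fixed
    point; the initial fraction persists, bounded by the carrying
    capacity) and 0 if b > 0 (pure decay).
    """
    if c_const < 0:
        raise ValueError("c_const must be >= 0")
    a, b = _rates(float(c_const), p)
    if a == 0.0:
        return 1.0 if b == 0.0 else 0.0
    return max(0.0, 1.0 - b / a)
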