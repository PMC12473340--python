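"""Two-pool parameter estimation: multi-offset nonlinear fit and single-offset solve.

Two estimation routes are provided:

* :func:`fit_multioffset` — nonlinear least squares of the full normalized
  two-pool signal over a set of (flip angle, offset) points, yielding
  F, R*M0A, T2A and T2B with RB fixed and RA constrained to the value
  measured by VFA T1 mapping.
* :func:`solve_single_offset` — the accelerated two-parameter route: three
  model parameters (T2B, RA*T2A, R*M0A) are held at literature-constant
  values, the high-offset image serves as the MT-free reference, and F is
  obtained in closed form from a single normalized low-offset measurement.

Both routes apply the relative-B1 scale to the MT flip angle and the B0
shift to the frequency offset before any model evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .mt_physics import (
    OFFSET_FLOOR_HZ,
    RFPulse,
    TwoPoolParams,
    omega1_cwpe,
    omega1_rms,
    ramani_signal_arrays,
    rrfb,
)

__all__ = [
    "QmtFitResult",
    "SingleOffsetConstants",
    "UnderDeterminedError",
    "DegenerateDataError",
    "SingularSolveError",
    "fit_multioffset",
    "solve_single_offset",
    "f_from_pool_ratio",
]


class UnderDeterminedError(ValueError):
    """Fewer measurement points than free parameters."""


class DegenerateDataError(ValueError):
    """The measurements carry no MT information (e.g. all signals at unity)."""


class SingularSolveError(ArithmeticError):
    """The single-offset closed form has a vanishing denominator."""


@dataclass(frozen=True)
class SingleOffsetConstants:
    """Parameters held fixed in the two-parameter (single-offset) qMT solve.

    Defaults are the literature-constant muscle values: T2B = 6 us,
    RA*T2A = 0.025, R*M0A = 48 1/s.
    """

    t2b: float = 6e-6
    ra_t2a: float = 0.025
    rm0a: float = 48.0

    def __post_init__(self) -> None:
        if min(self.t2b, self.ra_t2a, self.rm0a) <= 0:
            raise ValueError("single-offset constants must be positive")


@dataclass
class QmtFitResult:
    """Outcome of a two-pool parameter estimate."""

    params: TwoPoolParams
    f: float
    residual_rms: float
    n_points: int
    converged: bool
    warning: str | None = field(default=None)


def f_from_pool_ratio(F: float) -> float:
    """Macromolecular fraction f = F / (1 + F) from the pool-size ratio."""
    if F < 0:
        raise ValueError("pool-size ratio F must be non-negative")
    return F / (1.0 + F)


# fit bounds (physiologic ranges; the fit runs in log space to keep
# every parameter strictly positive)
_BOUNDS = {
    "F": (1e-4, 0.5),
    "rm0a": (1.0, 200.0),
    "T2A": (5e-3, 200e-3),
    "T2B": (1e-6, 30e-6),
}
# deterministic multistart: nominal init then symmetric +/-50% perturbations
_RESTART_SCALES = (1.0, 1.5, 0.5)


def _prepare_points(
    signals: list[tuple[float, RFPulse]],
    mode: str,
    b1_rel: float,
    b0_shift_hz: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sn = np.array([s for s, _ in signals], dtype=float)
    pulses = [p.scaled(b1_rel, b0_shift_hz) for _, p in signals]
    if mode == "ramani":
        w1 = np.array([omega1_cwpe(p) for p in pulses])
    elif mode == "yarnykh":
        w1 = np.array([omega1_rms(p) for p in pulses])
    else:
        raise ValueError(f"unknown RF approximation mode {mode!r}")
    offsets = np.array([p.offset_hz for p in pulses])
    if np.any(offsets < OFFSET_FLOOR_HZ):
        raise ValueError(
            f"B0-shifted offsets fall below the {OFFSET_FLOOR_HZ:.0f} Hz lineshape floor"
        )
    return sn, w1, offsets


def fit_multioffset(
    signals: list[tuple[float, RFPulse]],
    ra: float,
    mode: str = "ramani",
    b1_rel: float = 1.0,
    b0_shift_hz: float = 0.0,
    rb: float = 1.0,
    x0: dict | None = None,
) -> QmtFitResult:
    """Fit (F, rm0a, T2A, T2B) to normalized multi-offset MT measurements.

    Parameters
    ----------
    signals:
        Sequence of (Sn, pulse) pairs; Sn is the signal normalized to the
        MT-free volume.  At least 6 distinct (flip, offset) points required.
    ra:
        Free-pool longitudinal rate in 1/s, fixed during the fit (from VFA T1).
    mode:
        ``"ramani"`` (CW power equivalent) or ``"yarnykh"`` (RMS) pulse
        approximation.
    b1_rel, b0_shift_hz:
        Relative transmit field (1.0 nominal) applied to MT flip angles and
        off-resonance shift in Hz subtracted from the nominal offsets.
    rb:
        Bound-pool longitudinal rate, fixed (default 1/s).
    x0:
        Optional initial values overriding the defaults, keyed by parameter.
    """
    if ra <= 0:
        raise ValueError("ra must be positive")
    if not 0.5 <= b1_rel <= 1.5:
        raise ValueError("b1_rel outside the plausible [0.5, 1.5] range")
    sn_all, w1, offsets = _prepare_points(signals, mode, b1_rel, b0_shift_hz)
    distinct = {(round(p.flip_angle_deg, 6), round(p.offset_hz, 6)) for _, p in signals}
    if len(distinct) < 6:
        raise UnderDeterminedError(
            f"need >= 6 distinct (flip, offset) points, got {len(distinct)}"
        )
    if np.any(~np.isfinite(sn_all)) or np.any(sn_all <= 0) or np.any(sn_all > 1.5):
        raise ValueError("normalized signals must be finite and in (0, 1.5]")
    if np.all(sn_all > 0.995):
        raise DegenerateDataError(
            "all signals within 0.5% of the reference: no MT attenuation to fit"
        )

    names = ("F", "rm0a", "T2A", "T2B")
    lo = np.log([_BOUNDS[k][0] for k in names])
    hi = np.log([_BOUNDS[k][1] for k in names])
    init = {"F": 0.07, "rm0a": 48.0, "T2A": 0.025 / ra, "T2B": 6e-6}
    if x0:
        init.update(x0)
    base = np.array([init[k] for k in names])

    def residuals(logp: np.ndarray) -> np.ndarray:
        F, rm0a, t2a, t2b = np.exp(logp)
        model = ramani_signal_arrays(F, rm0a, ra, rb, t2a, t2b, w1, offsets)
        return model - sn_all

    best = None
    for scale in _RESTART_SCALES:
        start = np.clip(np.log(base * scale), lo, hi)
        try:
            res = least_squares(
                residuals, start, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12
            )
        except (ValueError, FloatingPointError):
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None or not np.all(np.isfinite(best.x)):
        return QmtFitResult(
            params=TwoPoolParams(
                F=init["F"], rm0a=init["rm0a"], RA=ra, T2A=init["T2A"], T2B=init["T2B"], RB=rb
            ),
            f=float("nan"),
            residual_rms=float("inf"),
            n_points=len(sn_all),
            converged=False,
            warning="optimizer failed on every restart",
        )

    F, rm0a, t2a, t2b = np.exp(best.x)
    params = TwoPoolParams(F=float(F), rm0a=float(rm0a), RA=ra, T2A=float(t2a), T2B=float(t2b), RB=rb)
    rms = float(np.sqrt(np.mean(best.fun**2)))
    return QmtFitResult(
        params=params,
        f=params.f,
        residual_rms=rms,
        n_points=len(sn_all),
        converged=bool(best.success),
    )


def solve_single_offset(
    sn_low: float,
    pulse_low: RFPulse,
    ra: float,
    constants: SingleOffsetConstants | None = None,
    b1_rel: float = 1.0,
    b0_shift_hz: float = 0.0,
    rb: float = 1.0,
) -> QmtFitResult:
    """Closed-form pool-size-ratio estimate from one normalized low-offset signal.

    With R_RFB evaluated at the B1-scaled, B0-shifted low-offset pulse (CW
    power-equivalent approximation) and D the direct-saturation factor
    ``1 + (omega1_cwpe / 2 pi df)^2 / (RA T2A)``:

        F / RA = (R_RFB + RB + rm0a) (1 - Sn D)
                 / (rm0a (Sn (R_RFB + RB) - RB))

    then F = ra * (F/RA) and f = F / (1 + F).  The free-pool T2A implied by
    the fixed product is ``ra_t2a / ra``.
    """
    if constants is None:
        constants = SingleOffsetConstants()
    if not (0 < sn_low < 1):
        raise ValueError("sn_low must lie in (0, 1)")
    if ra <= 0:
        raise ValueError("ra must be positive")
    pulse = pulse_low.scaled(b1_rel, b0_shift_hz)
    if pulse.offset_hz < OFFSET_FLOOR_HZ:
        raise ValueError(
            f"B0-shifted offset below the {OFFSET_FLOOR_HZ:.0f} Hz lineshape floor"
        )
    w1 = omega1_cwpe(pulse)
    r_rfb = rrfb(w1, pulse.offset_hz, constants.t2b)
    direct = 1.0 + (w1 / (2.0 * math.pi * pulse.offset_hz)) ** 2 / constants.ra_t2a
    denom = constants.rm0a * (sn_low * (r_rfb + rb) - rb)
    if abs(denom) < 1e-12:
        raise SingularSolveError(
            "single-offset denominator vanishes: Sn*(R_RFB+RB) == RB"
        )
    f_over_ra = (r_rfb + rb + constants.rm0a) * (1.0 - sn_low * direct) / denom
    F = ra * f_over_ra
    warning = None
    if F < 0:
        warning = "non-physical negative pool-size ratio"
        f_val = F / (1.0 + F)
    else:
        f_val = f_from_pool_ratio(F)
    t2a = constants.ra_t2a / ra
    params = TwoPoolParams(
        F=max(F, 0.0), rm0a=constants.rm0a, RA=ra, T2A=t2a, T2B=constants.t2b, RB=rb
    )
    return QmtFitResult(
        params=params,
        f=f_val,
        residual_rms=0.0,
        n_points=1,
        converged=warning is None,
        warning=warning,
    )
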