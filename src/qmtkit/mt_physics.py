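"""Pulse math, bound-pool lineshape, and the pulsed two-pool steady-state signal model.

The two-pool model describes magnetization exchange between free water
protons (pool A, millisecond-scale T2) and protons bound to macromolecules
(pool B, microsecond-scale T2).  An off-resonance RF pulse saturates the
bound pool through its absorption lineshape; exchange transfers that
saturation to the observable free pool.  All qMT computations in this
package (multi-offset fitting, the single-offset closed-form solve, and the
synthetic simulator) are built on the forward model in this module.

Two continuous-wave approximations of the pulsed MT irradiation are
supported and selected by ``mode``:

* ``"ramani"`` — continuous-wave power equivalent, averaging the RF power
  over the full pulse-train repetition time TR.
* ``"yarnykh"`` — root-mean-square amplitude, averaging over the pulse
  duration only.

Since the pulse duration is shorter than TR, the RMS convention always
implies at least as much saturation power as the CWPE convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import erf

__all__ = [
    "RFPulse",
    "TwoPoolParams",
    "OFFSET_FLOOR_HZ",
    "pulse_envelope",
    "flip_to_peak_omega1",
    "omega1_cwpe",
    "omega1_rms",
    "super_lorentzian_g",
    "rrfb",
    "ramani_signal",
]

#: Lowest frequency offset (Hz) at which the super-Lorentzian lineshape is
#: evaluated.  The orientationally averaged lineshape diverges on resonance;
#: rather than extrapolate we refuse to evaluate below this floor.
OFFSET_FLOOR_HZ = 100.0

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

# Fixed-order Gauss-Legendre rule used by the lineshape.  The integrand has
# a sharp (though finite) feature where 3cos^2(theta) - 1 vanishes, so the
# interval [0, pi/2] is split at the magic angle and each panel gets its own
# rule; at this order refining the rule changes G by < 1e-6 relative at
# muscle-scale T2B.  Nodes are cached at import for bit-stable results.
_GL_ORDER = 512
_MAGIC_ANGLE = math.acos(1.0 / math.sqrt(3.0))


def _gl_nodes(order: int = _GL_ORDER) -> tuple[np.ndarray, np.ndarray]:
    x, w = leggauss(order)
    theta_parts, weight_parts = [], []
    for a, b in ((0.0, _MAGIC_ANGLE), (_MAGIC_ANGLE, math.pi / 2.0)):
        mid, half = (a + b) / 2.0, (b - a) / 2.0
        theta_parts.append(mid + half * x)
        weight_parts.append(w * half)
    return np.concatenate(theta_parts), np.concatenate(weight_parts)


_GL_THETA, _GL_WEIGHTS = _gl_nodes()


class UnsupportedPulseShapeError(ValueError):
    """The requested RF pulse shape is not implemented."""


class OnResonanceError(ValueError):
    """Lineshape requested below the on-resonance evaluation floor."""


@dataclass(frozen=True)
class RFPulse:
    """One off-resonance MT saturation pulse within a steady pulse train.

    Parameters
    ----------
    flip_angle_deg:
        Nominal MT flip angle in degrees (integral of omega1 over the pulse).
    duration_s:
        Pulse duration t_mt in seconds.
    bandwidth_hz:
        Spectral full width at half maximum of the Gaussian pulse in Hz.
    offset_hz:
        Nominal frequency offset of the irradiation in Hz (>= 0).
    tr_s:
        Repetition time of the MT pulse train in seconds.
    shape:
        Envelope shape; only ``"gaussian"`` is supported.
    """

    flip_angle_deg: float
    duration_s: float
    bandwidth_hz: float
    offset_hz: float
    tr_s: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.flip_angle_deg <= 0:
            raise ValueError("flip_angle_deg must be positive")
        if not (0 < self.duration_s < self.tr_s):
            raise ValueError("duration_s must lie in (0, tr_s)")
        if self.bandwidth_hz <= 0:
            raise ValueError("bandwidth_hz must be positive")
        if self.offset_hz < 0:
            raise ValueError("offset_hz must be non-negative")

    @property
    def sigma_t(self) -> float:
        """Temporal standard deviation implied by the spectral FWHM.

        Gaussian Fourier pair: sigma_f = FWHM / (2 sqrt(2 ln 2)),
        sigma_t = 1 / (2 pi sigma_f).
        """
        sigma_f = self.bandwidth_hz / _FWHM_TO_SIGMA
        return 1.0 / (2.0 * math.pi * sigma_f)

    def scaled(self, b1_rel: float = 1.0, b0_shift_hz: float = 0.0) -> "RFPulse":
        """Pulse as experienced by a voxel: B1-scaled flip, B0-shifted offset."""
        return replace(
            self,
            flip_angle_deg=self.flip_angle_deg * b1_rel,
            offset_hz=self.offset_hz - b0_shift_hz,
        )


@dataclass(frozen=True)
class TwoPoolParams:
    """Tissue parameters of the binary spin-bath (two-pool) model.

    Attributes
    ----------
    F:
        Pool-size ratio M0B / M0A (dimensionless).
    rm0a:
        Composite exchange rate R * M0A, bound -> free, in 1/s.
    RA:
        Longitudinal relaxation rate of the free pool in 1/s.
    RB:
        Longitudinal relaxation rate of the bound pool in 1/s (conventionally
        fixed at 1/s; it has little influence on the other parameters).
    T2A:
        Transverse relaxation time of the free pool in seconds.
    T2B:
        Transverse relaxation time of the bound pool in seconds.
    """

    F: float
    rm0a: float
    RA: float
    T2A: float
    T2B: float
    RB: float = 1.0

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be non-negative")
        for name in ("rm0a", "RA", "RB", "T2A", "T2B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.T2B >= self.T2A:
            raise ValueError("T2B must be shorter than T2A")

    @property
    def f(self) -> float:
        """Macromolecular fraction f = M0B / (M0A + M0B) = F / (1 + F)."""
        return self.F / (1.0 + self.F)


def _envelope_integrals(pulse: RFPulse) -> tuple[float, float]:
    """(integral of unit-peak envelope, integral of its square) over the pulse.

    The envelope is exp(-(t - t_c)^2 / (2 sigma_t^2)) centered at t_c =
    duration/2 and truncated to [0, duration]; both integrals have erf
    closed forms.
    """
    s = pulse.sigma_t
    h = pulse.duration_s / 2.0
    # int_{-h}^{h} exp(-x^2 / (2 s^2)) dx
    i1 = s * math.sqrt(math.pi / 2.0) * 2.0 * erf(h / (s * math.sqrt(2.0)))
    # int_{-h}^{h} exp(-x^2 / s^2) dx
    i2 = s * math.sqrt(math.pi) * erf(h / s)
    return i1, i2


def pulse_envelope(pulse: RFPulse, peak_rate: float):
    """Return the time-domain RF amplitude omega1(t) in rad/s.

    The returned callable evaluates
    ``peak_rate * exp(-(t - t_c)^2 / (2 sigma_t^2))`` for t within
    [0, duration] and zero outside, with t_c at the pulse center.
    """
    if pulse.shape != "gaussian":
        raise UnsupportedPulseShapeError(
            f"unsupported pulse shape {pulse.shape!r}; only 'gaussian' is implemented"
        )
    sigma = pulse.sigma_t
    center = pulse.duration_s / 2.0
    duration = pulse.duration_s

    def omega1(t):
        t = np.asarray(t, dtype=float)
        inside = (t >= 0.0) & (t <= duration)
        val = peak_rate * np.exp(-((t - center) ** 2) / (2.0 * sigma**2))
        return np.where(inside, val, 0.0)

    return omega1


def flip_to_peak_omega1(pulse: RFPulse) -> float:
    """Peak omega1 (rad/s) so the truncated envelope integrates to the flip angle."""
    if pulse.shape != "gaussian":
        raise UnsupportedPulseShapeError(
            f"unsupported pulse shape {pulse.shape!r}; only 'gaussian' is implemented"
        )
    theta_rad = math.radians(pulse.flip_angle_deg)
    i1, _ = _envelope_integrals(pulse)
    if not (i1 > 0 and math.isfinite(i1)):
        raise FloatingPointError("degenerate pulse envelope integral")
    return theta_rad / i1


def _omega1_sq_integral(pulse: RFPulse) -> float:
    """Integral of omega1(t)^2 over the pulse duration, rad^2/s."""
    peak = flip_to_peak_omega1(pulse)
    _, i2 = _envelope_integrals(pulse)
    return peak**2 * i2


def omega1_cwpe(pulse: RFPulse) -> float:
    """Continuous-wave power-equivalent amplitude (rad/s), power averaged over TR.

    omega1_cwpe^2 = (1/TR) * int_0^{t_mt} omega1(t)^2 dt
    """
    return math.sqrt(_omega1_sq_integral(pulse) / pulse.tr_s)


def omega1_rms(pulse: RFPulse) -> float:
    """Root-mean-square amplitude (rad/s), power averaged over the pulse duration.

    omega1_rms^2 = (1/t_mt) * int_0^{t_mt} omega1(t)^2 dt
    """
    return math.sqrt(_omega1_sq_integral(pulse) / pulse.duration_s)


def super_lorentzian_g(offset_hz, t2b: float, order: int | None = None):
    """Super-Lorentzian absorption lineshape G(offset; T2B) in seconds.

    Orientational average over the dipolar-broadened semi-solid spectrum:

        G = int_0^{pi/2} sin(theta) sqrt(2/pi) T2B/|3cos^2(theta)-1|
            * exp(-2 (2 pi df T2B / (3cos^2(theta)-1))^2) dtheta

    evaluated by a fixed-order Gauss-Legendre rule.  Accepts scalar or array
    offsets; offsets below :data:`OFFSET_FLOOR_HZ` raise, since the integrand
    is singular on resonance.
    """
    if t2b <= 0:
        raise ValueError("t2b must be positive")
    offset = np.asarray(offset_hz, dtype=float)
    if np.any(offset < OFFSET_FLOOR_HZ):
        raise OnResonanceError(
            f"lineshape requested below the {OFFSET_FLOOR_HZ:.0f} Hz floor; "
            "the super-Lorentzian is singular on resonance and this package "
            "does not extrapolate below the floor"
        )
    if order is None:
        theta, weights = _GL_THETA, _GL_WEIGHTS
    else:
        theta, weights = _gl_nodes(order)
    u = 3.0 * np.cos(theta) ** 2 - 1.0
    u = np.where(np.abs(u) < 1e-12, 1e-12, u)
    # broadcast offsets against quadrature nodes
    arg = 2.0 * math.pi * offset[..., None] * t2b / u
    integrand = (
        np.sin(theta)
        * math.sqrt(2.0 / math.pi)
        * (t2b / np.abs(u))
        * np.exp(-2.0 * arg**2)
    )
    g = integrand @ weights
    return g if g.ndim else float(g)


def rrfb(omega1_eq, offset_hz, t2b: float):
    """Bound-pool RF saturation rate R_RFB = pi * omega1_eq^2 * G(offset; T2B), 1/s."""
    omega1_eq = np.asarray(omega1_eq, dtype=float)
    if np.any(omega1_eq < 0):
        raise ValueError("omega1_eq must be non-negative")
    out = math.pi * omega1_eq**2 * super_lorentzian_g(offset_hz, t2b)
    return out if out.ndim else float(out)


def _omega1_eq(pulse: RFPulse, mode: str) -> float:
    if mode == "ramani":
        return omega1_cwpe(pulse)
    if mode == "yarnykh":
        return omega1_rms(pulse)
    raise ValueError(f"unknown RF approximation mode {mode!r}")


def ramani_signal(params: TwoPoolParams, pulse: RFPulse, mode: str = "ramani") -> float:
    """Normalized steady-state MT-weighted signal Sn of the two-pool model.

    With X = rm0a * F / RA, D = 1 + (omega1_eq / (2 pi df))^2 / (RA * T2A)
    and R_RFB the bound-pool saturation rate:

        Sn = (RB * X + RB + R_RFB + rm0a)
             / (X * (RB + R_RFB) + D * (R_RFB + RB + rm0a))

    The signal is normalized to the MT-free acquisition, so the free-pool
    equilibrium magnetization and receiver scaling cancel.  Sn lies in
    (0, 1] for every physical parameter set.
    """
    for name in ("F", "rm0a", "RA", "RB", "T2A", "T2B"):
        if not math.isfinite(getattr(params, name)):
            raise ValueError(f"non-finite parameter {name}")
    omega1_eq = _omega1_eq(pulse, mode)
    return float(
        ramani_signal_arrays(
            params.F,
            params.rm0a,
            params.RA,
            params.RB,
            params.T2A,
            params.T2B,
            omega1_eq,
            pulse.offset_hz,
        )
    )


def ramani_signal_arrays(F, rm0a, RA, RB, t2a, t2b, omega1_eq, offset_hz):
    """Vectorized core of :func:`ramani_signal` (broadcasts over all inputs).

    ``omega1_eq`` must already embody the chosen RF approximation (and any B1
    scaling); ``offset_hz`` must already include any B0 shift.
    """
    F = np.asarray(F, dtype=float)
    offset = np.asarray(offset_hz, dtype=float)
    omega1_eq = np.asarray(omega1_eq, dtype=float)
    r_rfb = math.pi * omega1_eq**2 * super_lorentzian_g(offset, t2b)
    x = rm0a * F / RA
    direct = 1.0 + (omega1_eq / (2.0 * math.pi * offset)) ** 2 / (RA * t2a)
    num = RB * x + RB + r_rfb + rm0a
    den = x * (RB + r_rfb) + direct * (r_rfb + RB + rm0a)
    return num / den
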