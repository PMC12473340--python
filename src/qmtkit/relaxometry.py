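"""Relaxometry utilities: VFA T1 mapping, dual-echo B0, spoiled-GRE forward model.

Variable-flip-angle (VFA) T1 mapping fits the linearized spoiled-gradient
echo equation S/sin(a) = E1 * S/tan(a) + M0 (1 - E1) across flip angles,
after scaling the nominal angles by the relative transmit field.  B0 maps
come from the phase difference of a dual-echo acquisition, wrapped to
(-pi, pi] per voxel (temporal unwrapping only; muscle off-resonance at 3 T
stays well inside the unaliased +/- 1/(2 dTE) range).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VfaSet",
    "NonPhysicalT1Error",
    "spgr_signal",
    "vfa_fit_t1",
    "b0_from_dual_echo",
]


class NonPhysicalT1Error(ValueError):
    """The linearized VFA slope falls outside (0, 1)."""


@dataclass(frozen=True)
class VfaSet:
    """A variable-flip-angle measurement of one tissue or ROI."""

    signals: tuple
    flips_deg: tuple = (5.0, 15.0, 25.0)
    tr: float = 0.025
    b1_rel: float = 1.0

    def __post_init__(self) -> None:
        if len(self.signals) != len(self.flips_deg):
            raise ValueError("signals and flips_deg must have equal length")
        if len(set(np.round(self.flips_deg, 9))) < 2:
            raise ValueError("need >= 2 distinct flip angles")
        if any(s <= 0 for s in self.signals):
            raise ValueError("signals must be positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")


def spgr_signal(m0, t1, flip_rad, tr):
    """Steady-state spoiled gradient echo: S = M0 sin(a) (1-E1)/(1-E1 cos(a))."""
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0) or np.any(np.asarray(tr) <= 0):
        raise ValueError("t1 and tr must be positive")
    e1 = np.exp(-tr / t1)
    flip = np.asarray(flip_rad, dtype=float)
    out = m0 * np.sin(flip) * (1.0 - e1) / (1.0 - e1 * np.cos(flip))
    return out if np.ndim(out) else float(out)


def vfa_fit_t1(vfa: VfaSet) -> tuple[float, float]:
    """(T1 seconds, M0) from the linearized VFA fit with B1-scaled flips."""
    flips = np.radians(np.asarray(vfa.flips_deg, dtype=float)) * vfa.b1_rel
    s = np.asarray(vfa.signals, dtype=float)
    y = s / np.sin(flips)
    x = s / np.tan(flips)
    slope, intercept = np.polyfit(x, y, 1)
    if not 0.0 < slope < 1.0:
        raise NonPhysicalT1Error(
            f"VFA slope {slope:.4g} outside (0, 1); cannot convert to a T1"
        )
    t1 = -vfa.tr / np.log(slope)
    m0 = intercept / (1.0 - slope)
    return float(t1), float(m0)


def b0_from_dual_echo(phase1, phase2, te1: float, te2: float):
    """Off-resonance in Hz from two echo phases (radians).

    df = wrap(phase2 - phase1) / (2 pi (te2 - te1)), the wrap mapping the
    difference into (-pi, pi].  Positive df means the voxel resonates above
    nominal frequency.
    """
    if te2 <= te1:
        raise ZeroDivisionError("te2 must be strictly greater than te1")
    dphi = np.asarray(phase2, dtype=float) - np.asarray(phase1, dtype=float)
    wrapped = np.angle(np.exp(1j * dphi))
    # np.angle returns (-pi, pi]; the branch point maps -pi -> pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    out = wrapped / (2.0 * np.pi * (te2 - te1))
    return out if np.ndim(out) else float(out)
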