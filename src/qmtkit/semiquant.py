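"""Semi-quantitative MT indices: MT_sat (with B1 correction) and MTR / MTR_corr.

MT_sat is the fractional saturation imposed by a single MT pulse per TR,
estimated from a spoiled-gradient-echo triplet (proton-density-weighted,
MT-weighted, T1-weighted).  It is expressed in percent units (p.u.) at
every interface of this module.  MTR = 1 - S_mt/S_ref is stored as a
fraction; its B1 dependence can be removed with a per-subject k factor
fitted on a reference tissue (tibialis posterior by convention).

``b1_error`` throughout means ``b1_rel - 1`` so that every correction is
the identity at nominal transmit field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FlashTriplet",
    "MtrCorrectionFit",
    "MTSAT_B1_FACTOR",
    "estimate_A_R1",
    "mtsat_delta",
    "mtsat_b1_correct",
    "compute_mtr",
    "fit_k",
    "apply_mtr_correction",
]

#: Empirical factor of the semi-empirical MT_sat B1 correction.
MTSAT_B1_FACTOR = 0.4


class EstimationError(ValueError):
    """Signal ordering incompatible with the small-angle FLASH model."""


class CannotFitError(ValueError):
    """The k-factor regression cannot be performed on the given data."""


@dataclass(frozen=True)
class FlashTriplet:
    """PDw / MTw / T1w spoiled-gradient-echo measurement of one tissue.

    Flip angles in degrees (nominal), common repetition time ``tr`` in
    seconds per volume.  Signals are arbitrary (but common) units.
    """

    s_pdw: float
    s_mtw: float
    s_t1w: float
    alpha_pdw_deg: float = 4.0
    alpha_mtw_deg: float = 10.0
    alpha_t1w_deg: float = 20.0
    tr: float = 0.05

    def __post_init__(self) -> None:
        if min(self.s_pdw, self.s_mtw, self.s_t1w) <= 0:
            raise ValueError("signals must be positive")
        if self.alpha_pdw_deg >= self.alpha_t1w_deg:
            raise ValueError("PDw flip angle must be smaller than T1w flip angle")
        if self.tr <= 0:
            raise ValueError("tr must be positive")


@dataclass(frozen=True)
class MtrCorrectionFit:
    """Per-subject linear MTR-vs-B1-error fit on the reference tissue.

    ``mtr = intercept + k_specific * b1_error``; the tissue-independent
    factor is ``k = k_specific / intercept``.
    """

    k_specific: float
    mtr_at_nominal_b1: float
    k: float
    n_voxels: int
    r_squared: float


def estimate_A_R1(
    triplet: FlashTriplet, b1_rel: float = 1.0
) -> tuple[float, float]:
    """Amplitude A and longitudinal rate R1 from the PDw / T1w pair.

    Uses the rational small-angle spoiled-gradient-echo estimators (exact
    inverses of S = A * alpha * R1 TR / (alpha^2/2 + R1 TR)); the nominal
    flip angles are scaled by ``b1_rel`` first.
    """
    a_p = np.radians(triplet.alpha_pdw_deg) * b1_rel
    a_t = np.radians(triplet.alpha_t1w_deg) * b1_rel
    sp, st, tr = triplet.s_pdw, triplet.s_t1w, triplet.tr
    denom = sp / a_p - st / a_t
    if denom <= 0:
        raise EstimationError(
            "S_pdw/alpha_pdw <= S_t1w/alpha_t1w: signal ordering is "
            "incompatible with the spoiled-gradient-echo model"
        )
    r1 = 0.5 * (st * a_t / tr - sp * a_p / tr) / denom
    a_amp = sp * st * (tr * a_t / a_p - tr * a_p / a_t) / (st * tr * a_t - sp * tr * a_p)
    return float(a_amp), float(r1)


def mtsat_delta(
    s_mtw: float, a_amp: float, r1: float, alpha_mtw_rad: float, tr: float
) -> float:
    """MT_sat in percent units from the MT-weighted signal.

    Inverts S_mt = A alpha R1 TR / (alpha^2/2 + delta + R1 TR):

        delta = A alpha R1 TR / S_mt - alpha^2/2 - R1 TR

    and returns delta * 100 (p.u.).  A non-positive delta (no apparent
    saturation) is returned with a warning rather than raised, so noisy
    voxels do not abort map computation.
    """
    if min(s_mtw, a_amp, r1, alpha_mtw_rad, tr) <= 0:
        raise ValueError("all inputs must be positive")
    delta = a_amp * alpha_mtw_rad * r1 * tr / s_mtw - alpha_mtw_rad**2 / 2.0 - r1 * tr
    if delta <= 0:
        warnings.warn(
            "non-physical MT_sat <= 0 (signal exceeds the saturation-free model)",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(delta * 100.0)


def mtsat_b1_correct(delta, b1_rel: float):
    """Semi-empirical higher-order B1 correction of MT_sat.

    delta_corr = delta * (1 - 0.4) / (1 - 0.4 * b1_rel); the identity at
    nominal field.  Scale-agnostic (works on p.u. or fractional delta).
    """
    if not 0 < b1_rel:
        raise ValueError("b1_rel must be positive")
    denom = 1.0 - MTSAT_B1_FACTOR * b1_rel
    if denom <= 0:
        raise ValueError(
            f"b1_rel = {b1_rel} makes the correction denominator non-positive"
        )
    return delta * (1.0 - MTSAT_B1_FACTOR) / denom


def compute_mtr(s_mt, s_ref):
    """Magnetization transfer ratio MTR = 1 - S_mt / S_ref, as a fraction."""
    s_ref = np.asarray(s_ref, dtype=float)
    if np.any(s_ref <= 0):
        raise ZeroDivisionError("reference signal must be strictly positive")
    out = 1.0 - np.asarray(s_mt, dtype=float) / s_ref
    return out if out.ndim else float(out)


def fit_k(mtr_values, b1_error, min_n: int = 10) -> MtrCorrectionFit:
    """Per-subject ordinary least-squares fit of MTR against B1 error.

    ``mtr_values`` are voxelwise MTR fractions of the reference tissue,
    ``b1_error = b1_rel - 1`` at the same voxels.  Slope = k_specific,
    intercept = the tissue's MTR at nominal B1, and k = slope / intercept.
    """
    mtr = np.asarray(mtr_values, dtype=float).ravel()
    err = np.asarray(b1_error, dtype=float).ravel()
    if mtr.size != err.size:
        raise ValueError("mtr_values and b1_error must have the same length")
    if mtr.size < min_n:
        raise CannotFitError(f"need >= {min_n} voxels for the k fit, got {mtr.size}")
    if np.ptp(err) == 0:
        raise CannotFitError("b1_error has zero spread; the slope is unidentifiable")
    slope, intercept = np.polyfit(err, mtr, 1)
    if intercept <= 0:
        raise CannotFitError(
            "reference-tissue MTR intercept is non-positive: invalid reference ROI"
        )
    pred = intercept + slope * err
    ss_res = float(np.sum((mtr - pred) ** 2))
    ss_tot = float(np.sum((mtr - mtr.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return MtrCorrectionFit(
        k_specific=float(slope),
        mtr_at_nominal_b1=float(intercept),
        k=float(slope / intercept),
        n_voxels=int(mtr.size),
        r_squared=r2,
    )


def apply_mtr_correction(mtr, b1_error, k: float):
    """B1-debiased MTR: MTR_corr = MTR / (k * b1_error + 1)."""
    denom = k * np.asarray(b1_error, dtype=float) + 1.0
    if np.any(denom <= 0):
        raise ValueError("k * b1_error + 1 must be positive")
    out = np.asarray(mtr, dtype=float) / denom
    return out if out.ndim else float(out)
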