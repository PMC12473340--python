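"""Digital phantoms and acquisition simulation.

Two ground-truth phantom families are generated:

* a schematic calf cross-section with five elliptical muscle regions
  (soleus SOL, medial/lateral gastrocnemius MG/LG, tibialis anterior TA,
  tibialis posterior TP), per-muscle two-pool tissue truths drawn from
  young- or senior-cohort distributions, and smooth low-order B1
  (default 0.85-1.15 relative) and B0 (default +/- 40 Hz) fields;
* a homogeneous-cylinder agarose series at 0.5-4% concentration whose
  macromolecular-fraction truths follow the proton-counting values for
  doped agarose gels.

Every acquisition protocol of the study design can be simulated from a
phantom: noiseless voxel signals come from the two-pool steady-state and
spoiled-gradient-echo forward models with the voxel's B1-scaled flip
angles and B0-shifted offsets, then Rician noise is added at a configured
SNR (defined on the reference volume's mean muscle signal).  All draws are
deterministic given the seeds.

Age contrasts are induced exclusively through the tissue parameters
(macromolecular fraction down, T1 up in the senior group), never painted
onto index maps, so every estimation method sees one consistent ground
truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import VolumeMeta, VolumeStack
from .mt_physics import RFPulse, TwoPoolParams, omega1_cwpe, omega1_rms, ramani_signal_arrays
from .relaxometry import spgr_signal

__all__ = [
    "MUSCLE_LABELS",
    "CohortConfig",
    "AgarosePreset",
    "LegPhantom",
    "SubjectSim",
    "make_leg_phantom",
    "make_agarose_series",
    "simulate_protocol",
    "simulate_subject",
    "PROTOCOLS",
]

#: Label integers of the five calf-muscle ROIs.
MUSCLE_LABELS = {"SOL": 1, "MG": 2, "LG": 3, "TA": 4, "TP": 5}

# fractional (center_x, center_y, semi_x, semi_y) of each muscle ellipse on
# the cross-section; schematic placement, painted in order with later
# regions restricted to still-unlabelled voxels
_ELLIPSES = {
    "SOL": (0.50, 0.60, 0.30, 0.15),
    "MG": (0.32, 0.82, 0.14, 0.10),
    "LG": (0.68, 0.82, 0.13, 0.09),
    "TA": (0.38, 0.20, 0.13, 0.10),
    "TP": (0.56, 0.38, 0.12, 0.08),
}

# --- acquisition protocol presets (the study's sequence parameters) -------

_MT_TR = 0.050
_MT_TE = 0.003
_MT_READ_FLIP = 6.0
_MT_BW = 200.0
_MT_DUR = 10.24e-3

#: Multi-offset qMT: 2 MT flip angles x 7 offsets + one MT-free reference.
MULTIOFFSET_FLIPS = (350.0, 500.0)
MULTIOFFSET_OFFSETS_HZ = tuple(1e3 * k for k in (1, 2, 5, 10, 20, 50, 100))

#: Single-offset qMT / MTR: 650 deg MT pulse at 1 kHz and 100 kHz.
SINGLEOFFSET_FLIP = 650.0
SINGLEOFFSET_OFFSETS_HZ = (1e3, 100e3)

#: MT_sat triplet: PDw 4 deg, MTw 10 deg (with MT pulse), T1w 20 deg.
MTSAT_FLIPS = (4.0, 10.0, 20.0)
MTSAT_MT = dict(flip=500.0, offset=1.2e3, bw=375.0, dur=9.984e-3)

#: VFA T1 mapping flip angles at TR 25 ms.
VFA_FLIPS = (5.0, 15.0, 25.0)
VFA_TR = 0.025

#: Dual-echo B0 mapping echo times.
B0_TES = (4.92e-3, 7.38e-3)
B0_TR = 0.320

PROTOCOLS = ("multioffset", "singleoffset", "mtsat", "vfa", "b0", "b1")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the synthetic two-cohort experiment.

    Defaults reproduce the study conditions: 15 young and 9 senior
    subjects; per-muscle young macromolecular-fraction medians on the
    single-offset scale (higher in the tibialis muscles than the
    plantarflexors); a senior f decrement of 0.006 and T1 increment of
    0.07 s; subject- and muscle-level biological spread; smooth B1 within
    0.85-1.15 and B0 within +/- 40 Hz; reference-image SNR 100.
    """

    n_young: int = 15
    n_senior: int = 9
    shape: tuple = (64, 64, 4)
    f_young: dict = field(
        default_factory=lambda: {"SOL": 0.072, "MG": 0.071, "LG": 0.070, "TA": 0.075, "TP": 0.074}
    )
    f_age_contrast: float = 0.006
    t1_young_s: float = 1.40
    t1_age_contrast_s: float = 0.07
    subject_f_sd: float = 0.003
    muscle_f_sd: float = 0.001
    subject_t1_sd: float = 0.03
    muscle_t1_sd: float = 0.020
    f_t1_subject_corr: float = -0.5
    field_subject_fraction: float = 0.3
    rm0a: float = 48.0
    t2b_s: float = 6e-6
    ra_t2a: float = 0.025
    b1_half_range: float = 0.15
    b0_half_range_hz: float = 40.0
    snr: float = 100.0
    m0: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young < 2 or self.n_senior < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if min(self.f_young.values()) - self.f_age_contrast <= 0:
            raise ValueError("senior f medians must stay positive")


@dataclass(frozen=True)
class AgarosePreset:
    """Agarose-gel calibration series with known macromolecular fractions.

    The default fraction truths are the proton-counting values for
    nickel-doped agarose at 0.5 / 1 / 2 / 3 / 4 % concentration; T1 and
    free-pool T2 decrease with concentration at gel-typical scales.
    """

    concentrations_pct: tuple = (0.5, 1.0, 2.0, 3.0, 4.0)
    f_truth: tuple = (0.002, 0.004, 0.009, 0.013, 0.017)
    t1_s: tuple = (2.2, 2.0, 1.7, 1.5, 1.3)
    t2a_s: tuple = (0.15, 0.12, 0.09, 0.07, 0.055)
    rm0a: float = 48.0
    t2b_s: float = 6e-6
    shape: tuple = (48, 48, 2)

    def __post_init__(self) -> None:
        n = len(self.concentrations_pct)
        if any(len(x) != n for x in (self.f_truth, self.t1_s, self.t2a_s)):
            raise ValueError("per-concentration fields must have equal length")
        if any(b <= a for a, b in zip(self.f_truth[:-1], self.f_truth[1:])):
            raise ValueError("f_truth must increase strictly with concentration")


@dataclass
class LegPhantom:
    """Ground truth of one simulated subject (or phantom vial).

    ``labels`` is the integer ROI volume; ``label_names`` maps region name
    to label integer; ``tissue`` and ``t1`` hold per-region two-pool truths
    and T1 values; ``b1`` and ``b0_hz`` are the smooth field maps.
    """

    labels: np.ndarray
    label_names: dict
    tissue: dict
    t1: dict
    b1: np.ndarray
    b0_hz: np.ndarray
    m0: float = 1000.0

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.label_names[name]

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels > 0


def _smooth_field(rng: np.random.Generator, shape, half_range: float, center: float) -> np.ndarray:
    """Smooth low-order polynomial field over the cross-section.

    A random quadratic in the in-plane coordinates, rescaled so the maximum
    deviation from ``center`` equals a random fraction (0.6-1.0) of
    ``half_range``, replicated along slices.
    """
    nx, ny, nz = shape
    x = np.linspace(-1.0, 1.0, nx)[:, None]
    y = np.linspace(-1.0, 1.0, ny)[None, :]
    c = rng.uniform(-1.0, 1.0, size=5)
    raw = c[0] * x + c[1] * y + c[2] * x * y + c[3] * (x**2 - 1 / 3) + c[4] * (y**2 - 1 / 3)
    peak = np.max(np.abs(raw))
    if peak == 0:
        raw = x * 0.0 + y * 0.0
        peak = 1.0
    amplitude = half_range * rng.uniform(0.6, 1.0)
    plane = center + amplitude * raw / peak
    return np.repeat(plane[:, :, None], nz, axis=2)


def _paint_ellipses(shape) -> np.ndarray:
    nx, ny, nz = shape
    xs = (np.arange(nx) + 0.5) / nx
    ys = (np.arange(ny) + 0.5) / ny
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    plane = np.zeros((nx, ny), dtype=int)
    for name, (cx, cy, ax, ay) in _ELLIPSES.items():
        inside = ((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2 <= 1.0
        plane[inside & (plane == 0)] = MUSCLE_LABELS[name]
    labels = np.repeat(plane[:, :, None], nz, axis=2)
    for name, lab in MUSCLE_LABELS.items():
        if int((labels == lab).sum()) < 50:
            raise ValueError(f"muscle {name} has fewer than 50 voxels at shape {shape}")
    return labels


def make_leg_phantom(config: CohortConfig, subject_index: int, group: str) -> LegPhantom:
    """Deterministic ground-truth calf phantom for one subject.

    Tissue truths are drawn from the group's distributions: the senior
    group's macromolecular fraction is shifted down by ``f_age_contrast``
    and its T1 up by ``t1_age_contrast_s``; subject- and muscle-level
    normal perturbations model biological spread.
    """
    if group not in ("young", "senior"):
        raise ValueError(f"unknown group {group!r}; expected 'young' or 'senior'")
    group_code = 0 if group == "young" else 1
    rng = np.random.default_rng([config.seed, group_code, subject_index, 7919])

    labels = _paint_ellipses(config.shape)
    # subject-level biology: a shared latent (inflammation / composition)
    # factor raises T1 while lowering the macromolecular fraction, giving
    # the configured negative f-T1 coupling within groups
    z1, z2 = rng.normal(size=2)
    rho = config.f_t1_subject_corr
    subj_t1 = config.subject_t1_sd * z1
    subj_f = config.subject_f_sd * (rho * z1 + math.sqrt(max(1.0 - rho**2, 0.0)) * z2)
    senior = group == "senior"

    tissue, t1 = {}, {}
    for name in MUSCLE_LABELS:
        f_med = config.f_young[name] - (config.f_age_contrast if senior else 0.0)
        f_val = f_med + subj_f + rng.normal(0.0, config.muscle_f_sd)
        f_val = max(f_val, 0.01)
        t1_val = config.t1_young_s + (config.t1_age_contrast_s if senior else 0.0)
        t1_val = max(t1_val + subj_t1 + rng.normal(0.0, config.muscle_t1_sd), 0.5)
        ra = 1.0 / t1_val
        tissue[name] = TwoPoolParams(
            F=f_val / (1.0 - f_val),
            rm0a=config.rm0a,
            RA=ra,
            T2A=config.ra_t2a / ra,
            T2B=config.t2b_s,
        )
        t1[name] = t1_val

    # transmit and static fields: a coil-geometry pattern shared by every
    # subject of the study plus a smaller subject-specific perturbation
    shared_rng = np.random.default_rng([config.seed, 6151])
    frac = config.field_subject_fraction
    b1 = _smooth_field(shared_rng, config.shape, config.b1_half_range * (1 - frac), 1.0)
    b1 = b1 + _smooth_field(rng, config.shape, config.b1_half_range * frac, 0.0)
    b0 = _smooth_field(shared_rng, config.shape, config.b0_half_range_hz * (1 - frac), 0.0)
    b0 = b0 + _smooth_field(rng, config.shape, config.b0_half_range_hz * frac, 0.0)
    return LegPhantom(
        labels=labels,
        label_names=dict(MUSCLE_LABELS),
        tissue=tissue,
        t1=t1,
        b1=b1,
        b0_hz=b0,
        m0=config.m0,
    )


def make_agarose_phantom(
    preset: AgarosePreset,
    index: int,
    seed: int = 0,
    b1_half_range: float = 0.08,
    b1_center: float = 1.0,
) -> LegPhantom:
    """Homogeneous-cylinder phantom for one agarose concentration.

    ``b1_center`` is the mean relative transmit field over the vial: vials
    sit at different positions of one smooth coil field, so their mean B1
    differs even though each sees only a mild internal gradient.
    """
    nx, ny, nz = preset.shape
    xs = (np.arange(nx) + 0.5) / nx
    ys = (np.arange(ny) + 0.5) / ny
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    inside = (gx - 0.5) ** 2 + (gy - 0.5) ** 2 <= 0.35**2
    labels = np.repeat(inside[:, :, None].astype(int), nz, axis=2)
    rng = np.random.default_rng([seed, index, 104729])
    f_val = preset.f_truth[index]
    t1_val = preset.t1_s[index]
    tissue = {
        "AGAR": TwoPoolParams(
            F=f_val / (1.0 - f_val),
            rm0a=preset.rm0a,
            RA=1.0 / t1_val,
            T2A=preset.t2a_s[index],
            T2B=preset.t2b_s,
        )
    }
    b1 = _smooth_field(rng, preset.shape, b1_half_range, b1_center)
    b0 = _smooth_field(rng, preset.shape, 15.0, 0.0)
    return LegPhantom(
        labels=labels,
        label_names={"AGAR": 1},
        tissue=tissue,
        t1={"AGAR": t1_val},
        b1=b1,
        b0_hz=b0,
    )


def make_agarose_series(
    preset: AgarosePreset | None = None,
    snr: float = 200.0,
    seed: int = 0,
    mode: str = "ramani",
) -> list:
    """One phantom + simulated stacks per agarose concentration.

    The vials share one session's coil field: per-vial mean B1 values are
    drawn once for the series (within +/- 3% of nominal, phantom-at-
    isocenter scale) on top of each vial's mild internal gradient.  ``mode`` selects the RF-approximation
    convention used as the generative truth for the MT attenuation.
    Returns a list of (phantom, stacks) with all protocols simulated.
    """
    if preset is None:
        preset = AgarosePreset()
    rng = np.random.default_rng([seed, 4051])
    centers = 1.0 + rng.uniform(-0.03, 0.03, size=len(preset.concentrations_pct))
    series = []
    for i in range(len(preset.concentrations_pct)):
        phantom = make_agarose_phantom(preset, i, seed=seed, b1_center=float(centers[i]))
        stacks = {
            proto: simulate_protocol(
                phantom, proto, snr=snr, seed=seed * 1009 + 31 * i + j, mode=mode
            )
            for j, proto in enumerate(PROTOCOLS)
        }
        series.append((phantom, stacks))
    return series


# --- forward simulation ----------------------------------------------------


def _mt_pulse(flip_deg, offset_hz, bw=_MT_BW, dur=_MT_DUR, tr=_MT_TR) -> RFPulse:
    return RFPulse(
        flip_angle_deg=flip_deg,
        duration_s=dur,
        bandwidth_hz=bw,
        offset_hz=offset_hz,
        tr_s=tr,
    )


def _mt_meta(pulse: RFPulse, role: str = "mt", read_flip=_MT_READ_FLIP) -> VolumeMeta:
    return VolumeMeta(
        role=role,
        tr_s=pulse.tr_s,
        te_s=_MT_TE,
        read_flip_deg=read_flip,
        mt_flip_deg=pulse.flip_angle_deg,
        mt_offset_hz=pulse.offset_hz,
        mt_duration_s=pulse.duration_s,
        mt_bandwidth_hz=pulse.bandwidth_hz,
    )


def _mt_attenuation(phantom: LegPhantom, pulse: RFPulse, out: np.ndarray, mode: str) -> None:
    """Fill ``out`` with the two-pool normalized attenuation Sn per voxel."""
    w1_nominal = omega1_cwpe(pulse) if mode == "ramani" else omega1_rms(pulse)
    for name, params in phantom.tissue.items():
        m = phantom.mask(name)
        w1 = w1_nominal * phantom.b1[m]  # peak and CW-equivalent scale with flip
        offs = pulse.offset_hz - phantom.b0_hz[m]
        out[m] = ramani_signal_arrays(
            params.F, params.rm0a, params.RA, params.RB, params.T2A, params.T2B, w1, offs
        )


def _flash_volume(phantom: LegPhantom, read_flip_deg: float, tr: float) -> np.ndarray:
    """Noiseless spoiled-GRE magnitude volume with B1-scaled read flip."""
    out = np.zeros(phantom.labels.shape)
    for name in phantom.tissue:
        m = phantom.mask(name)
        flip = np.radians(read_flip_deg) * phantom.b1[m]
        out[m] = spgr_signal(phantom.m0, phantom.t1[name], flip, tr)
    return out


def _rician(noiseless: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Rician-distributed magnitude: |S + n1 + i n2| with Gaussian n1, n2."""
    if sigma == 0:
        return noiseless.copy()
    n1 = rng.normal(0.0, sigma, size=noiseless.shape)
    n2 = rng.normal(0.0, sigma, size=noiseless.shape)
    return np.sqrt((noiseless + n1) ** 2 + n2**2)


def _rational_flash(a_amp, r1, alpha_rad, tr, delta=0.0):
    """Small-angle rational spoiled-GRE signal with per-TR saturation delta."""
    return a_amp * alpha_rad * r1 * tr / (alpha_rad**2 / 2.0 + delta + r1 * tr)


def simulate_protocol(
    phantom: LegPhantom,
    protocol: str,
    snr: float | None = 100.0,
    seed: int = 0,
    mode: str = "ramani",
) -> VolumeStack:
    """Simulate one acquisition protocol from a ground-truth phantom.

    ``snr`` is the reference-volume SNR in tissue; ``None`` (or ``inf``)
    yields noiseless volumes.  ``mode`` selects the RF approximation used
    as the generative convention for MT attenuation (CW power equivalent
    by default).
    """
    noiseless_snr = snr is None or not math.isfinite(snr)
    rng = np.random.default_rng([seed, 15485863])
    shape = phantom.labels.shape
    tissue = phantom.tissue_mask

    if protocol == "multioffset":
        vols, meta = [], []
        for flip in MULTIOFFSET_FLIPS:
            for off in MULTIOFFSET_OFFSETS_HZ:
                pulse = _mt_pulse(flip, off)
                sn = np.ones(shape)
                _mt_attenuation(phantom, pulse, sn, mode)
                vols.append(_flash_volume(phantom, _MT_READ_FLIP, _MT_TR) * sn)
                meta.append(_mt_meta(pulse))
        ref = _flash_volume(phantom, _MT_READ_FLIP, _MT_TR)
        vols.append(ref)
        meta.append(VolumeMeta(role="reference", tr_s=_MT_TR, te_s=_MT_TE, read_flip_deg=_MT_READ_FLIP))
    elif protocol == "singleoffset":
        vols, meta = [], []
        base = _flash_volume(phantom, _MT_READ_FLIP, _MT_TR)
        for off, role in zip(SINGLEOFFSET_OFFSETS_HZ, ("mt", "reference")):
            pulse = _mt_pulse(SINGLEOFFSET_FLIP, off)
            sn = np.ones(shape)
            _mt_attenuation(phantom, pulse, sn, mode)
            vols.append(base * sn)
            meta.append(_mt_meta(pulse, role=role))
        ref = vols[1]
    elif protocol == "mtsat":
        pulse = _mt_pulse(MTSAT_MT["flip"], MTSAT_MT["offset"], MTSAT_MT["bw"], MTSAT_MT["dur"])
        sn = np.ones(shape)
        _mt_attenuation(phantom, pulse, sn, mode)
        vols, meta = [], []
        roles = ("pdw", "mtw", "t1w")
        for flip_deg, role in zip(MTSAT_FLIPS, roles):
            vol = np.zeros(shape)
            for name in phantom.tissue:
                m = phantom.mask(name)
                alpha = np.radians(flip_deg) * phantom.b1[m]
                r1 = 1.0 / phantom.t1[name]
                if role == "mtw":
                    # per-TR saturation equivalent to the steady-state
                    # two-pool attenuation of the MT_sat pulse
                    delta = (alpha**2 / 2.0 + r1 * _MT_TR) * (1.0 / sn[m] - 1.0)
                else:
                    delta = 0.0
                vol[m] = _rational_flash(phantom.m0, r1, alpha, _MT_TR, delta)
            vols.append(vol)
            if role == "mtw":
                meta.append(_mt_meta(pulse, role="mtw", read_flip=flip_deg))
            else:
                meta.append(VolumeMeta(role=role, tr_s=_MT_TR, te_s=_MT_TE, read_flip_deg=flip_deg))
        ref = vols[0]
    elif protocol == "vfa":
        vols = [_flash_volume(phantom, f, VFA_TR) for f in VFA_FLIPS]
        meta = [
            VolumeMeta(role="vfa", tr_s=VFA_TR, te_s=_MT_TE, read_flip_deg=f) for f in VFA_FLIPS
        ]
        ref = vols[0]
    elif protocol == "b0":
        base_phase = 0.3
        vols, meta = [], []
        for te, role in zip(B0_TES, ("b0_echo1", "b0_echo2")):
            phase = 2.0 * np.pi * phantom.b0_hz * te + base_phase
            if not noiseless_snr:
                phase = phase + rng.normal(0.0, 1.0 / snr, size=shape)
            phase = np.angle(np.exp(1j * phase))
            phase[~tissue] = rng.uniform(-np.pi, np.pi, size=int((~tissue).sum()))
            vols.append(phase)
            meta.append(VolumeMeta(role=role, tr_s=B0_TR, te_s=te, read_flip_deg=10.0))
        return VolumeStack(data=np.stack(vols, axis=-1), meta=meta)
    elif protocol == "b1":
        vol = phantom.b1.copy()
        vol[~tissue] = 0.0
        meta = [VolumeMeta(role="b1", tr_s=18.04, te_s=1.95e-3, read_flip_deg=8.0)]
        return VolumeStack(data=vol[..., None], meta=meta)
    else:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")

    data = np.stack(vols, axis=-1)
    if not noiseless_snr:
        sigma = float(ref[tissue].mean()) / snr
        data = _rician(data, sigma, rng)
    return VolumeStack(data=data, meta=meta)


@dataclass
class SubjectSim:
    """One simulated subject: ground truth plus all acquired stacks."""

    subject_id: str
    group: str
    phantom: LegPhantom
    stacks: dict


def simulate_subject(
    config: CohortConfig,
    subject_index: int,
    group: str,
    protocols=PROTOCOLS,
    snr: float | None = None,
    mode: str = "ramani",
) -> SubjectSim:
    """Phantom plus simulated stacks for one subject of the cohort.

    ``snr=None`` uses the configured cohort SNR (pass ``math.inf`` for
    noiseless volumes).
    """
    if snr is None:
        snr = config.snr
    phantom = make_leg_phantom(config, subject_index, group)
    group_code = 0 if group == "young" else 1
    stacks = {
        proto: simulate_protocol(
            phantom,
            proto,
            snr=snr,
            seed=config.seed * 2003 + 211 * group_code + 13 * subject_index + j,
            mode=mode,
        )
        for j, proto in enumerate(protocols)
    }
    sid = f"{'Y' if group == 'young' else 'S'}{subject_index:02d}"
    return SubjectSim(subject_id=sid, group=group, phantom=phantom, stacks=stacks)
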