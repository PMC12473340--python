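"""Volume stacks, acquisition metadata, label volumes and run configuration.

All volumes are NIfTI-1; every stack is assumed co-registered on a common
grid (registration is outside this package), which is enforced by geometry
checks rather than resampling.  Per-volume acquisition metadata travels in
a JSON sidecar: a list of records with the fields of :class:`VolumeMeta`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "VolumeMeta",
    "VolumeStack",
    "RunConfig",
    "GeometryError",
    "MetadataError",
    "load_stack",
    "save_stack",
    "load_labels",
    "save_volume",
]

#: Roles a volume may declare in its metadata record.
ROLES = {"mt", "reference", "pdw", "mtw", "t1w", "vfa", "b0_echo1", "b0_echo2", "b1"}


class GeometryError(ValueError):
    """Volumes do not share a common grid."""


class MetadataError(ValueError):
    """Acquisition metadata is missing or inconsistent with the stack."""


@dataclass(frozen=True)
class VolumeMeta:
    """Acquisition record of one volume in a stack.

    MT-pulse fields are ``None`` for volumes acquired without MT
    preparation (reference, PDw, T1w, VFA, field maps).
    """

    role: str
    tr_s: float
    te_s: float
    read_flip_deg: float
    mt_flip_deg: float | None = None
    mt_offset_hz: float | None = None
    mt_duration_s: float | None = None
    mt_bandwidth_hz: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise MetadataError(f"unknown volume role {self.role!r}; expected one of {sorted(ROLES)}")
        if self.role == "mt" or self.role == "mtw":
            for name in ("mt_flip_deg", "mt_offset_hz", "mt_duration_s", "mt_bandwidth_hz"):
                if getattr(self, name) is None:
                    raise MetadataError(f"MT volume metadata is missing field {name!r}")


@dataclass
class VolumeStack:
    """Co-registered 4D magnitude (or phase) data with per-volume metadata."""

    data: np.ndarray
    meta: list[VolumeMeta]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("stack data must be 4D (x, y, z, volume)")
        if len(self.meta) != self.data.shape[3]:
            raise MetadataError(
                f"metadata lists {len(self.meta)} volumes but stack has {self.data.shape[3]}"
            )

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def volumes(self, role: str) -> list[tuple[np.ndarray, VolumeMeta]]:
        """All (3D volume, metadata) pairs with the given role."""
        return [
            (self.data[..., i], m) for i, m in enumerate(self.meta) if m.role == role
        ]

    def single(self, role: str) -> tuple[np.ndarray, VolumeMeta]:
        """The unique volume with the given role."""
        hits = self.volumes(role)
        if len(hits) != 1:
            raise MetadataError(f"expected exactly one {role!r} volume, found {len(hits)}")
        return hits[0]


def _check_geometry(shapes, zooms) -> None:
    if len(set(shapes)) > 1:
        raise GeometryError(f"mixed grid shapes across volumes: {sorted(set(shapes))}")
    if len({tuple(np.round(z, 6)) for z in zooms}) > 1:
        raise GeometryError("mixed voxel sizes across volumes")


def load_stack(paths, metadata) -> VolumeStack:
    """Load one 4D NIfTI (or several 3D NIfTIs) plus its metadata sidecar.

    ``paths`` is a single path or a sequence of paths; ``metadata`` is a
    path to a JSON list of per-volume records or an already-parsed list.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    arrays, shapes, zooms = [], [], []
    affine = None
    for p in paths:
        img = nib.load(str(p))
        arr = np.asarray(img.dataobj, dtype=float)
        if arr.ndim == 3:
            arr = arr[..., None]
        if arr.ndim != 4:
            raise GeometryError(f"{p}: expected a 3D or 4D volume, got ndim={arr.ndim}")
        arrays.append(arr)
        shapes.append(arr.shape[:3])
        zooms.append(img.header.get_zooms()[:3])
        if affine is None:
            affine = img.affine
    _check_geometry(shapes, zooms)
    data = np.concatenate(arrays, axis=3)

    if isinstance(metadata, (str, Path)):
        with open(metadata) as fh:
            records = json.load(fh)
    else:
        records = metadata
    try:
        meta = [VolumeMeta(**r) for r in records]
    except TypeError as exc:
        raise MetadataError(f"malformed metadata record: {exc}") from exc
    if len(meta) != data.shape[3]:
        raise MetadataError(
            f"metadata lists {len(meta)} volumes but files contain {data.shape[3]}"
        )
    return VolumeStack(data=data, meta=meta, affine=affine)


def save_stack(stack: VolumeStack, nii_path, json_path) -> None:
    """Write a stack as a 4D NIfTI plus a JSON metadata sidecar."""
    img = nib.Nifti1Image(np.asarray(stack.data, dtype=np.float32), stack.affine)
    nib.save(img, str(nii_path))
    with open(json_path, "w") as fh:
        json.dump([asdict(m) for m in stack.meta], fh, indent=1)


def save_volume(volume: np.ndarray, path, affine=None) -> None:
    """Write a single 3D map as NIfTI."""
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def load_labels(path) -> np.ndarray:
    """Load an integer label volume."""
    arr = np.asarray(nib.load(str(path)).dataobj)
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("label volume contains non-integer values")
    return arr.astype(int)


_METHODS = {
    "multioffset_ramani",
    "multioffset_yarnykh",
    "singleoffset",
    "mtsat",
    "mtr",
    "mtr_corr",
    "t1_vfa",
    "b0",
}

# protocol inputs each method needs before any computation starts
_REQUIRED_INPUTS = {
    "multioffset_ramani": ("multioffset", "vfa", "b1", "b0"),
    "multioffset_yarnykh": ("multioffset", "vfa", "b1", "b0"),
    "singleoffset": ("singleoffset", "vfa", "b1", "b0"),
    "mtsat": ("mtsat", "b1"),
    "mtr": ("singleoffset",),
    "mtr_corr": ("singleoffset", "b1"),
    "t1_vfa": ("vfa", "b1"),
    "b0": ("b0",),
}


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run.

    ``inputs`` maps protocol names (multioffset, singleoffset, mtsat, vfa,
    b0, b1) to ``{"nii": ..., "json": ...}`` path pairs; ``labels`` is the
    ROI label volume path.  ``methods`` selects which indices to compute.
    """

    methods: list
    inputs: dict = field(default_factory=dict)
    labels: str | None = None
    analysis_mode: str = "roi_signal_mean"
    reference_label: int = 5  # tibialis posterior
    seed: int = 0
    out_dir: str = "qmtkit-out"

    def __post_init__(self) -> None:
        unknown = set(self.methods) - _METHODS
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.analysis_mode not in {"roi_signal_mean", "map_mean"}:
            raise ValueError(f"unknown analysis mode {self.analysis_mode!r}")

    def validate_inputs(self) -> None:
        """Check every requested method's inputs are present before computing."""
        for m in self.methods:
            for proto in _REQUIRED_INPUTS[m]:
                if proto not in self.inputs:
                    raise ValueError(
                        f"method {m!r} requires the {proto!r} acquisition, "
                        "which is missing from the configuration"
                    )
        if self.labels is None:
            raise ValueError("a label volume is required for ROI analysis")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)
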