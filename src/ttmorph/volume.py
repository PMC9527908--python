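"""Label-volume I/O and per-slice contour extraction.

A :class:`LabelVolume` is the universe every measurement runs on: a 3D
integer voxel grid in ``(Z, Y, X)`` axis order (Z the serial-sectioning
axis) with anisotropic spacing in nanometres per voxel.  Serial block-face
EM stacks are typically sampled at ~10 nm in-plane and 50 nm between
sections, so ``sz >> sx, sy`` is the normal case.

Label roles: one label marks the intracellular partition (cell mask), one
marks extracellular space outside the sarcolemma, and the remaining
positive labels mark segmented tubular objects.  Label 0 is unassigned
background/cytoplasm.

Supported on-disk formats are multi-page integer TIFF (spacing and label
roles in a JSON sidecar, ``<path>.json``) and MRC2014 maps (spacing also
encoded in the map header cell, in ångström).  Voxel coordinates follow the
convention that the centre of voxel ``i`` along an axis with spacing ``s``
sits at physical position ``i * s`` (0-based).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from skimage import measure as _skmeasure

from .errors import BoundsError, ConfigurationError, VolumeFormatError

__all__ = [
    "LabelVolume",
    "SliceContour",
    "read_label_volume",
    "write_label_volume",
    "crop_stack_portion",
    "extract_slice_contours",
    "contours_from_mask",
]


@dataclass
class LabelVolume:
    """3D integer label grid with physical spacing and label roles.

    Parameters
    ----------
    voxels
        Integer array of shape ``(nz, ny, nx)``; axis order (Z, Y, X).
    spacing
        ``(sx, sy, sz)`` voxel spacing in nm.  All components positive.
    cell_label
        Label of the intracellular (cell-mask) partition.
    extracellular_label
        Label of the space outside the sarcolemma.
    object_labels
        Positive labels marking segmented tubular objects.  If ``None``,
        all positive labels other than the two roles above are used.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    cell_label: int = 1
    extracellular_label: int = 2
    object_labels: frozenset[int] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise VolumeFormatError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise VolumeFormatError(f"label volumes must be integer-typed, got {self.voxels.dtype}")
        sx, sy, sz = self.spacing
        if not (sx > 0 and sy > 0 and sz > 0):
            raise ConfigurationError(f"spacing components must be positive, got {self.spacing}")
        self.spacing = (float(sx), float(sy), float(sz))
        if self.object_labels is None:
            present = np.unique(self.voxels)
            self.object_labels = frozenset(
                int(v) for v in present
                if v > 0 and v not in (self.cell_label, self.extracellular_label)
            )
        else:
            self.object_labels = frozenset(int(v) for v in self.object_labels)
        roles = {self.cell_label, self.extracellular_label}
        if len(roles) < 2 or roles & self.object_labels:
            raise ConfigurationError(
                "cell_label, extracellular_label and object_labels must be pairwise disjoint"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_nm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def object_mask(self) -> np.ndarray:
        """Boolean mask of all object-labelled voxels."""
        return np.isin(self.voxels, sorted(self.object_labels))

    def cell_mask(self, include_objects: bool = True) -> np.ndarray:
        """Boolean mask of the intracellular partition.

        Tubule lumina lie geometrically inside the cell, so by default the
        object labels are included.
        """
        m = self.voxels == self.cell_label
        if include_objects and self.object_labels:
            m |= self.object_mask()
        return m

    def labels_config(self) -> dict:
        return {
            "cell_label": int(self.cell_label),
            "extracellular_label": int(self.extracellular_label),
            "object_labels": sorted(int(v) for v in self.object_labels),
        }


@dataclass(frozen=True)
class SliceContour:
    """One closed in-plane cross-section polygon of a labelled object.

    ``vertices`` is an ``(n, 2)`` array of ``(x, y)`` positions in nm,
    traced at the 0.5 iso-level with sub-voxel linear interpolation.
    """

    slice_index: int
    vertices: np.ndarray
    perimeter: float
    area: float


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _is_mrc(path: Path) -> bool:
    return path.suffix.lower() in {".mrc", ".map", ".ccp4"}


def read_label_volume(
    path: str | Path,
    spacing: Sequence[float] | None = None,
    labels_config: dict | None = None,
) -> LabelVolume:
    """Read a label volume from a multi-page TIFF or an MRC2014 map.

    Spacing resolution order: explicit ``spacing`` argument, then the JSON
    sidecar, then (MRC only) the map header cell.  ``labels_config`` is a
    mapping with keys ``cell_label``, ``extracellular_label`` and optionally
    ``object_labels``; when omitted it is taken from the sidecar, falling
    back to defaults (1, 2, all other positive labels).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    sidecar: dict = {}
    sc = _sidecar_path(path)
    if sc.exists():
        sidecar = json.loads(sc.read_text())

    if _is_mrc(path):
        import gemmi

        m = gemmi.read_ccp4_map(str(path))
        arr = np.array(m.grid, copy=True)
        data = np.rint(arr).astype(np.int32)
        if not np.allclose(arr, data, atol=1e-3):
            raise VolumeFormatError(f"{path} does not contain integer label data")
        cell = m.grid.unit_cell
        nz, ny, nx = data.shape
        header_spacing = (cell.a / 10.0 / nx, cell.b / 10.0 / ny, cell.c / 10.0 / nz)
    else:
        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
        if not np.issubdtype(data.dtype, np.integer):
            raise VolumeFormatError(
                f"{path} has dtype {data.dtype}; label volumes must be integer-typed"
            )
        header_spacing = None

    if spacing is None:
        if "spacing_nm" in sidecar:
            spacing = tuple(sidecar["spacing_nm"])
        elif header_spacing is not None:
            spacing = header_spacing
        else:
            raise ConfigurationError(
                f"no spacing given for {path}: pass spacing= or provide a sidecar JSON"
            )

    cfg = dict(sidecar)
    if labels_config is not None:
        cfg.update(labels_config)
    return LabelVolume(
        voxels=data,
        spacing=tuple(float(s) for s in spacing),  # type: ignore[arg-type]
        cell_label=int(cfg.get("cell_label", 1)),
        extracellular_label=int(cfg.get("extracellular_label", 2)),
        object_labels=(
            frozenset(cfg["object_labels"]) if cfg.get("object_labels") is not None else None
        ),
        provenance=dict(cfg.get("provenance", {})),
    )


def write_label_volume(volume: LabelVolume, path: str | Path, format: str | None = None) -> Path:
    """Write a label volume as TIFF or MRC, plus a JSON sidecar.

    The sidecar records spacing, label roles and provenance so that
    :func:`read_label_volume` restores the volume losslessly.  MRC data are
    stored as float32 grids (exact for labels far below 2**24) with the
    spacing encoded in the header cell as ångström.
    """
    path = Path(path)
    if format is None:
        format = "mrc" if _is_mrc(path) else "tiff"
    if format not in {"tiff", "mrc"}:
        raise ConfigurationError(f"unknown format {format!r}")

    if format == "mrc":
        import gemmi

        m = gemmi.Ccp4Map()
        m.grid = gemmi.FloatGrid(np.ascontiguousarray(volume.voxels, dtype=np.float32))
        nz, ny, nx = volume.shape
        sx, sy, sz = volume.spacing
        m.grid.unit_cell = gemmi.UnitCell(nx * sx * 10, ny * sy * 10, nz * sz * 10, 90, 90, 90)
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))
    else:
        tifffile.imwrite(str(path), volume.voxels, photometric="minisblack")

    sidecar = {
        "spacing_nm": list(volume.spacing),
        **volume.labels_config(),
        "provenance": volume.provenance,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def crop_stack_portion(volume: LabelVolume, start_slice: int, n_slices: int = 100) -> LabelVolume:
    """Select a contiguous sub-stack of ``n_slices`` serial sections.

    Mirrors the analysis convention of measuring a portion projected along
    a fixed number of consecutive sections.  Spacing and label roles are
    unchanged; the crop window is recorded in provenance.
    """
    nz = volume.shape[0]
    if start_slice < 0 or n_slices <= 0 or start_slice + n_slices > nz:
        raise BoundsError(
            f"crop window [{start_slice}, {start_slice + n_slices}) outside stack of {nz} slices"
        )
    prov = dict(volume.provenance)
    prov["crop_window"] = {"start_slice": int(start_slice), "n_slices": int(n_slices)}
    return replace(
        volume,
        voxels=volume.voxels[start_slice : start_slice + n_slices].copy(),
        object_labels=volume.object_labels,
        provenance=prov,
    )


def _polygon_perimeter(vertices: np.ndarray) -> float:
    d = np.diff(vertices, axis=0)
    return float(np.sqrt((d**2).sum(axis=1)).sum())


def _polygon_area(vertices: np.ndarray) -> float:
    # shoelace on the closed polygon
    x, y = vertices[:, 0], vertices[:, 1]
    return float(abs(np.dot(x[:-1], y[1:]) - np.dot(x[1:], y[:-1])) / 2.0)


def _smooth_closed(vertices_open: np.ndarray, window: int) -> np.ndarray:
    """Circular moving average over the vertices of a closed polygon."""
    if window <= 1 or len(vertices_open) < 2 * window:
        return vertices_open
    k = np.ones(window) / window
    h = window // 2
    cols = []
    for i in range(vertices_open.shape[1]):
        wrapped = np.r_[vertices_open[-h:, i], vertices_open[:, i], vertices_open[:h, i]]
        cols.append(np.convolve(wrapped, k, mode="valid"))
    return np.column_stack(cols)


def contours_from_mask(
    mask2d: np.ndarray,
    spacing_xy: tuple[float, float],
    slice_index: int = 0,
    origin_xy: tuple[float, float] = (0.0, 0.0),
    smooth_window: int = 5,
) -> list[SliceContour]:
    """Trace closed 0.5-level contours of a binary in-plane mask.

    Sub-voxel marching-squares tracing (linear interpolation) is used
    rather than voxel-boundary staircase polygons, which would otherwise
    overestimate circular perimeters by ~27%.  On binary data the raw
    midpoint polygon still zig-zags and overestimates a smooth circle's
    perimeter by ~5%, so a short circular moving average
    (``smooth_window`` vertices) is applied before perimeter and area are
    computed; residual bias on discs of realistic radius is ≲0.5%.
    Vertices are returned in physical nm as ``(x, y)``.
    """
    sx, sy = spacing_xy
    if not mask2d.any():
        return []
    padded = np.pad(mask2d.astype(np.float32), 1)
    contours = _skmeasure.find_contours(padded, 0.5)
    out: list[SliceContour] = []
    for c in contours:
        if not np.allclose(c[0], c[-1]):
            c = np.vstack([c, c[:1]])
        c = _smooth_closed(c[:-1], smooth_window)
        # (row, col) in padded frame -> physical (x, y); voxel centre at index*spacing
        x = (c[:, 1] - 1.0 + origin_xy[0]) * sx
        y = (c[:, 0] - 1.0 + origin_xy[1]) * sy
        verts = np.column_stack([x, y])
        verts = np.vstack([verts, verts[:1]])
        per = _polygon_perimeter(verts)
        area = _polygon_area(verts)
        if per <= 0 or area <= 0:
            continue
        out.append(SliceContour(slice_index=slice_index, vertices=verts, perimeter=per, area=area))
    return out


def extract_slice_contours(volume: LabelVolume, label: int, slice_index: int) -> list[SliceContour]:
    """Closed contours of one label on one serial section.

    One contour per in-plane cross-section; an absent label yields an empty
    list.  Perimeters and areas are in nm and nm².
    """
    if slice_index < 0 or slice_index >= volume.shape[0]:
        raise BoundsError(f"slice {slice_index} outside stack of {volume.shape[0]}")
    mask = volume.voxels[slice_index] == label
    sx, sy, _ = volume.spacing
    return contours_from_mask(mask, (sx, sy), slice_index=slice_index)
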