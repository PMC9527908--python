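"""Per-tubule morphometry on labelled components.

The measurement chain mirrors serial-section volumetric analysis of
t-tubule networks: connected components over the object labels are the
per-tubule units; each is measured for

* **volume** — voxel count × voxel volume;
* **surface area** — sub-voxel iso-surface mesh (marching cubes at the
  0.5 level, anisotropic spacing honoured), with open faces at the crop
  boundary excluded;
* **equivalent diameter** — the circular-cross-section approximation
  ``Σᵢ perimeter(contourᵢ) / (n·π)``, i.e. the mean serial-section contour
  perimeter divided by π (a circle's perimeter/π is its diameter);
* **longest-branch length** — the longest skeleton path from the
  sarcolemmal attachment to any tip, on an isotropically resampled copy,
  with distance-transform tip corrections;
* **length fraction** — longest-branch length normalized to the cell
  width along the tubule's penetration axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure as _skmeasure
from skimage.morphology import skeletonize

from .errors import MeasurementError
from .volume import LabelVolume, SliceContour, contours_from_mask

logger = logging.getLogger(__name__)

__all__ = [
    "TubuleComponent",
    "label_components",
    "component_volume",
    "component_surface_area",
    "equivalent_diameter",
    "longest_branch_length",
    "length_fraction",
    "cell_width_at",
    "measure_components",
    "cell_summaries",
    "subsample_metrics",
]

_CROSS = ndimage.generate_binary_structure(3, 1)   # 6-connectivity
_FULL = np.ones((3, 3, 3), dtype=bool)             # 26-connectivity


@dataclass
class TubuleComponent:
    """One connected object: a cropped boolean mask plus connectivity flags.

    ``mask`` covers the component's bounding box; ``origin`` is the
    (z, y, x) index of the box within the parent volume.  The component
    keeps a reference to its parent volume for attachment and cell-width
    queries.
    """

    component_id: int
    mask: np.ndarray
    origin: tuple[int, int, int]
    n_voxels: int
    touches_extracellular: bool
    touches_crop_boundary: bool
    source_labels: frozenset[int]
    volume_ref: LabelVolume | None = field(default=None, repr=False)

    @property
    def spacing(self) -> tuple[float, float, float]:
        if self.volume_ref is None:
            raise MeasurementError("component has no parent volume attached")
        return self.volume_ref.spacing

    def voxel_indices(self) -> np.ndarray:
        """(n, 3) array of (z, y, x) indices in the parent volume frame."""
        idx = np.argwhere(self.mask)
        return idx + np.asarray(self.origin)

    def attachment_voxels(self) -> np.ndarray:
        """Component voxels face-adjacent (6-connectivity) to extracellular space."""
        vol = self.volume_ref
        if vol is None:
            raise MeasurementError("component has no parent volume attached")
        z0, y0, x0 = self.origin
        nz, ny, nx = self.mask.shape
        lo = (max(z0 - 1, 0), max(y0 - 1, 0), max(x0 - 1, 0))
        hi = (min(z0 + nz + 1, vol.shape[0]), min(y0 + ny + 1, vol.shape[1]),
              min(x0 + nx + 1, vol.shape[2]))
        ext = vol.voxels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] == vol.extracellular_label
        adj = ndimage.binary_dilation(ext, structure=_CROSS)
        pad_lo = (z0 - lo[0], y0 - lo[1], x0 - lo[2])
        adj_box = adj[pad_lo[0]:pad_lo[0] + nz, pad_lo[1]:pad_lo[1] + ny,
                      pad_lo[2]:pad_lo[2] + nx]
        return np.argwhere(self.mask & adj_box) + np.asarray(self.origin)

    def contour_stack(self) -> list[SliceContour]:
        """All per-slice closed contours of this component, in physical nm."""
        sx, sy, _ = self.spacing
        z0, y0, x0 = self.origin
        out: list[SliceContour] = []
        for iz in range(self.mask.shape[0]):
            sl = self.mask[iz]
            if not sl.any():
                continue
            out.extend(contours_from_mask(sl, (sx, sy), slice_index=z0 + iz,
                                          origin_xy=(float(x0), float(y0))))
        return out


def label_components(volume: LabelVolume, connectivity: int = 26,
                     min_voxels: int = 8) -> list[TubuleComponent]:
    """Connected components over the union of object labels.

    26-connectivity is the default: at typical anisotropy (50 nm sections
    vs ~10 nm in-plane) 6-connectivity fragments thin oblique tubes across
    section steps.  Components below ``min_voxels`` are discarded and
    counted in the log.  The extracellular-contact test always uses face
    adjacency regardless of the labelling connectivity: diagonal "contact"
    across anisotropic voxels is not physical continuity.
    """
    if connectivity not in (6, 26):
        raise MeasurementError(f"connectivity must be 6 or 26, got {connectivity}")
    structure = _FULL if connectivity == 26 else _CROSS
    mask = volume.object_mask()
    if not mask.any():
        logger.warning("no object labels present in volume")
        return []
    lab, n = ndimage.label(mask, structure=structure)

    counts = np.bincount(lab.ravel())
    ext_adjacent = ndimage.binary_dilation(
        volume.voxels == volume.extracellular_label, structure=_CROSS)
    touching_ext = set(np.unique(lab[ext_adjacent & mask])) - {0}
    boundary_ids: set[int] = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            boundary_ids |= set(np.unique(lab[tuple(sl)]))
    boundary_ids -= {0}

    objects = ndimage.find_objects(lab)
    components: list[TubuleComponent] = []
    n_discarded = 0
    cid = 0
    for i, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        if counts[i] < min_voxels:
            n_discarded += 1
            continue
        sub = lab[slc] == i
        origin = (slc[0].start, slc[1].start, slc[2].start)
        src = frozenset(int(v) for v in np.unique(volume.voxels[slc][sub]))
        components.append(TubuleComponent(
            component_id=cid,
            mask=sub,
            origin=origin,
            n_voxels=int(counts[i]),
            touches_extracellular=i in touching_ext,
            touches_crop_boundary=i in boundary_ids,
            source_labels=src,
            volume_ref=volume,
        ))
        cid += 1
    if n_discarded:
        logger.info("discarded %d components below min_voxels=%d", n_discarded, min_voxels)
    return components


def component_volume(component: TubuleComponent,
                     spacing: tuple[float, float, float] | None = None) -> float:
    """Voxel-count volume in µm³."""
    if component.n_voxels == 0:
        raise MeasurementError("empty component")
    sx, sy, sz = spacing if spacing is not None else component.spacing
    return component.n_voxels * sx * sy * sz / 1e9


def _triangle_areas(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)


def component_surface_area(component: TubuleComponent,
                           spacing: tuple[float, float, float] | None = None,
                           smooth_sigma_nm: float = 15.0) -> float:
    """Marching-cubes iso-surface area in µm².

    Marching cubes on a raw binary mask overestimates curved surfaces
    (in-plane pixelation plus terracing along the coarse sectioning axis:
    up to ~20% on spheres at 10×10×50 nm), so the mask is first smoothed
    with a Gaussian of physical width ``smooth_sigma_nm`` per axis; the
    0.5 iso-surface of the smoothed field tracks the true interface with
    residual bias ≲1% on cylinder/sphere/ellipsoid oracles.  The mask is
    zero-padded so the mesh closes; where the component abuts the crop
    boundary, the artificial closing caps on those faces are subtracted
    (their presence is flagged by ``touches_crop_boundary``).
    """
    if component.n_voxels == 0:
        raise MeasurementError("empty component")
    sx, sy, sz = spacing if spacing is not None else component.spacing
    sp = (sz, sy, sx)
    sigma_vox = tuple(smooth_sigma_nm / s for s in sp)
    pads = tuple(int(np.ceil(3 * sv)) + 1 for sv in sigma_vox)
    field = np.pad(component.mask, [(p, p) for p in pads]).astype(np.float32)
    if smooth_sigma_nm > 0:
        field = ndimage.gaussian_filter(field, sigma=sigma_vox)
    verts, faces, _, _ = _skmeasure.marching_cubes(field, level=0.5, spacing=sp)
    areas = _triangle_areas(verts, faces)
    total = float(areas.sum())

    if component.volume_ref is not None:
        vol_shape = component.volume_ref.shape
        for axis in range(3):
            n_axis = component.mask.shape[axis]
            for face, at_volume_edge in (
                (0, component.origin[axis] == 0),
                (n_axis - 1, component.origin[axis] + n_axis == vol_shape[axis]),
            ):
                if not at_volume_edge:
                    continue
                sel = [slice(None)] * 3
                sel[axis] = face
                if not component.mask[tuple(sel)].any():
                    continue
                # closing-cap plane sits half a voxel outside the outermost voxel centre
                if face == 0:
                    plane = (pads[axis] - 0.5) * sp[axis]
                else:
                    plane = (pads[axis] + n_axis - 0.5) * sp[axis]
                on_plane = np.abs(verts[:, axis] - plane) < 0.26 * sp[axis]
                cap = on_plane[faces].all(axis=1)
                total -= float(areas[cap].sum())
    return total / 1e6


def equivalent_diameter(component: TubuleComponent, variant: str = "perimeter") -> float:
    """Equivalent diameter (nm) from serial-section contours.

    ``variant="perimeter"`` (default): mean contour perimeter / π — the
    circular approximation under which a cross-section's perimeter/π is
    its diameter.  ``variant="area"``: 2·√(mean contour area / π), kept as
    a sensitivity alternative.
    """
    contours = component.contour_stack()
    return equivalent_diameter_from_contours(contours, variant=variant)


def equivalent_diameter_from_contours(contours: list[SliceContour],
                                      variant: str = "perimeter") -> float:
    if not contours:
        raise MeasurementError("no contours: equivalent diameter undefined")
    if variant == "perimeter":
        per = np.array([c.perimeter for c in contours])
        return float(per.sum() / (len(per) * np.pi))
    if variant == "area":
        ar = np.array([c.area for c in contours])
        return float(2.0 * math.sqrt(ar.mean() / np.pi))
    raise MeasurementError(f"unknown diameter variant {variant!r}")


def _isotropic_mask(component: TubuleComponent) -> tuple[np.ndarray, float, np.ndarray]:
    """Resample the component mask to the min in-plane spacing.

    Returns ``(iso_mask, iso_spacing_nm, scale)`` where ``scale`` maps
    original (z, y, x) indices to iso indices.  3D thinning assumes
    isotropy; lengths are computed in physical units afterwards.
    """
    sx, sy, sz = component.spacing
    t = min(sx, sy)
    factors = np.array([sz / t, sy / t, sx / t])
    int_factors = np.rint(factors).astype(int)
    if np.allclose(factors, int_factors, atol=1e-6):
        m = component.mask
        for ax, f in enumerate(int_factors):
            if f > 1:
                m = np.repeat(m, f, axis=ax)
        return m, t, factors
    m = ndimage.zoom(component.mask.astype(np.uint8), factors, order=0).astype(bool)
    return m, t, factors


def longest_branch_length(component: TubuleComponent,
                          spacing: tuple[float, float, float] | None = None) -> float:
    """Longest skeleton branch length in µm.

    The component is isotropically resampled, thinned to a 3D skeleton,
    and turned into a graph with physical edge lengths.  The reported
    length is the longest shortest-path from the node nearest the
    sarcolemmal attachment to any skeleton tip; without an attachment
    (fragments) the skeleton graph diameter is used.  Because thinning
    retracts skeleton tips by roughly the local radius, the Euclidean
    distance transform value at each path endpoint is added back.
    Single-voxel (or skeleton-less) components return 0 (degenerate).
    """
    if component.n_voxels <= 1:
        logger.info("component %d degenerate (<=1 voxel): length 0", component.component_id)
        return 0.0
    iso, t, factors = _isotropic_mask(component)
    iso = np.pad(iso, 1)
    sk = skeletonize(iso)
    coords = np.argwhere(sk)
    if len(coords) == 0:
        return 0.0
    edt = ndimage.distance_transform_edt(iso, sampling=t)
    if len(coords) == 1:
        # blob thinned to a point: extent is twice the inscribed radius
        z, y, x = coords[0]
        return float(2.0 * edt[z, y, x] / 1000.0)

    coord_index = {tuple(c): i for i, c in enumerate(coords)}
    G = nx.Graph()
    G.add_nodes_from(range(len(coords)))
    offsets = [np.array(o) for o in np.ndindex(3, 3, 3) if o != (1, 1, 1)]
    offsets = [o - 1 for o in offsets]
    for i, c in enumerate(coords):
        for o in offsets:
            j = coord_index.get(tuple(c + o))
            if j is not None and j > i:
                G.add_edge(i, j, weight=float(np.linalg.norm(o) * t))

    att = component.attachment_voxels()
    if len(att) > 0:
        att_local = (att - np.asarray(component.origin)) * factors + factors / 2.0 + 1.0
        tree = cKDTree(att_local)
        d_att, _ = tree.query(coords)
        start = int(np.argmin(d_att))
        sub = G.subgraph(nx.node_connected_component(G, start))
        lengths, paths = nx.single_source_dijkstra(sub, start, weight="weight")
        far = max(lengths, key=lengths.get)
    else:
        # graph diameter by double sweep (exact on trees, which skeletons are)
        comps = max(nx.connected_components(G), key=len)
        sub = G.subgraph(comps)
        n0 = next(iter(comps))
        l0 = nx.single_source_dijkstra_path_length(sub, n0, weight="weight")
        start = max(l0, key=l0.get)
        lengths, paths = nx.single_source_dijkstra(sub, start, weight="weight")
        far = max(lengths, key=lengths.get)

    # voxel-step paths zig-zag around the true centreline; smooth the path
    # coordinates over a ~150 nm window (endpoints kept) before measuring
    path = np.asarray([coords[i] for i in paths[far]], dtype=float) * t
    w = max(3, int(round(150.0 / t)) | 1)
    if len(path) > 2 * w:
        k = np.ones(w) / w
        inner = np.column_stack([np.convolve(path[:, i], k, mode="valid") for i in range(3)])
        path = np.vstack([path[:1], inner, path[-1:]])
    path_nm = float(np.sqrt((np.diff(path, axis=0) ** 2).sum(axis=1)).sum())

    tip_corr = float(edt[tuple(coords[start])] + edt[tuple(coords[far])])
    return (path_nm + tip_corr) / 1000.0


def length_fraction(length_um: float, cell_width_um: float) -> float:
    """Longest-branch length normalized to cell width (penetration measure)."""
    if cell_width_um <= 0:
        raise MeasurementError(f"cell width must be positive, got {cell_width_um}")
    return length_um / cell_width_um


def cell_width_at(volume: LabelVolume, component: TubuleComponent,
                  max_steps: int = 100_000, inside: np.ndarray | None = None) -> float:
    """Cell-mask chord length (µm) along the component's penetration axis.

    The axis is the first principal direction of the component's voxels,
    oriented inward from the sarcolemmal attachment point; the chord is
    marched through the cell mask (tubule lumina included) in half-voxel
    steps until it exits the mask or the volume.
    """
    att = component.attachment_voxels()
    if len(att) == 0:
        raise MeasurementError("component has no sarcolemmal attachment: width undefined")
    sx, sy, sz = volume.spacing
    sp = np.array([sz, sy, sx])
    pts = component.voxel_indices() * sp  # physical nm, (z, y, x)
    centred = pts - pts.mean(axis=0)
    if len(pts) < 2:
        raise MeasurementError("component too small for a principal axis")
    _, vecs = np.linalg.eigh(np.cov(centred.T))
    d = vecs[:, -1]
    p0 = (att * sp).mean(axis=0)
    inward = pts.mean(axis=0) - p0
    if np.dot(d, inward) < 0:
        d = -d

    if inside is None:
        inside = volume.cell_mask(include_objects=True)
    shape = np.array(volume.shape)
    step = min(sx, sy, sz) * 0.5

    def _march(direction: np.ndarray) -> float:
        tlen = 0.0
        for k in range(1, max_steps):
            p = p0 + direction * (k * step)
            idx = np.rint(p / sp).astype(int)
            if np.any(idx < 0) or np.any(idx >= shape):
                break
            if not inside[tuple(idx)]:
                break
            tlen = k * step
        return tlen

    return (_march(d) + _march(-d)) / 1000.0


def measure_components(volume: LabelVolume, components: list[TubuleComponent],
                       animal_id: str = "", cell_id: str = "", region: str = "",
                       diameter_variant: str = "perimeter",
                       cell_width_mode: str = "per_tubule") -> pd.DataFrame:
    """Full morphometry table: one row per component.

    ``cell_width_mode``: ``"per_tubule"`` measures the cell-mask chord
    along each tubule's own axis; ``"cell_mean"`` applies the mean of
    those chords to every tubule in the cell.
    """
    from .classify import classify_component

    rows = []
    widths: dict[int, float] = {}
    inside = volume.cell_mask(include_objects=True) if components else None
    for comp in components:
        cls = classify_component(comp)
        vol = component_volume(comp)
        area = component_surface_area(comp)
        try:
            diam = equivalent_diameter(comp, variant=diameter_variant)
        except MeasurementError:
            diam = np.nan
        if cls == "tubule":
            length = longest_branch_length(comp)
            try:
                width = cell_width_at(volume, comp, inside=inside)
            except MeasurementError:
                width = np.nan
            widths[comp.component_id] = width
        else:
            length, width = np.nan, np.nan
        rows.append({
            "component_id": comp.component_id,
            "class": cls,
            "volume_um3": vol,
            "surface_area_um2": area,
            "equivalent_diameter_nm": diam,
            "longest_branch_um": length,
            "cell_width_um": width,
            "n_voxels": comp.n_voxels,
            "touches_extracellular": comp.touches_extracellular,
            "touches_crop_boundary": comp.touches_crop_boundary,
            "source_labels": "+".join(str(s) for s in sorted(comp.source_labels)),
            "animal_id": animal_id,
            "cell_id": cell_id,
            "region": region,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    if cell_width_mode == "cell_mean" and widths:
        mean_w = float(np.nanmean(list(widths.values())))
        df.loc[df["class"] == "tubule", "cell_width_um"] = mean_w
    df["length_fraction"] = df["longest_branch_um"] / df["cell_width_um"]
    df["oblique_flag"] = df["length_fraction"] > 1.0
    return df


def cell_summaries(records: pd.DataFrame, cell_volume_um3: float) -> dict:
    """Per-cell aggregates: densities and volume fractions.

    Tubule density is the count of sarcolemma-connected tubules per µm³ of
    cell volume; the volume fraction is the summed tubule volume as a
    percentage of cell volume.  Fragment metrics are delegated to
    :func:`ttmorph.classify.fragment_summary`.
    """
    from .classify import fragment_summary

    if cell_volume_um3 <= 0:
        raise MeasurementError("cell volume must be positive")
    tub = records[records["class"] == "tubule"] if len(records) else records
    n_tub = int(len(tub))
    out = {
        "n_components": int(len(records)),
        "tubule_count": n_tub,
        "tubule_density_per_um3": n_tub / cell_volume_um3,
        "tubule_volume_fraction_pct": (
            float(tub["volume_um3"].sum()) / cell_volume_um3 * 100.0 if n_tub else 0.0
        ),
        "cell_volume_um3": cell_volume_um3,
    }
    frag = fragment_summary(records, cell_volume_um3)
    out.update({
        "fragment_count": frag.fragment_count,
        "fragment_density_per_um3": frag.fragment_density,
        "mean_fragment_volume_um3": frag.mean_fragment_volume,
        "fragment_volume_fraction_pct": frag.fragment_volume_fraction,
        "indeterminate_count": frag.indeterminate_count,
    })
    return out


def subsample_metrics(records: pd.DataFrame, k: int = 15, seed: int = 0) -> pd.DataFrame:
    """Uniform random subsample (without replacement) of tubule records.

    Used for the diameter and length statistics only — volume and surface
    area use all tubules.  If fewer than ``k`` tubules exist, all are
    returned (with a log note).  Deterministic given ``seed``.
    """
    tub = records[records["class"] == "tubule"]
    if len(tub) <= k:
        if len(tub) < k:
            logger.info("only %d tubules available for subsample of %d", len(tub), k)
        return tub.copy()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(tub), size=k, replace=False)
    return tub.iloc[np.sort(idx)].copy()
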