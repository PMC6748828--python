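"""Image- and mesh-derived statistics for cell growth and wall anisotropy.

These are the quantification routines of the analysis pipeline: nematic-
tensor texture anisotropy (cortical-microtubule / microfibril arrays), the
per-cell anisotropy normalisation, hysteresis background filtering, Manders
colocalisation at cell edges, root-diameter measurement from outline traces,
3D growth decomposition between segmented time points, and edge-region
intensity enrichment.  They operate on plain numpy arrays / trimesh surfaces
and are exercised against the seeded generators in
:mod:`wallmech.synthetic`, which carry ground truth.

Conventions: pixel/voxel indices are 0-based and refer to pixel centers;
physical distances come from the supplied pixel/voxel size.  The organ's
longitudinal axis is image axis ``x`` (columns for 2D images, first index
for volumes) unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AnisotropyScore",
    "GrowthReport",
    "EnrichmentReport",
    "ColocalisationReport",
    "nematic_orientation_anisotropy",
    "normalized_cell_anisotropy",
    "hysteresis_filter",
    "manders_edge_colocalisation",
    "mean_root_diameter",
    "growth_decomposition",
    "edge_enrichment",
    "EdgeSegment",
]


# ---------------------------------------------------------------------------
# Texture anisotropy (nematic tensor of intensity gradients)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnisotropyScore:
    """Mean texture orientation and degree of anisotropy of a fibril array.

    ``anisotropy`` is the eigenvalue difference of the mean nematic tensor:
    0 for a fully isotropic array, 1 for a perfectly parallel one.  ``angle``
    is in degrees in (-90, 90], measured from the image x-axis (the organ's
    longitudinal axis by convention; subtract from 90 for the angle to the
    transverse axis).
    """

    angle: float
    anisotropy: float
    degenerate: bool = False       # constant image: angle reported as 0


def nematic_orientation_anisotropy(image: np.ndarray,
                                   roi: np.ndarray | None = None,
                                   min_pixels: int = 100) -> AnisotropyScore:
    """Texture orientation/anisotropy from the gradient nematic tensor.

    The local fibril direction is the normal to the intensity gradient; unit
    direction vectors are averaged as a 2x2 nematic (orientation-order)
    tensor over the region of interest.  ``anisotropy`` is the difference of
    its eigenvalues, ``angle`` the principal eigenvector.

    Parameters
    ----------
    image : 2D float array (grayscale)
    roi : boolean mask of the same shape, or an (n, 2) polygon in (x, y)
        pixel coordinates; None uses the whole image.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    mask = _resolve_roi(image.shape, roi)
    if mask.sum() < min_pixels:
        raise ValueError(f"ROI must contain at least {min_pixels} pixels")

    gy, gx = np.gradient(image)     # axis 0 = y (rows), axis 1 = x (cols)
    g2 = gx ** 2 + gy ** 2
    sel = mask & (g2 > 1e-12 * max(g2.max(), 1e-300))
    if not np.any(sel):
        return AnisotropyScore(angle=0.0, anisotropy=0.0, degenerate=True)
    # fibril direction = gradient normal, as a unit vector
    norm = np.sqrt(g2[sel])
    tx, ty = gy[sel] / norm, -gx[sel] / norm
    mxx, myy, mxy = np.mean(tx * tx), np.mean(ty * ty), np.mean(tx * ty)
    # eigen-decomposition of [[mxx, mxy], [mxy, myy]] (trace = 1)
    d = np.hypot(mxx - myy, 2 * mxy)
    anis = float(d)                  # lambda1 - lambda2
    angle = 0.5 * np.degrees(np.arctan2(2 * mxy, mxx - myy))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return AnisotropyScore(angle=float(angle), anisotropy=anis)


def _resolve_roi(shape, roi):
    if roi is None:
        return np.ones(shape, dtype=bool)
    roi = np.asarray(roi)
    if roi.dtype == bool:
        if roi.shape != shape:
            raise ValueError("ROI mask shape mismatch")
        return roi
    from skimage.draw import polygon2mask
    # polygon given as (x, y) pixel coordinates -> (row, col)
    poly_rc = np.column_stack([roi[:, 1], roi[:, 0]])
    return polygon2mask(shape, poly_rc)


def normalized_cell_anisotropy(a_max: float, a_min: float) -> float:
    """Per-cell anisotropy normalisation (a_max - a_min) / (a_max + a_min).

    Maps a cell's extreme anisotropy readings to [0, 1]: 0 for a purely
    isotropic array (a_max = a_min), 1 for a purely anisotropic one
    (a_min = 0).
    """
    if not (a_max >= a_min >= 0):
        raise ValueError("require a_max >= a_min >= 0")
    if a_max == 0:
        raise ValueError("anisotropy normalisation undefined for a_max = a_min = 0")
    return (a_max - a_min) / (a_max + a_min)


# ---------------------------------------------------------------------------
# Background removal & colocalisation
# ---------------------------------------------------------------------------

def hysteresis_filter(stack: np.ndarray, low: float | None = None,
                      high: float | None = None) -> np.ndarray:
    """Hysteresis background filter for confocal stacks.

    Keeps connected components that contain at least one voxel >= ``high``,
    extended down to ``low``.  When thresholds are omitted they derive from
    image statistics: low = mean intensity, high = mean + 2 SD capped at the
    maximum intensity (so high >= low always holds).
    """
    from skimage.filters import apply_hysteresis_threshold
    stack = np.asarray(stack, dtype=float)
    if low is None:
        low = float(stack.mean())
    if high is None:
        high = float(min(stack.mean() + 2.0 * stack.std(), stack.max()))
        high = max(high, low)
    if low > high:
        raise ValueError("low threshold exceeds high threshold")
    if stack.max() < high or high == 0:
        return np.zeros(stack.shape, dtype=bool)
    return apply_hysteresis_threshold(stack, low, high)


@dataclass(frozen=True)
class ColocalisationReport:
    """Manders coefficients for one edge region.

    M1: fraction of channel-A intensity located where channel B is present;
    M2: the converse.  Regions where either fluorophore occupies less than
    the occupancy threshold (default 10% of pixels) are flagged excluded.
    """

    M1: float
    M2: float
    excluded: bool
    occupancy_a: float = float("nan")
    occupancy_b: float = float("nan")


def manders_edge_colocalisation(channel_a: np.ndarray, channel_b: np.ndarray,
                                region: np.ndarray,
                                min_occupancy: float = 0.10) -> ColocalisationReport:
    """Manders M1/M2 within one edge region of two registered channels."""
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must have identical shape")
    region = np.asarray(region, dtype=bool)
    if region.shape != a.shape:
        raise ValueError("region mask shape mismatch")
    n = int(region.sum())
    if n == 0:
        raise ValueError("empty edge region")
    av, bv = a[region], b[region]
    occ_a = float(np.count_nonzero(av) / n)
    occ_b = float(np.count_nonzero(bv) / n)
    sum_a, sum_b = av.sum(), bv.sum()
    m1 = float(av[bv > 0].sum() / sum_a) if sum_a > 0 else 0.0
    m2 = float(bv[av > 0].sum() / sum_b) if sum_b > 0 else 0.0
    excluded = (occ_a < min_occupancy) or (occ_b < min_occupancy)
    return ColocalisationReport(M1=m1, M2=m2, excluded=excluded,
                                occupancy_a=occ_a, occupancy_b=occ_b)


# ---------------------------------------------------------------------------
# Root diameter from outline traces
# ---------------------------------------------------------------------------

def mean_root_diameter(trace_a: np.ndarray, trace_b: np.ndarray,
                       pixel_size: float = 1.0,
                       tip_exclusion: float = 100.0,
                       tip: str = "start") -> float:
    """Mean root diameter from two traced outline polylines.

    For each retained pixel on one side the closest neighbour on the other
    side is found and the Euclidean distance recorded; the mean over all
    evaluated pixels of both sides is returned (um).  Points within
    ``tip_exclusion`` (um of arc length) of the tip are excluded to avoid
    the tapering apex.  ``tip`` names the polyline end nearest the root tip
    ('start' or 'end').
    """
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or len(a) < 2 or b.ndim != 2 or len(b) < 2:
        raise ValueError("traces must be (n, 2) arrays with n >= 2")
    if tip not in ("start", "end"):
        raise ValueError("tip must be 'start' or 'end'")

    def retained(t):
        arc = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(t, axis=0), axis=1))]) * pixel_size
        if tip == "end":
            arc = arc[-1] - arc
        keep = arc >= tip_exclusion
        if keep.sum() < 1:
            raise ValueError("trace shorter than the tip exclusion")
        return t[keep]

    ra, rb = retained(a), retained(b)
    d_ab, _ = cKDTree(b).query(ra)
    d_ba, _ = cKDTree(a).query(rb)
    return float(np.concatenate([d_ab, d_ba]).mean() * pixel_size)


# ---------------------------------------------------------------------------
# 3D growth decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthReport:
    """Relative growth of one cell between two time points.

    Ratios are t1/t0; the zone label separates slowly growing meristematic
    cells from elongation-zone cells at the volume-growth threshold
    (default 1.5-fold per observation interval).
    """

    volume_ratio: float
    longitudinal_ratio: float
    radial_ratio: float
    circumferential_ratio: float
    zone: str

    @property
    def is_meristematic(self) -> bool:
        return self.zone == "meristematic"


def growth_decomposition(mesh_t0, mesh_t1, frame: np.ndarray | None = None,
                         threshold: float = 1.5) -> GrowthReport:
    """Total and per-direction growth of a segmented cell.

    Parameters
    ----------
    mesh_t0, mesh_t1 : trimesh.Trimesh
        Watertight surface meshes of the same cell at the two time points.
    frame : (3, 3) array, rows = longitudinal / radial / circumferential
        unit vectors of the organ frame (default: identity).
    threshold : volume-ratio cutoff separating meristematic (<) from
        elongation-zone (>=) cells.

    Directional ratios are ratios of cell extents along each frame axis,
    which is exact for affine growth.
    """
    frame = np.eye(3) if frame is None else np.asarray(frame, dtype=float)
    if frame.shape != (3, 3) or not np.allclose(frame @ frame.T, np.eye(3),
                                                atol=1e-8):
        raise ValueError("frame must be orthonormal (rows = axes)")
    for m in (mesh_t0, mesh_t1):
        if not m.is_watertight:
            raise ValueError("growth decomposition requires watertight meshes")
    vol = float(mesh_t1.volume / mesh_t0.volume)

    def extents(m):
        proj = m.vertices @ frame.T
        return proj.max(axis=0) - proj.min(axis=0)

    e0, e1 = extents(mesh_t0), extents(mesh_t1)
    ratios = e1 / e0
    zone = "meristematic" if vol < threshold else "elongation"
    return GrowthReport(volume_ratio=vol, longitudinal_ratio=float(ratios[0]),
                        radial_ratio=float(ratios[1]),
                        circumferential_ratio=float(ratios[2]), zone=zone)


# ---------------------------------------------------------------------------
# Edge-region intensity enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeSegment:
    """One geometric cell edge: a line segment with an orientation class."""

    p0: np.ndarray                 # um
    p1: np.ndarray                 # um
    edge_class: str                # 'longitudinal' | 'transverse'

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.asarray(self.p1) - np.asarray(self.p0)))


@dataclass
class EnrichmentReport:
    """Per-edge relative intensity within the outer-shell edge bands.

    ``relative_intensity[i]`` is the mean intensity of voxels assigned to
    edge i divided by the voxel-weighted mean over all edge voxels of the
    cell, so the voxel-weighted mean of the entries is 1 by construction.
    """

    relative_intensity: np.ndarray
    edge_length: np.ndarray
    edge_class: list
    voxel_counts: np.ndarray

    def to_frame(self):
        """Tabular form: one row per edge (CSV-ready).

        Columns: ``edge_index``, ``edge_class``, ``edge_length_um``,
        ``relative_intensity``, ``voxel_count``.
        """
        import pandas as pd
        return pd.DataFrame({
            "edge_index": np.arange(len(self.edge_class)),
            "edge_class": self.edge_class,
            "edge_length_um": self.edge_length,
            "relative_intensity": self.relative_intensity,
            "voxel_count": self.voxel_counts,
        })

    def class_mean(self, edge_class: str) -> float:
        sel = np.array([c == edge_class for c in self.edge_class])
        if not sel.any():
            raise ValueError(f"no edges of class {edge_class!r}")
        w = self.voxel_counts[sel]
        return float((self.relative_intensity[sel] * w).sum() / w.sum())


def edge_enrichment(volume: np.ndarray, cell_mask: np.ndarray,
                    edges: list, voxel_size: float = 1.0,
                    shell_depth: float = 2.0,
                    edge_band: float = 1.0) -> EnrichmentReport:
    """Edge enrichment of a marker intensity within a segmented cell.

    The analysis is restricted to the shell 0..``shell_depth`` um from the
    cell surface; within it, voxels closer than ``edge_band`` um to a
    geometric edge line form that edge's band (each voxel is assigned to its
    nearest edge).  Intensities are normalised by the voxel-weighted mean
    over all edge voxels of the cell.
    """
    from scipy.ndimage import distance_transform_edt
    volume = np.asarray(volume, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if volume.shape != cell_mask.shape:
        raise ValueError("volume and cell mask shapes differ")
    if not edges:
        raise ValueError("no edges supplied")

    depth = distance_transform_edt(cell_mask) * voxel_size
    shell = cell_mask & (depth <= shell_depth)

    idx = np.argwhere(shell)
    pts = idx * voxel_size
    dists = np.stack([_point_segment_distance(pts, e.p0, e.p1) for e in edges],
                     axis=1)
    nearest = np.argmin(dists, axis=1)
    dmin = dists[np.arange(len(pts)), nearest]
    in_band = dmin <= edge_band
    if not in_band.any():
        raise ValueError("edge band contains no voxels")

    vals = volume[tuple(idx[in_band].T)]
    owner = nearest[in_band]
    n_edges = len(edges)
    counts = np.bincount(owner, minlength=n_edges)
    sums = np.bincount(owner, weights=vals, minlength=n_edges)
    grand_mean = vals.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = (sums / np.maximum(counts, 1)) / grand_mean
    rel[counts == 0] = np.nan
    return EnrichmentReport(
        relative_intensity=rel,
        edge_length=np.array([e.length for e in edges]),
        edge_class=[e.edge_class for e in edges],
        voxel_counts=counts,
    )


def _point_segment_distance(pts, p0, p1):
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        return np.linalg.norm(pts - p0, axis=1)
    t = np.clip((pts - p0) @ d / L2, 0.0, 1.0)
    return np.linalg.norm(pts - (p0 + t[:, None] * d), axis=1)
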