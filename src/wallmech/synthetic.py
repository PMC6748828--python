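"""Seeded synthetic-data generators with attached ground truth.

Each generator emulates one class of input the morphometric statistics
consume — oriented fibril textures, two-channel colocalisation pairs,
tapering root outline traces, affinely grown cell mesh pairs, and
edge-enriched intensity volumes around a labelled cell surface — and returns
the payload together with a ground-truth record sufficient to score the
corresponding statistic.  Identical seed and parameters give bit-identical
payloads; all randomness flows through an explicit ``numpy`` Generator (no
global state).

Noise is additive Gaussian clipped at zero for images/volumes; mesh vertex
jitter is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphometrics import EdgeSegment, GrowthReport

__all__ = [
    "make_fibril_texture",
    "make_colocalised_pair",
    "make_root_outline",
    "make_cell_timepair",
    "make_edge_intensity_cell",
]


def _rng(seed):
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Oriented fibril texture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FibrilTextureTruth:
    angle: float          # degrees from image x-axis
    coherence: float
    noise_sd: float
    seed: int


def make_fibril_texture(angle: float, coherence: float, noise_sd: float = 0.0,
                        size: int = 128, seed: int = 0,
                        n_waves: int = 6, wavelength: float = 10.0):
    """Oriented band-pass texture emulating a fibril (CMT/CMF) array.

    A superposition of sinusoidal plane waves whose propagation direction is
    normal to the fibril angle (so intensity is constant along the fibrils)
    is blended with an isotropic filtered-noise field; ``coherence`` in
    [0, 1] sets the oriented fraction.  The gradient nematic anisotropy of
    the result increases monotonically with coherence: 0 gives an isotropic
    texture, 1 a perfectly parallel one.

    Returns ``(image, truth)`` with the image in [0, 1].
    """
    if not 0.0 <= coherence <= 1.0:
        raise ValueError("coherence must lie in [0, 1]")
    rng = _rng(seed)
    y, x = np.mgrid[0:size, 0:size].astype(float)
    th = np.radians(angle)
    # coordinate along the normal to the fibril direction
    s = -np.sin(th) * x + np.cos(th) * y
    oriented = np.zeros((size, size))
    for _ in range(n_waves):
        # keep wavelengths well above the pixel scale so finite-difference
        # gradients stay direction-unbiased
        k = 2 * np.pi / (wavelength * (0.8 + 0.8 * rng.random()))
        phase = rng.uniform(0, 2 * np.pi)
        oriented += np.sin(k * s + phase)
    oriented /= n_waves

    from scipy.ndimage import gaussian_filter
    iso = gaussian_filter(rng.standard_normal((size, size)),
                          sigma=wavelength / 4.0)
    iso /= max(iso.std(), 1e-12)
    oriented /= max(oriented.std(), 1e-12)

    img = coherence * oriented + (1.0 - coherence) * iso
    if noise_sd > 0:
        img = img + noise_sd * rng.standard_normal((size, size))
    img = (img - img.min()) / max(np.ptp(img), 1e-12)
    truth = FibrilTextureTruth(angle=float(angle), coherence=float(coherence),
                               noise_sd=float(noise_sd), seed=int(seed))
    return img, truth


# ---------------------------------------------------------------------------
# Colocalisation pair
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColocalisedPairTruth:
    M1: float
    M2: float
    overlap: float
    occupancy_a: float
    occupancy_b: float
    seed: int


def make_colocalised_pair(overlap: float, occupancy_a: float = 0.3,
                          occupancy_b: float = 0.3, size: int = 64,
                          seed: int = 0, noise_sd: float = 0.0):
    """Two binary-plus-noise channels with controlled support overlap.

    ``overlap`` is the fraction of channel A's support also occupied by B.
    For noiseless uniform-intensity channels the expected Manders
    coefficients are M1 = overlap and M2 = overlap * |A| / |B|.
    """
    for name, v in [("overlap", overlap), ("occupancy_a", occupancy_a),
                    ("occupancy_b", occupancy_b)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    n = size * size
    na, nb = int(round(occupancy_a * n)), int(round(occupancy_b * n))
    n_common = int(round(overlap * na))
    if n_common > nb:
        raise ValueError("infeasible: overlap * |A| exceeds |B|")
    if na + nb - n_common > n:
        raise ValueError("infeasible: supports exceed the image")
    rng = _rng(seed)
    perm = rng.permutation(n)
    ia = perm[:na]
    ib = np.concatenate([perm[:n_common],                 # shared with A
                         perm[na:na + nb - n_common]])    # disjoint from A
    a = np.zeros(n)
    b = np.zeros(n)
    a[ia] = 1.0
    b[ib] = 1.0
    a, b = a.reshape(size, size), b.reshape(size, size)
    if noise_sd > 0:
        a = np.clip(a + noise_sd * rng.standard_normal(a.shape), 0, None)
        b = np.clip(b + noise_sd * rng.standard_normal(b.shape), 0, None)
    m1 = overlap
    m2 = overlap * na / nb if nb else 0.0
    truth = ColocalisedPairTruth(M1=float(m1), M2=float(m2),
                                 overlap=float(overlap),
                                 occupancy_a=na / n, occupancy_b=nb / n,
                                 seed=int(seed))
    return a, b, truth


# ---------------------------------------------------------------------------
# Root outline traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RootOutlineTruth:
    plateau_diameter: float
    taper_length: float
    length: float
    pixel_size: float
    seed: int

    def diameter_profile(self, x):
        """d(x): linear taper from 0 at the tip to the plateau diameter."""
        x = np.asarray(x, dtype=float)
        if self.taper_length <= 0:
            return np.full_like(x, self.plateau_diameter)
        return self.plateau_diameter * np.clip(x / self.taper_length, 0.0, 1.0)

    def expected_mean_diameter(self, tip_exclusion: float,
                               n_quad: int = 20001) -> float:
        """Mean nearest-neighbour side-to-side distance on the retained region.

        Evaluated by dense quadrature of the analytic outline: for each point
        on one side, the exact distance to the opposite straight-line outline
        segment (accounting for taper obliquity).  Independent of the
        pixel-based estimator.
        """
        xs = np.linspace(tip_exclusion, self.length, n_quad)
        yi = self.diameter_profile(xs) / 2.0
        # exact distance from each point (x, d/2) on one side to the
        # opposite outline polyline: taper segment (0,0)->(taper,-D/2),
        # then the plateau half-line y = -D/2
        D, Lt = self.plateau_diameter, self.taper_length
        if Lt > 0:
            p0 = np.array([0.0, 0.0])
            p1 = np.array([Lt, -D / 2.0])
            seg = p1 - p0
            t = np.clip(((xs - p0[0]) * seg[0] + (yi - p0[1]) * seg[1])
                        / (seg @ seg), 0.0, 1.0)
            d_seg = np.hypot(xs - (p0[0] + t * seg[0]),
                             yi - (p0[1] + t * seg[1]))
        else:
            d_seg = np.full_like(xs, np.inf)
        d_plat = np.hypot(np.maximum(Lt - xs, 0.0), yi + D / 2.0)
        return float(np.minimum(d_seg, d_plat).mean())


def make_root_outline(plateau_diameter: float = 50.0,
                      taper_length: float = 100.0, noise_sd: float = 0.0,
                      length: float = 500.0, pixel_size: float = 1.0,
                      seed: int = 0):
    """Two outline traces of a tapering root, tip at x = 0.

    The diameter grows linearly from the tip over ``taper_length`` um and
    then plateaus.  Returns ``(trace_a, trace_b, truth)`` with traces in
    pixel coordinates, one point per pixel along x.
    """
    if plateau_diameter <= 0 or length <= 0 or pixel_size <= 0:
        raise ValueError("dimensions must be positive")
    rng = _rng(seed)
    truth = RootOutlineTruth(plateau_diameter=float(plateau_diameter),
                             taper_length=float(taper_length),
                             length=float(length),
                             pixel_size=float(pixel_size), seed=int(seed))
    xs_um = np.arange(0.0, length + 1e-9, pixel_size)
    d = truth.diameter_profile(xs_um)
    ya = d / 2.0
    yb = -d / 2.0
    if noise_sd > 0:
        ya = ya + noise_sd * rng.standard_normal(len(xs_um))
        yb = yb + noise_sd * rng.standard_normal(len(xs_um))
    xs_px = xs_um / pixel_size
    trace_a = np.column_stack([xs_px, ya / pixel_size])
    trace_b = np.column_stack([xs_px, yb / pixel_size])
    return trace_a, trace_b, truth


# ---------------------------------------------------------------------------
# Cell mesh time pair (growth)
# ---------------------------------------------------------------------------

def make_cell_timepair(base_dims=(8.0, 5.0, 5.0), scales=(1.2, 1.0, 1.0),
                       seed: int = 0, jitter_sd: float = 0.0):
    """Watertight cell surface meshes at two time points under affine growth.

    ``scales`` = (longitudinal, radial, circumferential) stretch factors
    applied between t0 and t1.  Returns ``(mesh_t0, mesh_t1, truth)`` where
    truth is the exact :class:`GrowthReport` (threshold 1.5).
    """
    import trimesh
    sL, sR, sC = (float(s) for s in scales)
    if min(sL, sR, sC) <= 0:
        raise ValueError("scale factors must be positive")
    m0 = trimesh.creation.box(extents=list(base_dims))
    m1 = m0.copy()
    m1.vertices = m1.vertices * np.array([sL, sR, sC])
    if jitter_sd > 0:
        rng = _rng(seed)
        for m in (m0, m1):
            m.vertices = m.vertices + jitter_sd * rng.standard_normal(
                m.vertices.shape)
    vol = sL * sR * sC
    truth = GrowthReport(
        volume_ratio=vol, longitudinal_ratio=sL, radial_ratio=sR,
        circumferential_ratio=sC,
        zone="meristematic" if vol < 1.5 else "elongation")
    return m0, m1, truth


# ---------------------------------------------------------------------------
# Edge-enriched intensity volume
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeIntensityTruth:
    relative_intensity: np.ndarray   # expected per-edge enrichment
    edge_class: tuple
    seed: int


def make_edge_intensity_cell(edge_ratios: dict | None = None,
                             background: float = 0.1, noise_sd: float = 0.0,
                             voxel_size: float = 0.25,
                             cell_dims=(10.0, 6.0, 6.0), margin: float = 1.5,
                             edge_band: float = 1.0, seed: int = 0):
    """Intensity volume around a box cell with edge-localised marker signal.

    ``edge_ratios`` maps edge class ('longitudinal'/'transverse') to the
    marker intensity laid down in that edge's band (arbitrary units).  The
    cell is an axis-aligned box (x = organ longitudinal axis); its 12
    geometric edges are classified by their direction: edges parallel to x
    are longitudinal, the others transverse.

    Returns ``(volume, cell_mask, edges, truth)`` matching the signature of
    :func:`wallmech.morphometrics.edge_enrichment`; ``truth`` holds the
    expected per-edge relative enrichment computed analytically from the
    constructed intensities and exact voxel band assignment.
    """
    edge_ratios = dict(edge_ratios or {"longitudinal": 2.0, "transverse": 1.0})
    rng = _rng(seed)
    dims = np.asarray(cell_dims, dtype=float)
    lo = np.full(3, margin)
    hi = lo + dims
    shape = tuple(int(np.ceil((d + 2 * margin) / voxel_size)) for d in dims)

    centers = [np.arange(s) * voxel_size for s in shape]
    X, Y, Z = np.meshgrid(*centers, indexing="ij")
    cell_mask = ((X >= lo[0]) & (X <= hi[0]) & (Y >= lo[1]) & (Y <= hi[1])
                 & (Z >= lo[2]) & (Z <= hi[2]))

    corners = [lo, hi]
    edges = []
    for ax in range(3):
        for s1 in (0, 1):
            for s2 in (0, 1):
                axes = [a for a in range(3) if a != ax]
                p0 = np.empty(3)
                p1 = np.empty(3)
                p0[ax], p1[ax] = lo[ax], hi[ax]
                p0[axes[0]] = p1[axes[0]] = corners[s1][axes[0]]
                p0[axes[1]] = p1[axes[1]] = corners[s2][axes[1]]
                cls = "longitudinal" if ax == 0 else "transverse"
                edges.append(EdgeSegment(p0=p0, p1=p1, edge_class=cls))

    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    from .morphometrics import _point_segment_distance
    dists = np.stack([_point_segment_distance(pts, e.p0, e.p1)
                      for e in edges], axis=1)
    nearest = np.argmin(dists, axis=1)
    dmin = dists[np.arange(len(pts)), nearest]
    in_band = (dmin <= edge_band).reshape(shape)
    owner = nearest.reshape(shape)

    volume = np.full(shape, background, dtype=float)
    edge_vals = np.array([edge_ratios[e.edge_class] for e in edges])
    volume[in_band] = edge_vals[owner[in_band]]
    if noise_sd > 0:
        volume = np.clip(volume + noise_sd * rng.standard_normal(shape),
                         0, None)

    # expected enrichment: the statistic restricts to the outer shell, but
    # within each band the laid-down intensity is constant, so the expected
    # relative value is the class intensity over the voxel-weighted mean
    from scipy.ndimage import distance_transform_edt
    depth = distance_transform_edt(cell_mask) * voxel_size
    shell = cell_mask & (depth <= 2.0)
    sel = shell & in_band
    vals = edge_vals[owner[sel]]
    grand = vals.mean()
    counts = np.bincount(owner[sel], minlength=len(edges))
    sums = np.bincount(owner[sel], weights=vals, minlength=len(edges))
    rel = (sums / np.maximum(counts, 1)) / grand
    truth = EdgeIntensityTruth(relative_intensity=rel,
                               edge_class=tuple(e.edge_class for e in edges),
                               seed=int(seed))
    return volume, cell_mask, edges, truth
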