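"""Synthetic tissue simulator: ground-truthed binary membrane images.

The prior domain for training is a honeycomb of bright cell membranes inside
tissue islands separated by dark grooves, the en-face appearance of the
living epidermis under reflectance confocal microscopy. Images are built in
three stages:

1. a random tissue mask: islands bounded by closed composite quadratic
   Bezier curves through jittered control points on a circle;
2. cell centers: a hard-core (sequential inhibition) point process inside the
   tissue, controlled by a density and a minimum inter-point distance;
3. membranes: the Voronoi tessellation of the centers restricted to the
   tissue, plus the island outer contours, dilated to a target width.

A rendering step corrupts the binary image with multiplicative spatially
correlated speckle, additive bright blobs (organelle-like noise), and a
low-frequency illumination field, emulating the degradations of real
confocal images. A non-confluent variant draws disk-shaped cells with a
bounded pairwise overlap, the prior used when cells do not tile the tissue.

Every generator is a pure function of its arguments including the seed;
per-sample seeds are derived with ``numpy.random.SeedSequence([seed, i])``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from skimage.morphology import disk as disk_se


def _dilate(x, r):
    return ndi.binary_dilation(x, structure=disk_se(r))


def _erode(x, r):
    return ndi.binary_erosion(x, structure=disk_se(r))


# ---------------------------------------------------------------------------
# Types


@dataclass
class TissueMask:
    mask: np.ndarray  # 2D bool, True = tissue island

    @property
    def shape(self):
        return self.mask.shape

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class SeedSet:
    points: np.ndarray  # (n, 2) float, (row, col)
    min_distance: float
    density: float
    saturated: bool = False

    def __len__(self):
        return len(self.points)


@dataclass
class SynthSample:
    binary: np.ndarray  # 2D bool, True = membrane
    centers: SeedSet
    mask: TissueMask
    params: dict
    rng_seed: int


@dataclass
class NoiseParams:
    """Rendering degradations; all dimensionless except the two scales (px).

    ``membrane_contrast`` is the noiseless membrane brightness in (0, 1];
    speckle is multiplicative Gaussian noise smoothed at
    ``speckle_correlation_px``; blobs are additive bright Gaussian spots at
    ``blob_density`` per px^2; the illumination field modulates brightness at
    the ``illum_scale_px`` scale with relative amplitude ``illum_amplitude``.
    """

    speckle_sigma: float = 0.35
    speckle_correlation_px: float = 2.0
    blob_density: float = 2e-4
    blob_intensity: float = 0.5
    illum_amplitude: float = 0.3
    illum_scale_px: float = 64.0
    membrane_contrast: float = 0.75

    def __post_init__(self):
        vals = asdict(self)
        for k, v in vals.items():
            if v < 0:
                raise ValueError(f"{k} must be non-negative")
        if not (0 < self.membrane_contrast <= 1):
            raise ValueError("membrane_contrast must be in (0, 1]")


def sample_rng(base_seed: int, index: int = 0) -> np.random.Generator:
    """Counter-based per-artifact generator so sample i is reproducible alone."""
    return np.random.default_rng(np.random.SeedSequence([int(base_seed), int(index)]))


# ---------------------------------------------------------------------------
# Tissue mask


def _bezier_island(center, radius, n_ctrl, jitter, rng):
    """Closed composite quadratic Bezier through jittered circle points."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_ctrl))
    radii = radius * (1 + jitter * rng.uniform(-1, 1, n_ctrl))
    pts = np.stack([center[0] + radii * np.sin(angles),
                    center[1] + radii * np.cos(angles)], axis=1)
    # smooth closed curve: each Bezier piece runs between consecutive edge
    # midpoints with the control point at the vertex
    mids = (pts + np.roll(pts, -1, axis=0)) / 2.0
    t = np.linspace(0, 1, 20)[:, None]
    curve = []
    for i in range(n_ctrl):
        p0 = mids[i - 1]
        p1 = pts[i]
        p2 = mids[i]
        seg = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2
        curve.append(seg)
    return np.concatenate(curve, axis=0)


def generate_tissue_mask(shape: Tuple[int, int], n_islands: int, rng_seed: int,
                         smoothness: float = 0.7,
                         radius_frac: Tuple[float, float] = (0.18, 0.32),
                         max_retries: int = 200) -> TissueMask:
    """Random tissue mask with exactly ``n_islands`` connected components.

    ``smoothness`` in (0, 1]: 1 gives near-circular islands, smaller values
    increase the boundary jitter of the Bezier control points. Candidate
    islands touching an existing island (within a 2 px gap) are redrawn;
    after ``max_retries`` failed draws a ``RuntimeError`` is raised.
    """
    h, w = shape
    if h < 64 or w < 64:
        raise ValueError("shape must be at least 64x64")
    if n_islands < 0:
        raise ValueError("n_islands must be >= 0")
    rng = sample_rng(rng_seed, 0)
    mask = np.zeros(shape, dtype=bool)
    if n_islands == 0:
        return TissueMask(mask)

    jitter = float(np.clip(1.0 - smoothness, 0.0, 0.9))
    placed = 0
    tries = 0
    se = disk_se(2)  # enforce a >=2 px groove between islands
    while placed < n_islands:
        if tries >= max_retries:
            raise RuntimeError(
                f"could not place {n_islands} islands in {shape} after "
                f"{max_retries} retries")
        tries += 1
        # islands may be clipped by the patch border (a 3 px background frame
        # is kept so grooves always reach the border); the radius shrinks
        # slowly over retries so crowded layouts remain placeable
        radius = (rng.uniform(*radius_frac) * min(h, w)
                  / max(1.0, n_islands ** 0.35) * 0.98 ** tries)
        center = (rng.uniform(0.15 * h, 0.85 * h), rng.uniform(0.15 * w, 0.85 * w))
        n_ctrl = int(rng.integers(6, 13))
        curve = _bezier_island(center, radius, n_ctrl, jitter, rng)
        cand = np.zeros(shape, dtype=bool)
        rr, cc = draw_polygon(curve[:, 0], curve[:, 1], shape=shape)
        cand[rr, cc] = True
        cand[:3, :] = cand[-3:, :] = False
        cand[:, :3] = cand[:, -3:] = False
        cand = ndi.binary_fill_holes(cand)
        if cand.sum() < 64:
            continue
        # a fill of a self-intersecting curve may split; keep largest part
        lab, n = ndi.label(cand)
        if n != 1:
            sizes = ndi.sum(cand, lab, index=range(1, n + 1))
            cand = lab == (1 + int(np.argmax(sizes)))
        if (ndi.binary_dilation(cand, structure=se) & mask).any():
            continue
        mask |= cand
        placed += 1

    lab, n = ndi.label(mask)
    assert n == n_islands
    return TissueMask(mask)


# ---------------------------------------------------------------------------
# Hard-core seeds


def sample_hardcore_seeds(mask: TissueMask, density: float, min_distance: float,
                          rng_seed: int, edge_margin: float = 3.0,
                          max_proposals: Optional[int] = None) -> SeedSet:
    """Sequential-inhibition sampling of cell centers inside the tissue.

    A uniform candidate (drawn from tissue pixels eroded by ``edge_margin``
    so centers stay clear of the island contour) is accepted iff it lies at
    least ``min_distance`` from every previously accepted point. Sampling
    stops at ``round(density * tissue_area)`` points or when the proposal
    budget is exhausted, in which case the returned set is flagged
    ``saturated``.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    if min_distance <= 0:
        raise ValueError("min_distance must be > 0")
    m = mask.mask
    target = int(round(density * m.sum()))
    empty = SeedSet(points=np.empty((0, 2)), min_distance=min_distance,
                    density=density)
    if target == 0:
        return empty
    interior = _erode(m, int(round(edge_margin))) if edge_margin > 0 else m
    coords = np.argwhere(interior)
    if len(coords) == 0:
        coords = np.argwhere(m)
        if len(coords) == 0:
            return empty
    rng = sample_rng(rng_seed, 0)
    if max_proposals is None:
        max_proposals = max(2000, 200 * target)

    accepted = np.empty((0, 2))
    d2 = min_distance * min_distance
    proposals = 0
    while len(accepted) < target and proposals < max_proposals:
        proposals += 1
        p = coords[rng.integers(len(coords))] + rng.uniform(-0.5, 0.5, 2)
        if len(accepted):
            dd = accepted - p
            if np.min(np.einsum("ij,ij->i", dd, dd)) < d2:
                continue
        accepted = np.vstack([accepted, p])
    return SeedSet(points=accepted, min_distance=min_distance, density=density,
                   saturated=len(accepted) < target)


# ---------------------------------------------------------------------------
# Voronoi membranes


def render_membranes(seeds: SeedSet, mask: TissueMask,
                     membrane_width: int = 3) -> SynthSample:
    """Voronoi boundaries inside the tissue plus island contours.

    Each tissue pixel is affiliated with its nearest seed; membrane pixels are
    those whose 4-neighbourhood spans two affiliations, unioned with the
    island outer contour, then dilated to ``membrane_width``. Every seed ends
    up inside its own enclosed interior region.
    """
    if membrane_width < 1:
        raise ValueError("membrane_width must be >= 1")
    if len(seeds) == 0:
        raise ValueError("seeds must be non-empty")
    m = mask.mask
    h, w = m.shape
    contour = m & ~_erode(m, 1)
    if len(seeds) == 1:
        boundary = np.zeros_like(m)
    else:
        tree = cKDTree(seeds.points)
        coords = np.argwhere(m)
        _, lab_flat = tree.query(coords, k=1)
        labels = np.full((h, w), -1, dtype=np.int32)
        labels[m] = lab_flat
        boundary = np.zeros_like(m)
        # 4-neighbour affiliation change (within tissue)
        dv = (labels[:-1, :] != labels[1:, :]) & m[:-1, :] & m[1:, :]
        boundary[:-1, :] |= dv
        dh = (labels[:, :-1] != labels[:, 1:]) & m[:, :-1] & m[:, 1:]
        boundary[:, :-1] |= dh
    membrane = boundary | contour
    r = (membrane_width - 1) // 2
    if r > 0:
        membrane = _dilate(membrane, r)
    membrane &= m | contour
    # absorb rasterization slivers: interior components that contain no seed
    # (1-2 px crescents pinched off between the contour and a dilated Voronoi
    # edge) are merged back into the membrane
    interior = m & ~membrane
    lab, n = ndi.label(interior)
    if n > len(seeds):
        idx = np.clip(np.round(seeds.points).astype(int), 0,
                      [h - 1, w - 1])
        seeded = set(lab[idx[:, 0], idx[:, 1]]) - {0}
        sliver = np.isin(lab, [k for k in range(1, n + 1) if k not in seeded])
        membrane |= sliver
    return SynthSample(
        binary=membrane, centers=seeds, mask=mask,
        params={"membrane_width": membrane_width}, rng_seed=-1)


# ---------------------------------------------------------------------------
# Rendering


def _correlated_field(shape, scale_px, rng):
    g = rng.standard_normal(shape)
    if scale_px > 0:
        g = ndi.gaussian_filter(g, scale_px)
    s = g.std()
    if s > 0:
        g = g / s
    return g


def render_synthetic_rcm(sample: SynthSample, noise: NoiseParams,
                         rng_seed: int) -> np.ndarray:
    """Corrupt a binary membrane image into a confocal-like grayscale image.

    image = clip(base * illumination * (1 + speckle) + blobs, 0, 1) with
    base = membrane_contrast on membrane pixels. With all noise parameters
    zero and contrast 1 the output equals the binary image exactly.
    """
    rng = sample_rng(rng_seed, 0)
    binary = sample.binary
    h, w = binary.shape
    base = binary.astype(np.float64) * noise.membrane_contrast

    if noise.illum_amplitude > 0:
        f = _correlated_field((h, w), noise.illum_scale_px, rng)
        mx = np.abs(f).max()
        if mx > 0:
            f = f / mx
        illum = 1.0 + noise.illum_amplitude * f
    else:
        illum = 1.0

    if noise.speckle_sigma > 0:
        speckle = 1.0 + noise.speckle_sigma * _correlated_field(
            (h, w), noise.speckle_correlation_px, rng)
    else:
        speckle = 1.0

    img = base * illum * speckle

    n_blobs = rng.poisson(noise.blob_density * h * w) if noise.blob_density > 0 else 0
    for _ in range(n_blobs):
        r0, c0 = rng.uniform(0, h), rng.uniform(0, w)
        sig = rng.uniform(1.0, 3.0)
        rad = int(np.ceil(3 * sig))
        rr = np.arange(max(0, int(r0) - rad), min(h, int(r0) + rad + 1))
        cc = np.arange(max(0, int(c0) - rad), min(w, int(c0) + rad + 1))
        if len(rr) == 0 or len(cc) == 0:
            continue
        dr = (rr - r0)[:, None] ** 2
        dc = (cc - c0)[None, :] ** 2
        img[np.ix_(rr, cc)] += noise.blob_intensity * np.exp(-(dr + dc) / (2 * sig ** 2))

    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Non-confluent disk cells


def _lens_area(d, r1, r2):
    """Intersection area of two disks with radii r1, r2 at center distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return np.pi * min(r1, r2) ** 2
    a1 = r1 * r1 * np.arccos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = r2 * r2 * np.arccos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    tri = 0.5 * np.sqrt(max(0.0, (-d + r1 + r2) * (d + r1 - r2)
                            * (d - r1 + r2) * (d + r1 + r2)))
    return a1 + a2 - tri


def generate_nonconfluent_sample(shape: Tuple[int, int], n_cells: int,
                                 radius_range: Tuple[float, float] = (6.0, 12.0),
                                 max_overlap_fraction: float = 0.0,
                                 rng_seed: int = 0,
                                 membrane_width: int = 2,
                                 max_proposals: Optional[int] = None) -> SynthSample:
    """Disk cells placed by rejection sampling with a bounded pairwise overlap.

    Any two disks may overlap by at most ``max_overlap_fraction`` of the
    smaller disk's area. ``binary`` holds the disk outlines (membranes);
    ``centers`` holds the disk centers. If the packing saturates before
    ``n_cells`` disks are placed the result is flagged ``saturated``.
    """
    if not (0 <= max_overlap_fraction < 1):
        raise ValueError("max_overlap_fraction must be in [0, 1)")
    h, w = shape
    rng = sample_rng(rng_seed, 0)
    if max_proposals is None:
        max_proposals = max(2000, 300 * max(1, n_cells))

    centers = []
    radii = []
    proposals = 0
    while len(centers) < n_cells and proposals < max_proposals:
        proposals += 1
        r = rng.uniform(*radius_range)
        p = np.array([rng.uniform(r + 1, h - r - 1), rng.uniform(r + 1, w - r - 1)])
        ok = True
        for q, rq in zip(centers, radii):
            d = float(np.linalg.norm(p - q))
            small = min(r, rq)
            if _lens_area(d, r, rq) > max_overlap_fraction * np.pi * small ** 2 + 1e-9:
                ok = False
                break
        if ok:
            centers.append(p)
            radii.append(r)

    binary = np.zeros(shape, dtype=bool)
    mask = np.zeros(shape, dtype=bool)
    for p, r in zip(centers, radii):
        rr, cc = draw_disk((p[0], p[1]), r, shape=shape)
        outer = np.zeros(shape, dtype=bool)
        outer[rr, cc] = True
        mask |= outer
        ring = outer & ~_erode(outer, max(1, membrane_width))
        binary |= ring

    pts = np.array(centers) if centers else np.empty((0, 2))
    seeds = SeedSet(points=pts, min_distance=0.0, density=float(n_cells) / (h * w),
                    saturated=len(centers) < n_cells)
    return SynthSample(
        binary=binary, centers=seeds, mask=TissueMask(mask),
        params={"radius_range": tuple(radius_range), "radii": radii,
                "max_overlap_fraction": max_overlap_fraction,
                "membrane_width": membrane_width},
        rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# Training-set recipe


def generate_training_sample(shape=(256, 256), n_islands=2, density=0.0045,
                             min_distance=10.0, membrane_width=3,
                             rng_seed=0, index=0) -> SynthSample:
    """One ground-truthed binary sample of the default honeycomb recipe.

    Defaults target roughly 80-150 cells per 256x256 patch (density x typical
    island area), with a 10 px hard-core distance matching keratinocyte
    packing at ~1 um/px.
    """
    seed_i = int(np.random.SeedSequence([int(rng_seed), int(index)]).generate_state(1)[0] % (2**31))
    mask = generate_tissue_mask(shape, n_islands, rng_seed=seed_i,
                                radius_frac=(0.30, 0.45))
    seeds = sample_hardcore_seeds(mask, density, min_distance, rng_seed=seed_i + 1,
                                  edge_margin=membrane_width)
    if len(seeds) == 0:  # degenerate tiny mask; fall back to a single seed
        coords = np.argwhere(mask.mask)
        pt = coords[len(coords) // 2][None, :].astype(float) if len(coords) else np.empty((0, 2))
        seeds = SeedSet(points=pt, min_distance=min_distance, density=density)
    sample = render_membranes(seeds, mask, membrane_width=membrane_width)
    sample.params.update({"n_islands": n_islands, "density": density,
                          "min_distance": min_distance, "index": index})
    sample.rng_seed = seed_i
    return sample
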