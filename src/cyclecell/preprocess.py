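"""Preprocessing: ROI extraction, local normalisation, membrane enhancement,
patching.

Raw full-frame images are turned into the model's input domains:

* domain A — ROI-masked, locally normalised raw images;
* domain C — membrane-enhanced images (a Gabor filter bank for tube-like
  epidermal membranes, or a Canny edge map for non-confluent cells).

The region of interest is found in two stages: a morphological geodesic
active contour separates tissue from the dark micro-relief grooves, then a
per-window texture veto built on four gray-level co-occurrence-matrix
features (homogeneity, contrast, dissimilarity, energy) removes
non-informative, noise-dominated areas. Full frames are split into
non-overlapping square patches for the networks and stitched back after
inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure
from skimage.feature import canny, graycomatrix, graycoprops
from skimage.filters import gabor_kernel, threshold_local, threshold_otsu
from skimage.segmentation import (inverse_gaussian_gradient,
                                  morphological_geodesic_active_contour)

PATCH_SIZE = 256


# ---------------------------------------------------------------------------
# Types


@dataclass
class RoiMask:
    mask: np.ndarray  # bool, True = informative tissue
    provenance: dict


@dataclass
class GaborBank:
    """Orientations/wavelengths of the membrane-enhancement bank.

    The response is the maximum real part over the bank; defaults cover eight
    orientations and two wavelengths bracketing the membrane width.
    """

    wavelengths: Tuple[float, ...] = (8.0, 16.0)
    orientations: Tuple[float, ...] = tuple(np.pi * k / 8 for k in range(8))

    def __post_init__(self):
        if not self.wavelengths or not self.orientations:
            raise ValueError("bank must have wavelengths and orientations")
        if any(w <= 2 for w in self.wavelengths):
            raise ValueError("wavelengths must exceed 2 px")


# ---------------------------------------------------------------------------
# ROI


def _glcm_features(patch: np.ndarray) -> np.ndarray:
    """(homogeneity, contrast, dissimilarity, energy) averaged over angles."""
    q = np.clip((patch * 31), 0, 31).astype(np.uint8)
    glcm = graycomatrix(q, distances=[1], angles=[0, np.pi / 4, np.pi / 2,
                                                  3 * np.pi / 4],
                        levels=32, symmetric=True, normed=True)
    return np.array([graycoprops(glcm, prop).mean()
                     for prop in ("homogeneity", "contrast", "dissimilarity",
                                  "energy")])


def extract_roi(image: np.ndarray, window: int = 31, classifier=None,
                n_iter: int = 40, veto_separation: float = 1.0) -> RoiMask:
    """Two-stage region-of-interest mask.

    Stage 1 separates tissue islands from the dark groove background with a
    morphological geodesic active contour initialised from an Otsu blob of
    the smoothed image (the result is eroded by 2 px to undo the smoothing
    bleed past the island edge). Stage 2 tiles the tissue into ``window`` x
    ``window`` blocks, computes the four GLCM texture features per block and
    vetoes blocks classified non-informative. With no classifier an
    unsupervised 2-cluster split is used and the cluster with the lower
    energy+homogeneity (noise-dominated texture) is vetoed; the veto only
    fires when the cluster centres are at least ``veto_separation`` apart in
    standardised feature units and the vetoed cluster is a strict minority
    (uniform-texture images are never vetoed).
    """
    if window < 9 or window % 2 == 0:
        raise ValueError("window must be odd and >= 9")
    img = np.asarray(image, dtype=np.float64)
    prov: dict = {"window": window}

    sm = ndi.gaussian_filter(img, 2.5)
    if sm.max() - sm.min() < 1e-6 or img.max() <= 1e-6:
        return RoiMask(mask=np.zeros(img.shape, dtype=bool),
                       provenance={**prov, "empty": True})

    thr = threshold_otsu(sm)
    init = ndi.binary_fill_holes(sm > thr)
    gimg = inverse_gaussian_gradient(sm, alpha=100.0, sigma=2.0)
    tissue = morphological_geodesic_active_contour(
        gimg, num_iter=n_iter, init_level_set=init.astype(np.int8),
        smoothing=1, balloon=0).astype(bool)
    tissue = ndi.binary_erosion(ndi.binary_fill_holes(tissue), iterations=2)
    prov["tissue_px"] = int(tissue.sum())
    if not tissue.any():
        return RoiMask(mask=tissue, provenance={**prov, "empty": True})

    # stage 2: texture veto on tiled windows
    h, w = img.shape
    boxes = []
    feats = []
    for r0 in range(0, h - window + 1, window):
        for c0 in range(0, w - window + 1, window):
            box = (slice(r0, r0 + window), slice(c0, c0 + window))
            if tissue[box].mean() < 0.9:  # only windows fully inside tissue
                continue
            boxes.append(box)
            feats.append(_glcm_features(img[box]))
    mask = tissue.copy()
    prov["n_windows"] = len(boxes)
    prov["n_vetoed"] = 0
    if len(boxes) >= 4:
        feats_arr = np.asarray(feats)
        mu = feats_arr.mean(axis=0)
        sd = feats_arr.std(axis=0)
        sd[sd == 0] = 1.0
        z = (feats_arr - mu) / sd
        if classifier is not None:
            keep = np.asarray(classifier.predict(feats_arr)).astype(bool)
        else:
            from sklearn.cluster import KMeans

            km = KMeans(n_clusters=2, n_init=5, random_state=0).fit(z)
            centers = km.cluster_centers_
            # energy + homogeneity (standardised) per cluster; the lower
            # (noise-dominated) cluster is the veto candidate
            score = centers[:, 3] + centers[:, 0]
            veto_label = int(np.argmin(score))
            n_veto = int((km.labels_ == veto_label).sum())
            separated = np.linalg.norm(centers[0] - centers[1]) >= veto_separation
            if separated and n_veto < len(boxes) / 2:
                keep = km.labels_ != veto_label
            else:
                keep = np.ones(len(boxes), dtype=bool)
        for box, k in zip(boxes, keep):
            if not k:
                mask[box] = False
                prov["n_vetoed"] += 1
    return RoiMask(mask=mask, provenance=prov)


# ---------------------------------------------------------------------------
# Normalisation and enhancement


def local_normalize(image: np.ndarray, window: int = 31,
                    eps: float = 1e-6) -> np.ndarray:
    """Per-pixel (x - local_mean) / (local_std + eps), rescaled to [0, 1].

    The rescaling is symmetric about 0.5 (division by the maximum absolute
    z-value), so the output is invariant to global affine intensity changes
    a*x + b with a > 0, and a constant image maps to all 0.5.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    img = np.asarray(image, dtype=np.float64)
    mean = ndi.uniform_filter(img, window)
    sq = ndi.uniform_filter(img * img, window)
    var = np.maximum(sq - mean * mean, 0.0)
    z = (img - mean) / (np.sqrt(var) + eps)
    m = np.abs(z).max()
    if m == 0:
        return np.full_like(img, 0.5)
    return 0.5 + z / (2 * m)


def _bank_kernels(bank: GaborBank):
    kernels = []
    for lam in bank.wavelengths:
        for theta in bank.orientations:
            # elongated envelope along the stripe direction favours
            # tube-like ridges over isotropic blobs
            k = gabor_kernel(frequency=1.0 / lam, theta=theta,
                             sigma_x=lam / 3.0, sigma_y=lam)
            kernels.append(np.real(k))
    return kernels


def enhance_membranes(image: np.ndarray, mode: str = "gabor",
                      bank: Optional[GaborBank] = None,
                      sigma: float = 2.0) -> np.ndarray:
    """Highlight membranes: max Gabor response over a bank, or a Canny edge map.

    ``gabor``: maximum real-part response over the bank, min-max rescaled to
    [0, 1] (a constant image maps to all zeros). ``canny``: edge map at
    ``sigma``, dilated by 1 px, as float.
    """
    img = np.asarray(image, dtype=np.float64)
    if mode == "gabor":
        bank = bank or GaborBank()
        resp = None
        for k in _bank_kernels(bank):
            r = ndi.convolve(img, k, mode="reflect")
            resp = r if resp is None else np.maximum(resp, r)
        lo, hi = resp.min(), resp.max()
        if hi - lo < 1e-12:
            return np.zeros_like(img)
        return (resp - lo) / (hi - lo)
    if mode == "canny":
        edges = canny(img, sigma=sigma)
        return ndi.binary_dilation(edges, iterations=1).astype(np.float64)
    raise ValueError(f"unknown mode {mode!r}")


def binarize_enhanced(image: np.ndarray, block: int = 31,
                      offset: float = 0.02) -> np.ndarray:
    """Histogram-equalize, then adaptive Gaussian threshold.

    A pixel is foreground when its equalized value exceeds the
    Gaussian-weighted local mean plus ``offset``; a constant image therefore
    maps to all background for offset > 0.
    """
    if block < 3 or block % 2 == 0:
        raise ValueError("block must be odd and >= 3")
    img = np.asarray(image, dtype=np.float64)
    if img.max() > img.min():
        eq = exposure.equalize_hist(img)
        # equalisation maps the lowest grey level to its cdf value, not 0;
        # stretch back to the full range so sparse bright structures keep
        # their margin over the local mean
        eq = (eq - eq.min()) / (eq.max() - eq.min())
    else:
        eq = img.copy()
    # skimage threshold_local computes local_mean - offset; negate to add
    thresh = threshold_local(eq, block_size=block, method="gaussian",
                             offset=-offset)
    return eq > thresh


# ---------------------------------------------------------------------------
# Patching


def _grid_offsets(size: int, patch: int) -> List[int]:
    k = size // patch
    if k <= 1:
        return [0]
    span = size - patch
    return [int(round(i * span / (k - 1))) for i in range(k)]


def extract_patches(image: np.ndarray, patch: int = PATCH_SIZE
                    ) -> List[Tuple[np.ndarray, Tuple[int, int]]]:
    """Split a frame into non-overlapping square patches with offsets.

    A 1000x1000 frame yields the nine 256x256 patches at offsets
    {0, 372, 744} per axis (borders and corners represented); smaller frames
    fall back to the largest centered non-overlapping grid. Raises if the
    image is smaller than one patch.
    """
    img = np.asarray(image)
    h, w = img.shape
    if h < patch or w < patch:
        raise ValueError(f"image {img.shape} smaller than patch size {patch}")
    out = []
    for r0 in _grid_offsets(h, patch):
        for c0 in _grid_offsets(w, patch):
            out.append((img[r0:r0 + patch, c0:c0 + patch].copy(), (r0, c0)))
    return out


def stitch_patches(patches: Sequence[Tuple[np.ndarray, Tuple[int, int]]],
                   full_shape: Tuple[int, int]
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Place patches at their offsets; overlaps averaged, gaps zero.

    Returns ``(image, coverage)`` where ``coverage`` flags pixels covered by
    at least one patch.
    """
    acc = np.zeros(full_shape, dtype=np.float64)
    cnt = np.zeros(full_shape, dtype=np.int32)
    for tile, (r0, c0) in patches:
        ph, pw = tile.shape
        if r0 < 0 or c0 < 0 or r0 + ph > full_shape[0] or c0 + pw > full_shape[1]:
            raise ValueError(f"patch at {(r0, c0)} exceeds frame {full_shape}")
        acc[r0:r0 + ph, c0:c0 + pw] += tile
        cnt[r0:r0 + ph, c0:c0 + pw] += 1
    covered = cnt > 0
    out = np.zeros(full_shape, dtype=np.float64)
    out[covered] = acc[covered] / cnt[covered]
    return out, covered


def tile_for_inference(image: np.ndarray, patch: int, stride: int
                       ) -> List[Tuple[np.ndarray, Tuple[int, int]]]:
    """Overlapping tiles covering the whole frame (full-image inference)."""
    img = np.asarray(image)
    h, w = img.shape
    if h < patch or w < patch:
        raise ValueError("image smaller than patch")
    rows = sorted(set(list(range(0, h - patch + 1, stride)) + [h - patch]))
    cols = sorted(set(list(range(0, w - patch + 1, stride)) + [w - patch]))
    return [(img[r:r + patch, c:c + patch].copy(), (r, c))
            for r in rows for c in cols]
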