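"""Independent brute-force / closed-form oracles used only by the tests.

These deliberately do NOT reuse the package's implementations: IoU here is
pixel-center membership evaluated directly, corner search is exhaustive
enumeration, and the ICC oracle computes variance components from the
classical ANOVA mean squares.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage


def pixel_iou(mask: np.ndarray, quad_pts: np.ndarray, spacing: float) -> float:
    """Pixel-center-in-polygon IoU, independent of the package evaluator."""
    rows, cols = np.nonzero(mask)
    r0, r1 = rows.min() - 2, rows.max() + 3
    c0, c1 = cols.min() - 2, cols.max() + 3
    yy, xx = np.mgrid[r0:r1, c0:c1]
    centers = np.column_stack([xx.ravel() * spacing, yy.ravel() * spacing])
    inside = MplPath(quad_pts).contains_points(centers)
    mask_flat = mask[r0:r1, c0:c1].ravel().astype(bool)
    inter = int((inside & mask_flat).sum())
    union = int(mask_flat.sum()) + int(inside.sum()) - inter
    return inter / union if union else 0.0


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    inner = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1))
    rows, cols = np.nonzero(mask & ~inner)
    return np.column_stack([cols, rows])  # (x, y) pixel indices


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Border polyline vertices (marching squares), (n, 2) as (x, y) px."""
    from skimage import measure

    padded = np.pad(mask.astype(float), 1)
    contour = max(measure.find_contours(padded, 0.5), key=len)
    rc = contour[:-1] - 1.0  # drop duplicate closing vertex, undo padding
    return np.column_stack([rc[:, 1], rc[:, 0]])


def exhaustive_corner_search(mask: np.ndarray, spacing: float,
                             chunk: int = 4096) -> tuple[np.ndarray, float]:
    """Best convex 4-subsets of border points under pixel-center IoU.

    Candidates are the vertices of the component's boundary polyline;
    subsets are taken in their cyclic order, so every candidate quad is
    simple; non-convex candidates are discarded (the optimum for the toy
    shapes used in the tests is convex).  Because the discrete objective
    can have exactly tied optima (e.g. mirror-symmetric staircase
    configurations), ALL co-optimal quads are returned.
    Returns (list of 4 x 2 mm point arrays, best IoU).
    """
    bp = boundary_points(mask)
    centroid = bp.mean(axis=0)
    ang = np.arctan2(bp[:, 1] - centroid[1], bp[:, 0] - centroid[0])
    bp = bp[np.argsort(ang)] * spacing
    n = len(bp)

    rows, cols = np.nonzero(mask)
    r0, r1 = rows.min() - 2, rows.max() + 3
    c0, c1 = cols.min() - 2, cols.max() + 3
    yy, xx = np.mgrid[r0:r1, c0:c1]
    centers = np.column_stack([xx.ravel() * spacing, yy.ravel() * spacing])
    mask_flat = mask[r0:r1, c0:c1].ravel().astype(bool)
    mask_count = int(mask_flat.sum())

    combos = np.array(list(combinations(range(n), 4)))
    best_iou, best_quads = -1.0, []
    all_quads, all_ious = [], []
    for start in range(0, len(combos), chunk):
        quads = bp[combos[start:start + chunk]]  # (B, 4, 2), cyclic order
        e = np.roll(quads, -1, axis=1) - quads
        # convexity + orientation: all consecutive edge crosses same sign
        cr = (e[:, :, 0] * np.roll(e, -1, axis=1)[:, :, 1]
              - e[:, :, 1] * np.roll(e, -1, axis=1)[:, :, 0])
        convex = (cr > 0).all(axis=1) | (cr < 0).all(axis=1)
        if not convex.any():
            continue
        quads = quads[convex]
        e = e[convex]
        sign = np.sign(cr[convex][:, 0])[:, None]
        # half-plane membership for each pixel center
        rel = centers[None, None, :, :] - quads[:, :, None, :]
        crosses = e[:, :, None, 0] * rel[..., 1] - e[:, :, None, 1] * rel[..., 0]
        inside = (sign[..., None] * crosses >= 0).all(axis=1)
        inter = (inside & mask_flat[None, :]).sum(axis=1)
        union = mask_count + inside.sum(axis=1) - inter
        ious = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
        i = int(np.argmax(ious))
        if ious[i] > best_iou:
            best_iou = float(ious[i])
        all_quads.append(quads)
        all_ious.append(ious)
    for quads, ious in zip(all_quads, all_ious):
        tied = ious >= best_iou - 1e-9
        best_quads.extend(quads[tied])
    return best_quads, best_iou


def icc2_variance_components(x: np.ndarray) -> float:
    """ICC(2,1) via variance components estimated from ANOVA mean squares."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = (((x - x.mean(axis=1, keepdims=True)
             - x.mean(axis=0, keepdims=True) + grand)) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    var_r = (msr - mse) / k
    var_c = (msc - mse) / n
    return var_r / (var_r + var_c + mse)


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial CI straight from the beta-quantile definition."""
    from scipy.stats import beta

    lo = 0.0 if x == 0 else float(beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def kcosine_corner_oracle(mask: np.ndarray, spacing: float,
                          window: int = 5) -> np.ndarray:
    """Brute-force k-cosine over all boundary pixels (cyclic by angle)."""
    bp = boundary_pixels(mask).astype(float)
    centroid = bp.mean(axis=0)
    ang = np.arctan2(bp[:, 1] - centroid[1], bp[:, 0] - centroid[0])
    bp = bp[np.argsort(ang)] * spacing
    n = len(bp)
    fwd = bp[(np.arange(n) + window) % n] - bp
    bwd = bp[(np.arange(n) - window) % n] - bp
    score = (fwd * bwd).sum(axis=1) / np.maximum(
        np.linalg.norm(fwd, axis=1) * np.linalg.norm(bwd, axis=1), 1e-12)
    chosen: list[int] = []
    min_sep = n / 8
    for i in np.argsort(score)[::-1]:
        if all(min(abs(i - j), n - abs(i - j)) >= min_sep for j in chosen):
            chosen.append(int(i))
        if len(chosen) == 4:
            break
    return bp[chosen]
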