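"""Mask post-processing and vertebral corner detection.

Cleans the binary segmentation (hole filling, small-cluster removal,
far-outlier removal against the line through the vertebral column), splits
it into individually labeled vertebra components, and locates each body's
four anatomical corners by three strategies:

1. ``basin-hopping`` — seeded global optimization of the four points'
   polygon-vs-mask IoU, initialized at the minimum-area bounding rectangle;
2. ``curvature``     — the four strongest k-cosine curvature maxima of the
   concave hull of the component border, with a minimum arc separation;
3. ``line-fit``      — robust straight lines fitted to the four border
   sides; corners are the boundary points nearest the adjacent-line
   intersections.

The quad whose spanned polygon maximizes IoU with the component wins.

Corner roles (anterosuperior, posterosuperior, posteroinferior,
anteroinferior) are assigned by quadrant around the centroid after
rotating into the component's principal-axis frame, using the canvas
orientation convention (anterior = left, cranial = top).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint, Polygon as ShapelyPolygon

from .core import GeometryError
from .segmentation import SegmentationMask

__all__ = [
    "CornerQuad",
    "VertebraComponent",
    "clean_mask",
    "split_and_label",
    "lumbar_components",
    "corners_basinhopping",
    "corners_curvature",
    "corners_linefit",
    "select_corners",
    "detect_corners",
    "quad_mask_iou",
]

STRATEGY_ORDER = ("basin-hopping", "curvature", "line-fit")

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass(frozen=True)
class CornerQuad:
    """Four corner landmarks in mm with fixed anatomical roles."""

    anterosuperior: tuple[float, float]
    posterosuperior: tuple[float, float]
    posteroinferior: tuple[float, float]
    anteroinferior: tuple[float, float]
    strategy: str = ""
    overlap: float | None = None

    def points(self) -> np.ndarray:
        """4 x 2 array in role order AS, PS, PI, AI (a closed ring)."""
        return np.array([self.anterosuperior, self.posterosuperior,
                         self.posteroinferior, self.anteroinferior],
                        dtype=float)

    @staticmethod
    def from_points(pts: np.ndarray, strategy: str = "",
                    overlap: float | None = None) -> "CornerQuad":
        pts = np.asarray(pts, dtype=float)
        return CornerQuad(
            anterosuperior=tuple(pts[0]), posterosuperior=tuple(pts[1]),
            posteroinferior=tuple(pts[2]), anteroinferior=tuple(pts[3]),
            strategy=strategy, overlap=overlap,
        )


@dataclass
class VertebraComponent:
    """One 4-connected vertebra sub-mask with derived geometry."""

    mask: np.ndarray
    spacing: float
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.sum() == 0:
            raise GeometryError("empty vertebra component")

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * self.spacing ** 2

    @property
    def centroid_mm(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.mask)
        return (float(cols.mean()) * self.spacing,
                float(rows.mean()) * self.spacing)

    @property
    def principal_angle_deg(self) -> float:
        """Rotation of the major axis w.r.t. the image x-axis, in (-45, 45]."""
        rows, cols = np.nonzero(self.mask)
        x = cols * self.spacing
        y = rows * self.spacing
        cxx = np.var(x)
        cyy = np.var(y)
        cxy = np.mean((x - x.mean()) * (y - y.mean()))
        theta = 0.5 * math.degrees(math.atan2(2 * cxy, cxx - cyy))
        while theta > 45.0:
            theta -= 90.0
        while theta <= -45.0:
            theta += 90.0
        return theta

    def boundary_pixels_mm(self) -> np.ndarray:
        """Centers of boundary pixels (mask minus its erosion), (n, 2) mm."""
        inner = ndimage.binary_erosion(self.mask, structure=_CROSS)
        rows, cols = np.nonzero(self.mask & ~inner)
        return np.column_stack([cols * self.spacing, rows * self.spacing])

    def contour_mm(self) -> np.ndarray:
        """Closed sub-pixel boundary polyline (n, 2) in mm, from marching squares."""
        from skimage import measure

        padded = np.pad(self.mask.astype(float), 1)
        contours = measure.find_contours(padded, 0.5)
        if not contours:
            raise GeometryError("component has no boundary contour")
        contour = max(contours, key=len)
        rc = contour - 1.0  # undo padding
        return np.column_stack([rc[:, 1], rc[:, 0]]) * self.spacing


# ---------------------------------------------------------------------------
# mask cleanup and splitting
# ---------------------------------------------------------------------------


def _perpendicular_distances(points: np.ndarray, anchor: np.ndarray,
                             direction: np.ndarray) -> np.ndarray:
    d = direction / np.linalg.norm(direction)
    rel = points - anchor
    return np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0])


def clean_mask(
    mask: SegmentationMask | np.ndarray,
    spacing: float | None = None,
    *,
    min_area_mm2: float = 50.0,
    max_dist_mm: float = 40.0,
) -> SegmentationMask:
    """Fill holes, drop small clusters and far-outlier clusters.

    Outliers are components whose centroid lies farther than ``max_dist_mm``
    from the total-least-squares line through the centroids of all
    sufficiently large components (the vertebral column axis).
    """
    if isinstance(mask, SegmentationMask):
        values = mask.values
        spacing = mask.spacing[0] if spacing is None else spacing
        provenance = mask.provenance
        sp = mask.spacing
    else:
        if spacing is None:
            raise ValueError("spacing required for a bare array mask")
        values = np.asarray(mask).astype(bool)
        provenance = "array"
        sp = (spacing, spacing)

    filled = ndimage.binary_fill_holes(values, structure=_CROSS)
    labeled, n = ndimage.label(filled, structure=_CROSS)
    if n == 0:
        return SegmentationMask(values=filled, provenance=provenance,
                                spacing=sp, meta={"cleaned": True})

    areas = ndimage.sum_labels(np.ones_like(labeled), labeled,
                               index=np.arange(1, n + 1))
    keep = areas * spacing ** 2 >= min_area_mm2
    big_ids = np.flatnonzero(keep) + 1

    if big_ids.size >= 2:
        centroids = np.array(ndimage.center_of_mass(filled, labeled, big_ids))
        pts = np.column_stack([centroids[:, 1], centroids[:, 0]]) * spacing
        anchor = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - anchor)
        dists = _perpendicular_distances(pts, anchor, vt[0])
        for comp_id, dist in zip(big_ids, dists):
            if dist > max_dist_mm:
                keep[comp_id - 1] = False

    lut = np.zeros(n + 1, dtype=bool)
    lut[1:] = keep
    out = lut[labeled]
    return SegmentationMask(values=out, provenance=provenance, spacing=sp,
                            meta={"cleaned": True,
                                  "min_area_mm2": min_area_mm2,
                                  "max_dist_mm": max_dist_mm})


def split_and_label(
    mask: SegmentationMask | np.ndarray,
    spacing: float | None = None,
    *,
    labels: list[str] | None = None,
    sacrum_present: bool = False,
) -> list[VertebraComponent]:
    """Split a cleaned mask into components ordered cranial -> caudal.

    Labels come from the caller; without an explicit list a declared sacrum
    anchors the most caudal component as S1 with L5..L1 (then T12, T11, ...)
    assigned upward.
    """
    if isinstance(mask, SegmentationMask):
        values = mask.values
        spacing = mask.spacing[0] if spacing is None else spacing
    else:
        if spacing is None:
            raise ValueError("spacing required for a bare array mask")
        values = np.asarray(mask).astype(bool)

    labeled, n = ndimage.label(values, structure=_CROSS)
    if n == 0:
        return []

    centroids = np.array(ndimage.center_of_mass(values, labeled,
                                                np.arange(1, n + 1)))
    # cranial -> caudal by centroid row; ties broken by anterior (column)
    order = np.lexsort((centroids[:, 1], centroids[:, 0]))

    if labels is not None:
        if len(labels) != n:
            raise GeometryError(
                f"label/component count mismatch: {len(labels)} labels "
                f"requested but {n} components found"
            )
        names = list(labels)
    elif sacrum_present:
        ladder = ["S1", "L5", "L4", "L3", "L2", "L1"] + \
            [f"T{i}" for i in range(12, 0, -1)]
        if n > len(ladder):
            raise GeometryError(f"too many components ({n}) to label")
        names = list(reversed(ladder[:n]))
    else:
        raise GeometryError(
            "no labels supplied and no sacrum declared; supply explicit labels"
        )

    comps = []
    for name, idx in zip(names, order):
        comps.append(VertebraComponent(mask=labeled == idx + 1,
                                       spacing=spacing, label=name))
    return comps


def lumbar_components(comps: list[VertebraComponent]) -> list[VertebraComponent]:
    """Only L1-L5 enter fracture assessment."""
    return [c for c in comps if c.label in {"L1", "L2", "L3", "L4", "L5"}]


# ---------------------------------------------------------------------------
# polygon-vs-mask IoU
# ---------------------------------------------------------------------------


def _mask_polygon(mask: np.ndarray, spacing: float):
    """Continuum outline of a pixelated component (marching squares, mm)."""
    from skimage import measure

    padded = np.pad(np.asarray(mask, dtype=float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise GeometryError("mask has no outline")
    rings = sorted(contours, key=len, reverse=True)
    exterior = rings[0] - 1.0
    poly = ShapelyPolygon(np.column_stack([exterior[:, 1],
                                           exterior[:, 0]]) * spacing)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


class _IoUEvaluator:
    """Continuum-area IoU between the mask outline and a candidate quad.

    Pixel-center sampling makes the objective piecewise constant, which
    stalls sub-pixel corner optimization and biases corners inward by up to
    a pixel; exact polygon areas avoid both problems.  Used only inside the
    free-floating optimization phase — reported overlap scores use the
    pixel-center evaluator below.
    """

    def __init__(self, mask: np.ndarray, spacing: float):
        self.poly = _mask_polygon(mask, spacing)
        self.area = self.poly.area

    def iou(self, pts: np.ndarray) -> float:
        quad = ShapelyPolygon(pts)
        if not quad.is_valid:
            quad = quad.buffer(0)
        if quad.is_empty:
            return 0.0
        inter = quad.intersection(self.poly).area
        union = self.area + quad.area - inter
        if union <= 0:
            return 0.0
        return inter / union


class _PixelIoUEvaluator:
    """|mask ∩ polygon| / |mask ∪ polygon| via pixel-center membership."""

    def __init__(self, mask: np.ndarray, spacing: float, margin_px: int = 8):
        from matplotlib.path import Path as MplPath

        self._path_cls = MplPath
        rows, cols = np.nonzero(mask)
        r0 = max(rows.min() - margin_px, 0)
        r1 = min(rows.max() + margin_px + 1, mask.shape[0])
        c0 = max(cols.min() - margin_px, 0)
        c1 = min(cols.max() + margin_px + 1, mask.shape[1])
        yy, xx = np.mgrid[r0:r1, c0:c1]
        self.centers = np.column_stack([xx.ravel() * spacing,
                                        yy.ravel() * spacing])
        self.mask_flat = mask[r0:r1, c0:c1].ravel().astype(bool)
        self.mask_count = int(self.mask_flat.sum())

    def iou(self, pts: np.ndarray) -> float:
        inside = self._path_cls(pts).contains_points(self.centers)
        inter = int((inside & self.mask_flat).sum())
        union = self.mask_count + int(inside.sum()) - inter
        if union == 0:
            return 0.0
        return inter / union


def quad_mask_iou(mask: np.ndarray, quad: CornerQuad, spacing: float) -> float:
    """IoU between a component mask and the polygon spanned by the quad."""
    return _PixelIoUEvaluator(np.asarray(mask).astype(bool),
                              spacing).iou(quad.points())


# ---------------------------------------------------------------------------
# corner roles
# ---------------------------------------------------------------------------


def _rotate(pts: np.ndarray, angle_deg: float, center: np.ndarray) -> np.ndarray:
    th = math.radians(angle_deg)
    rot = np.array([[math.cos(th), -math.sin(th)],
                    [math.sin(th), math.cos(th)]])
    return (pts - center) @ rot.T + center


def assign_roles(pts: np.ndarray, comp: VertebraComponent) -> np.ndarray:
    """Order 4 arbitrary points as AS, PS, PI, AI.

    Works in the principal-axis frame: anterior = smaller x, superior =
    smaller y.  Falls back to an angular sort when the quadrants are not
    uniquely occupied.
    """
    pts = np.asarray(pts, dtype=float)
    if pts.shape != (4, 2):
        raise GeometryError("role assignment needs exactly four points")
    center = np.asarray(comp.centroid_mm)
    local = _rotate(pts, -comp.principal_angle_deg, center) - center

    quadrant = {}
    for i, (x, y) in enumerate(local):
        q = (x < 0, y < 0)
        quadrant.setdefault(q, []).append(i)
    wanted = [(True, True), (False, True), (False, False), (True, False)]
    if all(len(quadrant.get(q, [])) == 1 for q in wanted):
        order = [quadrant[q][0] for q in wanted]
    else:
        # angular fallback: counter-clockwise from the upper-left diagonal
        ang = np.arctan2(local[:, 1], local[:, 0])
        start = np.argsort(np.abs(ang - (-3 * np.pi / 4)))[0]
        ccw = np.argsort(ang)
        pos = int(np.flatnonzero(ccw == start)[0])
        ring = np.roll(ccw, -pos)
        order = list(ring)
    ordered = pts[order]
    # enforce: superior landmarks cranial to inferior ones
    if ordered[[0, 1], 1].mean() > ordered[[2, 3], 1].mean():
        ordered = ordered[[3, 2, 1, 0]]
    return ordered


def _validate_component(comp: VertebraComponent) -> None:
    rows, cols = np.nonzero(comp.mask)
    if np.ptp(rows) < 3 or np.ptp(cols) < 3:
        raise GeometryError("degenerate component: width or height < 3 px")


# ---------------------------------------------------------------------------
# strategy 1: basin-hopping on the IoU objective
# ---------------------------------------------------------------------------


def _bounding_rect_corners(comp: VertebraComponent) -> np.ndarray:
    pts = MultiPoint(comp.boundary_pixels_mm()).minimum_rotated_rectangle
    xy = np.asarray(pts.exterior.coords)[:4]
    return assign_roles(xy, comp)


def _coordinate_descent(pts: np.ndarray, ev: _IoUEvaluator, spacing: float,
                        steps: tuple[float, ...]) -> tuple[np.ndarray, float]:
    best = pts.copy()
    score = ev.iou(best)
    for step in steps:
        improved = True
        while improved:
            improved = False
            for i in range(4):
                for j in range(2):
                    for sign in (1.0, -1.0):
                        cand = best.copy()
                        cand[i, j] += sign * step * spacing
                        s = ev.iou(cand)
                        if s > score + 1e-12:
                            best, score = cand, s
                            improved = True
    return best, score


def _refine_on_boundary(pts: np.ndarray, contour: np.ndarray,
                        pixel_ev: "_PixelIoUEvaluator",
                        area_ev: "_IoUEvaluator", spacing: float,
                        radius_px: float = 4.0, rounds: int = 5,
                        ) -> tuple[np.ndarray, float]:
    """Constrain each corner to the boundary and locally re-optimize.

    Candidate positions are the vertices of the boundary polyline; each
    corner in turn moves to the best candidate within ``radius_px`` of its
    current position (iterated conditional search, alternating sweep
    order).  The score is the pixel-overlap IoU with a small continuum-area
    tiebreak so that plateaus of the piecewise-constant pixel objective do
    not let corners drift inward.
    """
    candidates = contour
    if np.allclose(candidates[0], candidates[-1]):
        candidates = candidates[:-1]
    radius = radius_px * spacing

    def score_of(quad: np.ndarray) -> float:
        return pixel_ev.iou(quad) + 0.1 * area_ev.iou(quad)

    n = len(candidates)
    nearest = np.array([
        int(np.argmin(np.linalg.norm(candidates - p, axis=1))) for p in pts])

    def icm(start_idx: np.ndarray) -> tuple[np.ndarray, float]:
        best = candidates[start_idx]
        score = score_of(best)
        for rnd in range(rounds):
            moved = False
            order = range(4) if rnd % 2 == 0 else range(3, -1, -1)
            for i in order:
                near = candidates[
                    np.linalg.norm(candidates - best[i], axis=1) <= radius]
                for cand_pt in near:
                    cand = best.copy()
                    cand[i] = cand_pt
                    s = score_of(cand)
                    if s > score + 1e-12:
                        best, score = cand, s
                        moved = True
            if not moved:
                break
        return best, score

    # the nearest-vertex snap picks one of two near-symmetric rotations on
    # staircase corners; multi-start from the adjacent vertices escapes the
    # wrong basin
    best, score = None, -1.0
    for shift in (0, 1, -1):
        cand, s = icm((nearest + shift) % n)
        if s > score:
            best, score = cand, s
    return best, pixel_ev.iou(best)


def corners_basinhopping(
    comp: VertebraComponent,
    seed: int = 0,
    iterations: int = 50,
) -> CornerQuad:
    """Global IoU optimization from the minimum-area bounding rectangle."""
    _validate_component(comp)
    ev = _IoUEvaluator(comp.mask, comp.spacing)
    init = _bounding_rect_corners(comp)

    best, best_score = _coordinate_descent(init, ev, comp.spacing,
                                           steps=(2.0, 1.0, 0.5))
    rng = np.random.default_rng(seed)
    for _ in range(iterations):
        cand = best + rng.normal(0.0, 1.2 * comp.spacing, size=(4, 2))
        cand, score = _coordinate_descent(cand, ev, comp.spacing,
                                          steps=(1.0, 0.5))
        if score > best_score:
            best, best_score = cand, score
    best, best_score = _coordinate_descent(best, ev, comp.spacing,
                                           steps=(0.25, 0.1))
    # land the corners on the component border (anatomical landmarks) and
    # re-optimize along the boundary polyline under the pixel-overlap metric
    pixel_ev = _PixelIoUEvaluator(comp.mask, comp.spacing)
    best, best_score = _refine_on_boundary(best, comp.contour_mm(), pixel_ev,
                                           ev, comp.spacing)
    ordered = assign_roles(best, comp)
    return CornerQuad.from_points(ordered, strategy="basin-hopping",
                                  overlap=best_score)


# ---------------------------------------------------------------------------
# strategy 2: curvature maxima of the concave hull
# ---------------------------------------------------------------------------


def _concave_outline(contour_mm: np.ndarray, alpha: float) -> np.ndarray:
    """Concave hull of the raster border at scale ``alpha``.

    The marching-squares border is already a tight non-convex outline of
    the component; reducing it with a Douglas-Peucker pass at tolerance
    ``alpha / 2`` removes pixel-level staircase detail below the hull
    scale while preserving every concavity larger than ``alpha``.
    (A Delaunay alpha shape degenerates on the collinear runs of a pixel
    boundary, so the border-simplification route is used instead.)
    """
    ring = ShapelyPolygon(contour_mm)
    if not ring.is_valid:
        ring = ring.buffer(0)
    simplified = ring.simplify(alpha / 2.0, preserve_topology=True)
    if simplified.is_empty or simplified.geom_type != "Polygon":
        return contour_mm
    coords = np.asarray(simplified.exterior.coords)[:-1]
    if len(coords) < 4:
        return contour_mm
    return coords


def _resample_closed(poly: np.ndarray, step: float) -> np.ndarray:
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    n = max(int(round(total / step)), 8)
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    for d in range(2):
        out[:, d] = np.interp(targets, arclen, closed[:, d])
    return out


def corners_curvature(
    comp: VertebraComponent,
    hull_alpha: float | None = None,
    window: int = 7,
) -> CornerQuad:
    """Four strongest k-cosine curvature maxima on the concave hull."""
    _validate_component(comp)
    alpha = 3.0 * comp.spacing if hull_alpha is None else hull_alpha

    outline = _concave_outline(comp.contour_mm(), alpha)
    poly = _resample_closed(outline, step=comp.spacing)

    n = len(poly)
    if n < 4 * window:
        raise GeometryError(
            f"boundary too short ({n} points) for curvature window {window}"
        )
    fwd = poly[(np.arange(n) + window) % n] - poly
    bwd = poly[(np.arange(n) - window) % n] - poly
    dot = (fwd * bwd).sum(axis=1)
    norm = np.linalg.norm(fwd, axis=1) * np.linalg.norm(bwd, axis=1)
    score = dot / np.maximum(norm, 1e-12)  # k-cosine: sharp corner -> high

    # greedy maxima with minimum cyclic arc separation of perimeter / 8
    perimeter = float(np.linalg.norm(np.diff(
        np.vstack([poly, poly[:1]]), axis=0), axis=1).sum())
    min_sep = n / 8.0
    chosen: list[int] = []
    for i in np.argsort(score)[::-1]:
        if all(min(abs(i - j), n - abs(i - j)) >= min_sep for j in chosen):
            chosen.append(int(i))
        if len(chosen) == 4:
            break
    if len(chosen) < 4:
        raise GeometryError("fewer than four separated curvature maxima")

    ordered = assign_roles(poly[chosen], comp)
    return CornerQuad.from_points(ordered, strategy="curvature")


# ---------------------------------------------------------------------------
# strategy 3: side line fits
# ---------------------------------------------------------------------------


def _fit_line_tls(pts: np.ndarray, spacing: float,
                  trim_rounds: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line with residual trimming; (point, direction)."""
    sel = pts
    for _ in range(trim_rounds + 1):
        mean = sel.mean(axis=0)
        _, _, vt = np.linalg.svd(sel - mean)
        direction = vt[0]
        res = np.abs((sel - mean) @ np.array([direction[1], -direction[0]]))
        cut = max(spacing, 2.5 * res.std())
        keep = res <= cut
        if keep.sum() < 3 or keep.all():
            break
        sel = sel[keep]
    mean = sel.mean(axis=0)
    _, _, vt = np.linalg.svd(sel - mean)
    return mean, vt[0]


def _line_intersection(p1, d1, p2, d2) -> np.ndarray:
    a = np.column_stack([d1, -d2])
    if abs(np.linalg.det(a)) < 1e-12:
        raise GeometryError("side lines are parallel; no corner intersection")
    t = np.linalg.solve(a, p2 - p1)
    return p1 + t[0] * d1


def corners_linefit(comp: VertebraComponent) -> CornerQuad:
    """Corners next to the intersections of lines fitted to the four sides."""
    _validate_component(comp)
    boundary = comp.boundary_pixels_mm()
    center = np.asarray(comp.centroid_mm)
    local = _rotate(boundary, -comp.principal_angle_deg, center) - center

    ang = np.degrees(np.arctan2(local[:, 1], local[:, 0]))
    sectors = {
        "posterior": (ang > -45) & (ang <= 45),   # +x in rotated frame
        "inferior": (ang > 45) & (ang <= 135),    # +y (caudal)
        "anterior": (ang > 135) | (ang <= -135),  # -x
        "superior": (ang > -135) & (ang <= -45),  # -y (cranial)
    }
    lines = {}
    for name, sel in sectors.items():
        pts = boundary[sel]
        if len(pts) < 3:
            raise GeometryError(f"side {name!r} has fewer than 3 boundary pixels")
        lines[name] = _fit_line_tls(pts, comp.spacing)

    corners = []
    for side_a, side_b in (("superior", "anterior"),
                           ("superior", "posterior"),
                           ("inferior", "posterior"),
                           ("inferior", "anterior")):
        p = _line_intersection(*lines[side_a], *lines[side_b])
        # snap to the nearest boundary point ("next to the intersection")
        snap = boundary[np.argmin(np.linalg.norm(boundary - p, axis=1))]
        corners.append(snap)
    ordered = assign_roles(np.array(corners), comp)
    return CornerQuad.from_points(ordered, strategy="line-fit")


# ---------------------------------------------------------------------------
# selector
# ---------------------------------------------------------------------------


def select_corners(
    comp: VertebraComponent,
    quads: dict[str, CornerQuad | Exception],
) -> CornerQuad:
    """Pick the quad maximizing polygon-vs-mask IoU; ties by strategy order."""
    ev = _PixelIoUEvaluator(comp.mask, comp.spacing)
    best: CornerQuad | None = None
    best_score = -1.0
    failures = {}
    for strategy in STRATEGY_ORDER:
        quad = quads.get(strategy)
        if quad is None:
            continue
        if isinstance(quad, Exception):
            failures[strategy] = repr(quad)
            continue
        score = ev.iou(quad.points())
        scored = replace(quad, overlap=score, strategy=strategy)
        if score > best_score + 1e-12:
            best, best_score = scored, score
    if best is None:
        raise GeometryError(f"all corner strategies failed: {failures}")
    return best


def detect_corners(
    comp: VertebraComponent,
    seed: int = 0,
    iterations: int = 50,
) -> tuple[CornerQuad, dict[str, CornerQuad | Exception]]:
    """Run all three strategies and the overlap selector."""
    quads: dict[str, CornerQuad | Exception] = {}
    for name, fn in (
        ("basin-hopping", lambda: corners_basinhopping(comp, seed=seed,
                                                       iterations=iterations)),
        ("curvature", lambda: corners_curvature(comp)),
        ("line-fit", lambda: corners_linefit(comp)),
    ):
        try:
            quads[name] = fn()
        except GeometryError as exc:
            quads[name] = exc
    return select_corners(comp, quads), quads
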