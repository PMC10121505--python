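"""Synthetic mid-sagittal lumbar-spine phantom.

Renders a stack of quadrilateral vertebral bodies with circular-arc
endplate depressions on the standard 448 x 320 / 0.6 mm canvas, together
with a labeled ground-truth mask and analytically derived per-vertebra
truth (corners, heights, concavities, angle, deformity status).  Truth is
computed from the generating shapes, never measured from the raster.

Deformity model (single parameter ``severity`` in [0, 1]):

* ``wedge``   — anterior height scaled to ``1 - severity * max_anterior_loss``
  with the loss taken from the superior-anterior corner (the superior
  endplate tilts, the inferior stays put);
* ``concave`` — both endplate depression depths deepened linearly from the
  healthy baseline to ``max_concavity_mm``;
* ``crush``   — anterior AND posterior heights scaled equally by
  ``1 - severity * max_anterior_loss``, symmetric about the body center;
* ``none``    — identity.

Severity 0 is geometrically identical to ``none`` for every kind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import Polygon, Point, LineString

from .core import (
    CANVAS_SHAPE,
    DEFAULT_ORIENTATION,
    STANDARD_SPACING_MM,
    GeometryError,
    StandardSlice,
)
from .morphometry import DEFAULT_NORMS, Morphometry, ReferenceNorms, classify

__all__ = [
    "Deformity",
    "PhantomConfig",
    "VertebraShape",
    "VertebraTruth",
    "PhantomTruth",
    "apply_deformity",
    "generate_phantom",
]

DEFORMITY_KINDS = ("none", "wedge", "concave", "crush")


@dataclass(frozen=True)
class Deformity:
    kind: str = "none"
    severity: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in DEFORMITY_KINDS:
            raise ValueError(
                f"unknown deformity kind {self.kind!r}; expected one of "
                f"{DEFORMITY_KINDS}"
            )
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("deformity severity must lie in [0, 1]")


def _default_labels(n: int) -> tuple[str, ...]:
    if n == 7:
        return ("T12", "L1", "L2", "L3", "L4", "L5", "S1")
    if n == 6:
        return ("L1", "L2", "L3", "L4", "L5", "S1")
    if n == 5:
        return ("L1", "L2", "L3", "L4", "L5")
    return tuple(f"V{i + 1}" for i in range(n))


@dataclass(frozen=True)
class PhantomConfig:
    n_vertebrae: int = 7
    vertebra_height_mm: float = 27.0
    vertebra_width_mm: float = 33.0
    disc_gap_mm: float = 9.0
    endplate_concavity_mm: float = 1.0
    deformities: tuple[Deformity, ...] | None = None
    pixel_spacing_mm: float = STANDARD_SPACING_MM
    noise_sd: float = 0.0
    tilts_deg: tuple[float, ...] | None = None
    seed: int = 0
    # deformity parameterization: severity 1 must clearly exceed any
    # plausible 3-SD threshold
    max_anterior_loss: float = 0.6
    max_concavity_mm: float = 6.0
    concavity_width_fraction: float = 0.4
    bone_intensity: float = 0.75
    background_intensity: float = 0.15
    canvas_shape: tuple[int, int] = CANVAS_SHAPE
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_vertebrae < 1:
            raise ValueError("need at least one vertebra")
        for name in ("vertebra_height_mm", "vertebra_width_mm", "disc_gap_mm",
                     "pixel_spacing_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.endplate_concavity_mm < 0 or self.noise_sd < 0:
            raise ValueError("concavity depth and noise SD must be >= 0")
        if self.deformities is not None and len(self.deformities) != self.n_vertebrae:
            raise ValueError("deformities must list one entry per vertebra")
        if self.tilts_deg is not None:
            if len(self.tilts_deg) != self.n_vertebrae:
                raise ValueError("tilts_deg must list one entry per vertebra")
            if any(abs(t) > 15 for t in self.tilts_deg):
                raise ValueError("per-vertebra tilt limited to [-15, 15] degrees")
        if self.labels is not None and len(self.labels) != self.n_vertebrae:
            raise ValueError("labels must list one entry per vertebra")

    def resolved_deformities(self) -> tuple[Deformity, ...]:
        if self.deformities is None:
            return tuple(Deformity() for _ in range(self.n_vertebrae))
        return tuple(self.deformities)

    def resolved_tilts(self) -> tuple[float, ...]:
        if self.tilts_deg is None:
            return tuple(0.0 for _ in range(self.n_vertebrae))
        return tuple(self.tilts_deg)

    def resolved_labels(self) -> tuple[str, ...]:
        if self.labels is not None:
            return tuple(self.labels)
        return _default_labels(self.n_vertebrae)


@dataclass(frozen=True)
class VertebraShape:
    """Analytic generating shape: corner quad plus endplate-arc depths (mm).

    Corner order/roles: anterosuperior, posterosuperior, posteroinferior,
    anteroinferior; ``x`` runs anterior -> posterior, ``y`` cranial -> caudal.
    """

    anterosuperior: tuple[float, float]
    posterosuperior: tuple[float, float]
    posteroinferior: tuple[float, float]
    anteroinferior: tuple[float, float]
    depth_sup: float
    depth_inf: float
    #: fraction of the endplate width spanned by the depression arc,
    #: centered on the endplate (real depressions spare the corner regions)
    concavity_fraction: float = 0.4

    def corners(self) -> np.ndarray:
        return np.array([self.anterosuperior, self.posterosuperior,
                         self.posteroinferior, self.anteroinferior], dtype=float)

    def translated(self, dx: float, dy: float) -> "VertebraShape":
        c = self.corners() + np.array([dx, dy])
        return replace(
            self,
            anterosuperior=tuple(c[0]),
            posterosuperior=tuple(c[1]),
            posteroinferior=tuple(c[2]),
            anteroinferior=tuple(c[3]),
        )

    def rotated(self, angle_deg: float, center: tuple[float, float]) -> "VertebraShape":
        th = math.radians(angle_deg)
        rot = np.array([[math.cos(th), -math.sin(th)],
                        [math.sin(th), math.cos(th)]])
        c = (self.corners() - center) @ rot.T + center
        return replace(
            self,
            anterosuperior=tuple(c[0]),
            posterosuperior=tuple(c[1]),
            posteroinferior=tuple(c[2]),
            anteroinferior=tuple(c[3]),
        )

    # -- derived analytic quantities ------------------------------------
    def _carve_disk(self, a: np.ndarray, b: np.ndarray, depth: float,
                    inward: np.ndarray) -> Point | None:
        if depth <= 0:
            return None
        f = self.concavity_fraction
        mid0 = 0.5 * (a + b)
        a = mid0 + f * (a - mid0)
        b = mid0 + f * (b - mid0)
        c = float(np.linalg.norm(b - a))
        radius = (c * c / 4.0 + depth * depth) / (2.0 * depth)
        mid = 0.5 * (a + b)
        center = mid - (radius - depth) * inward
        return Point(center).buffer(radius, quad_segs=128)

    def polygon(self) -> Polygon:
        """Shapely polygon of the body with endplate depressions carved out."""
        corners = self.corners()
        a_s, p_s, p_i, a_i = corners
        body = Polygon(corners)
        centroid = corners.mean(axis=0)

        def inward(a: np.ndarray, b: np.ndarray) -> np.ndarray:
            d = b - a
            n = np.array([-d[1], d[0]])
            n = n / np.linalg.norm(n)
            if np.dot(n, centroid - 0.5 * (a + b)) < 0:
                n = -n
            return n

        sup = self._carve_disk(a_s, p_s, self.depth_sup, inward(a_s, p_s))
        inf = self._carve_disk(a_i, p_i, self.depth_inf, inward(a_i, p_i))
        geom = body
        for disk in (sup, inf):
            if disk is not None:
                geom = geom.difference(disk)
        if geom.is_empty or geom.geom_type != "Polygon":
            raise GeometryError("endplate depressions destroy the body polygon")
        return geom

    def true_morphometry(self) -> Morphometry:
        corners = self.corners()
        a_s, p_s, p_i, a_i = corners
        ah = float(np.linalg.norm(a_s - a_i))
        ph = float(np.linalg.norm(p_s - p_i))
        sup = p_s - a_s
        inf = p_i - a_i
        va = math.degrees(math.atan2(inf[1], inf[0]) - math.atan2(sup[1], sup[0]))
        if va > 180.0:
            va -= 360.0
        elif va < -180.0:
            va += 360.0

        # central height: boundary-to-boundary extent of the carved polygon
        # along the perpendicular of the mean chord direction through the
        # chord midpoints
        sup_n = sup / np.linalg.norm(sup)
        inf_n = inf / np.linalg.norm(inf)
        mean_dir = sup_n + inf_n
        mean_dir = mean_dir / np.linalg.norm(mean_dir)
        normal = np.array([-mean_dir[1], mean_dir[0]])
        center = 0.25 * (a_s + p_s + p_i + a_i)
        reach = 2.0 * max(ah, ph)
        probe = LineString([center - reach * normal, center + reach * normal])
        seg = self.polygon().intersection(probe)
        if seg.is_empty:
            raise GeometryError("central-height probe misses the body")
        if seg.geom_type == "MultiLineString":
            # take the piece containing the body center
            seg = min(seg.geoms, key=lambda g: g.distance(Point(center)))
        ch = float(seg.length)
        return Morphometry(ah=ah, ph=ph, ch=ch, sc=self.depth_sup,
                           ic=self.depth_inf, va=va)


def baseline_shape(height_mm: float, width_mm: float, concavity_mm: float,
                   concavity_fraction: float = 0.4) -> VertebraShape:
    """Healthy body centered at the origin."""
    h2, w2 = height_mm / 2.0, width_mm / 2.0
    return VertebraShape(
        anterosuperior=(-w2, -h2),
        posterosuperior=(w2, -h2),
        posteroinferior=(w2, h2),
        anteroinferior=(-w2, h2),
        depth_sup=concavity_mm,
        depth_inf=concavity_mm,
        concavity_fraction=concavity_fraction,
    )


def apply_deformity(
    shape: VertebraShape,
    kind: str,
    severity: float,
    *,
    max_anterior_loss: float = 0.6,
    max_concavity_mm: float = 6.0,
) -> VertebraShape:
    """Deform a baseline shape; severity 0 (or kind 'none') is the identity."""
    if kind not in DEFORMITY_KINDS:
        raise ValueError(f"unknown deformity kind {kind!r}")
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    if kind == "none":
        return shape

    a_s = np.asarray(shape.anterosuperior, dtype=float)
    p_s = np.asarray(shape.posterosuperior, dtype=float)
    p_i = np.asarray(shape.posteroinferior, dtype=float)
    a_i = np.asarray(shape.anteroinferior, dtype=float)

    if kind == "wedge":
        scale = 1.0 - severity * max_anterior_loss
        # loss taken from the superior-anterior corner; inferior edge fixed
        a_s = a_i + scale * (a_s - a_i)
        return replace(shape, anterosuperior=tuple(a_s))

    if kind == "crush":
        scale = 1.0 - severity * max_anterior_loss
        ca = 0.5 * (a_s + a_i)
        cp = 0.5 * (p_s + p_i)
        return replace(
            shape,
            anterosuperior=tuple(ca + scale * (a_s - ca)),
            anteroinferior=tuple(ca + scale * (a_i - ca)),
            posterosuperior=tuple(cp + scale * (p_s - cp)),
            posteroinferior=tuple(cp + scale * (p_i - cp)),
        )

    # concave: deepen both endplate depressions toward max_concavity_mm
    depth_sup = shape.depth_sup + severity * (max_concavity_mm - shape.depth_sup)
    depth_inf = shape.depth_inf + severity * (max_concavity_mm - shape.depth_inf)
    return replace(shape, depth_sup=depth_sup, depth_inf=depth_inf)


@dataclass
class VertebraTruth:
    label: str
    index: int  # 1-based value in the label raster
    corners_mm: dict[str, tuple[float, float]]
    morphometry: Morphometry
    deformity: str
    severity: float
    fractured: bool


@dataclass
class PhantomTruth:
    vertebrae: list[VertebraTruth]
    norms: ReferenceNorms

    def to_frame(self):
        import pandas as pd

        rows = []
        for v in self.vertebrae:
            row = {"label": v.label, **v.morphometry.as_dict(),
                   "deformity": v.deformity, "severity": v.severity,
                   "fractured": v.fractured}
            rows.append(row)
        return pd.DataFrame(rows)


def _build_shapes(config: PhantomConfig) -> list[VertebraShape]:
    spacing = config.pixel_spacing_mm
    canvas_h_mm = config.canvas_shape[0] * spacing
    canvas_w_mm = config.canvas_shape[1] * spacing
    n = config.n_vertebrae
    total_h = n * config.vertebra_height_mm + (n - 1) * config.disc_gap_mm
    if total_h > canvas_h_mm - 2 * config.pixel_spacing_mm:
        raise GeometryError(
            f"{n} vertebrae of {config.vertebra_height_mm} mm with "
            f"{config.disc_gap_mm} mm gaps do not fit a {canvas_h_mm:.1f} mm canvas"
        )
    y0 = (canvas_h_mm - total_h) / 2.0
    cx = canvas_w_mm / 2.0

    shapes = []
    deformities = config.resolved_deformities()
    tilts = config.resolved_tilts()
    for i in range(n):
        cy = y0 + i * (config.vertebra_height_mm + config.disc_gap_mm) \
            + config.vertebra_height_mm / 2.0
        shape = baseline_shape(config.vertebra_height_mm,
                               config.vertebra_width_mm,
                               config.endplate_concavity_mm,
                               config.concavity_width_fraction)
        shape = apply_deformity(
            shape, deformities[i].kind, deformities[i].severity,
            max_anterior_loss=config.max_anterior_loss,
            max_concavity_mm=config.max_concavity_mm,
        )
        shape = shape.translated(cx, cy)
        if tilts[i] != 0.0:
            shape = shape.rotated(tilts[i], (cx, cy))
        shapes.append(shape)

    polys = [s.polygon() for s in shapes]
    for a, b in zip(polys, polys[1:]):
        if a.intersection(b).area > 1e-9:
            raise GeometryError("vertebrae overlap after deformity/tilt")
    return shapes


def _rasterize(poly: Polygon, shape: tuple[int, int], spacing: float) -> np.ndarray:
    """Pixel-center-in-polygon rasterization (pixel center = index * spacing)."""
    out = np.zeros(shape, dtype=bool)
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(int(math.floor(minx / spacing)) - 1, 0)
    c1 = min(int(math.ceil(maxx / spacing)) + 2, shape[1])
    r0 = max(int(math.floor(miny / spacing)) - 1, 0)
    r1 = min(int(math.ceil(maxy / spacing)) + 2, shape[0])
    if c0 >= c1 or r0 >= r1:
        return out
    cols = np.arange(c0, c1) * spacing
    rows = np.arange(r0, r1) * spacing
    xx, yy = np.meshgrid(cols, rows)
    inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)
    out[r0:r1, c0:c1] = inside
    return out


def generate_phantom(
    config: PhantomConfig,
) -> tuple[StandardSlice, np.ndarray, PhantomTruth]:
    """Render a phantom and return (image, labeled mask, analytic truth).

    Identical (config, seed) yields bit-identical outputs.  Fracture truth
    is obtained by applying the deformity-rule classifier to the analytic
    morphometry with the shipped default norms, so it is consistent with
    the generating thresholds by construction.
    """
    shapes = _build_shapes(config)
    spacing = config.pixel_spacing_mm
    labels = np.zeros(config.canvas_shape, dtype=np.int16)
    for i, s in enumerate(shapes):
        labels[_rasterize(s.polygon(), config.canvas_shape, spacing)] = i + 1

    image = np.full(config.canvas_shape, config.background_intensity,
                    dtype=np.float32)
    image[labels > 0] = config.bone_intensity
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        image = image + rng.normal(0.0, config.noise_sd,
                                   size=image.shape).astype(np.float32)
    image = np.clip(image, 0.0, 1.0)

    names = config.resolved_labels()
    morphs = [s.true_morphometry() for s in shapes]
    vertebrae = []
    for i, (s, m) in enumerate(zip(shapes, morphs)):
        neighbors = [morphs[j] for j in (i - 1, i + 1) if 0 <= j < len(morphs)]
        call = classify(m, neighbors, DEFAULT_NORMS, label=names[i])
        d = config.resolved_deformities()[i]
        vertebrae.append(VertebraTruth(
            label=names[i],
            index=i + 1,
            corners_mm={
                "anterosuperior": s.anterosuperior,
                "posterosuperior": s.posterosuperior,
                "posteroinferior": s.posteroinferior,
                "anteroinferior": s.anteroinferior,
            },
            morphometry=m,
            deformity=d.kind,
            severity=d.severity,
            fractured=call.fractured,
        ))

    slc = StandardSlice(
        pixels=image,
        spacing=(spacing, spacing),
        orientation=DEFAULT_ORIENTATION,
        meta={"source": "phantom", "seed": config.seed},
    )
    return slc, labels, PhantomTruth(vertebrae=vertebrae, norms=DEFAULT_NORMS)
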