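"""Vertebral body morphometry and deformity classification.

From a vertebra mask and its four corner landmarks this module measures

* ``AH`` — anterior height: distance anterosuperior <-> anteroinferior corner,
* ``PH`` — posterior height: distance posterosuperior <-> posteroinferior,
* ``CH`` — central (mid-body) height, boundary to boundary at the chord
  midpoints,
* ``SC``/``IC`` — maximum depression depth of the superior / inferior
  endplate, measured perpendicular to the corner chord,
* ``VA`` — signed angle between the superior and inferior endplate chords,
  positive when the chords converge anteriorly,

and classifies each vertebra as intact or as a wedge / concave / crush
deformity by comparing height ratios against healthy-population reference
norms at the mean - 3 SD bound (strict inequality).

The shipped :data:`DEFAULT_NORMS` are synthetic placeholders in the spirit
of semiquantitative population tables.  They are NOT clinically derived;
any real use must supply externally validated norms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import GeometryError

__all__ = [
    "Morphometry",
    "NormEntry",
    "ReferenceNorms",
    "FractureCall",
    "DEFAULT_NORMS",
    "measure",
    "classify",
]


@dataclass(frozen=True)
class Morphometry:
    """Per-vertebra measurements, all heights in mm, angle in degrees."""

    ah: float
    ph: float
    ch: float
    sc: float
    ic: float
    va: float

    def __post_init__(self) -> None:
        if not (self.ah > 0 and self.ph > 0 and self.ch > 0):
            raise ValueError("AH, PH and CH must be strictly positive")
        if self.sc < 0 or self.ic < 0:
            raise ValueError("concavity depths must be non-negative")
        if not -90.0 < self.va < 90.0:
            raise ValueError("vertebral angle out of (-90, 90)")

    def as_dict(self) -> dict[str, float]:
        return {
            "AH": self.ah,
            "PH": self.ph,
            "CH": self.ch,
            "SC": self.sc,
            "IC": self.ic,
            "VA": self.va,
        }


@dataclass(frozen=True)
class NormEntry:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd <= 0:
            raise ValueError("norm mean and SD must be strictly positive")

    @property
    def lower_3sd(self) -> float:
        return self.mean - 3.0 * self.sd


@dataclass(frozen=True)
class ReferenceNorms:
    """Healthy-population means/SDs of the three deformity-rule ratios."""

    anterior_ratio: NormEntry
    middle_ratio: NormEntry
    neighbor_height_ratio: NormEntry

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceNorms":
        def entry(key: str) -> NormEntry:
            try:
                e = d[key]
            except KeyError as exc:
                raise ValueError(f"norms file is missing entry {key!r}") from exc
            return NormEntry(mean=float(e["mean"]), sd=float(e["sd"]))

        return cls(
            anterior_ratio=entry("anterior_ratio"),
            middle_ratio=entry("middle_ratio"),
            neighbor_height_ratio=entry("neighbor_height_ratio"),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ReferenceNorms":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def as_dict(self) -> dict:
        return {
            "anterior_ratio": asdict(self.anterior_ratio),
            "middle_ratio": asdict(self.middle_ratio),
            "neighbor_height_ratio": asdict(self.neighbor_height_ratio),
        }


#: Placeholder norms, clearly non-clinical (see module docstring).
DEFAULT_NORMS = ReferenceNorms(
    anterior_ratio=NormEntry(mean=0.96, sd=0.04),
    middle_ratio=NormEntry(mean=0.91, sd=0.045),
    neighbor_height_ratio=NormEntry(mean=1.00, sd=0.05),
)


@dataclass
class FractureCall:
    """Classification outcome for one vertebra with a full audit trail."""

    label: str
    fractured: bool
    deformity: str  # none | wedge | concave | crush
    audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fractured != (self.deformity != "none"):
            raise ValueError("fractured flag inconsistent with deformity kind")


# ---------------------------------------------------------------------------
# measurement helpers
# ---------------------------------------------------------------------------


def _mask_at(mask: np.ndarray, x: np.ndarray, y: np.ndarray, spacing: float) -> np.ndarray:
    """Nearest-pixel mask lookup at mm coordinates; outside-grid -> False."""
    r = np.rint(y / spacing).astype(int)
    c = np.rint(x / spacing).astype(int)
    ok = (r >= 0) & (r < mask.shape[0]) & (c >= 0) & (c < mask.shape[1])
    out = np.zeros(x.shape, dtype=bool)
    out[ok] = mask[r[ok], c[ok]]
    return out


def _concavity_depth(
    mask: np.ndarray,
    chord_a: np.ndarray,
    chord_b: np.ndarray,
    inward: np.ndarray,
    spacing: float,
    max_depth: float,
) -> float:
    """Maximum marching distance from the chord to the mask along ``inward``.

    The chord is sampled away from the corners; from each sample we step
    into the body along the inward normal until the first mask pixel.  The
    largest gap is the depression depth (0 when the mask reaches the chord).
    """
    ts = np.linspace(0.10, 0.90, 41)
    pts = chord_a[None, :] + ts[:, None] * (chord_b - chord_a)[None, :]
    step = 0.2 * spacing
    depths = np.arange(0.0, max_depth, step)
    # sample a (n_ts, n_depths) fan of points
    sample = pts[:, None, :] + depths[None, :, None] * inward[None, None, :]
    hit = _mask_at(mask, sample[..., 0], sample[..., 1], spacing)
    first = np.argmax(hit, axis=1).astype(float) * step
    first[~hit.any(axis=1)] = 0.0  # never hit: treat as no measurable depression
    return float(first.max())


def _central_height(
    mask: np.ndarray,
    mid_sup: np.ndarray,
    mid_inf: np.ndarray,
    mean_dir: np.ndarray,
    spacing: float,
    reach: float,
) -> float:
    """Boundary-to-boundary extent of the mask along the mid perpendicular."""
    normal = np.array([-mean_dir[1], mean_dir[0]])
    if np.dot(normal, mid_inf - mid_sup) < 0:
        normal = -normal
    center = 0.5 * (mid_sup + mid_inf)
    step = 0.1 * spacing
    ts = np.arange(-reach, reach, step)
    pts = center[None, :] + ts[:, None] * normal[None, :]
    inside = _mask_at(mask, pts[:, 0], pts[:, 1], spacing)
    if not inside.any():
        raise GeometryError("central-height probe line misses the mask")
    # contiguous run containing (or nearest to) the center point
    idx = np.flatnonzero(inside)
    center_i = np.argmin(np.abs(ts))
    nearest = idx[np.argmin(np.abs(idx - center_i))]
    lo = nearest
    while lo - 1 >= 0 and inside[lo - 1]:
        lo -= 1
    hi = nearest
    while hi + 1 < len(ts) and inside[hi + 1]:
        hi += 1
    return float((hi - lo + 1) * step)


def measure(mask: np.ndarray, quad, spacing: float) -> Morphometry:
    """Measure one vertebra from its binary mask and corner quad.

    Parameters
    ----------
    mask:
        Binary raster containing the single vertebra component.
    quad:
        A :class:`~spinemorph.geometry.CornerQuad` (or anything exposing
        ``anterosuperior``/``posterosuperior``/``posteroinferior``/
        ``anteroinferior`` as (x, y) mm pairs).
    spacing:
        Pixel spacing in mm.
    """
    mask = np.asarray(mask).astype(bool)
    a_s = np.asarray(quad.anterosuperior, dtype=float)
    p_s = np.asarray(quad.posterosuperior, dtype=float)
    p_i = np.asarray(quad.posteroinferior, dtype=float)
    a_i = np.asarray(quad.anteroinferior, dtype=float)

    sup = p_s - a_s
    inf = p_i - a_i
    if np.linalg.norm(sup) < 1e-9 or np.linalg.norm(inf) < 1e-9:
        raise GeometryError("endplate chord of zero length")

    ah = float(np.linalg.norm(a_s - a_i))
    ph = float(np.linalg.norm(p_s - p_i))

    # signed angle, positive when the chords converge anteriorly
    va = math.degrees(math.atan2(inf[1], inf[0]) - math.atan2(sup[1], sup[0]))
    if va > 180.0:
        va -= 360.0
    elif va < -180.0:
        va += 360.0

    sup_n = sup / np.linalg.norm(sup)
    inf_n = inf / np.linalg.norm(inf)
    mid_sup = 0.5 * (a_s + p_s)
    mid_inf = 0.5 * (a_i + p_i)
    body_axis = mid_inf - mid_sup  # points caudally (into the body from above)
    if np.linalg.norm(body_axis) < 1e-9:
        raise GeometryError("superior and inferior chords coincide")
    body_axis = body_axis / np.linalg.norm(body_axis)

    max_depth = 0.6 * max(ah, ph)
    sup_inward = np.array([-sup_n[1], sup_n[0]])
    if np.dot(sup_inward, body_axis) < 0:
        sup_inward = -sup_inward
    inf_inward = np.array([-inf_n[1], inf_n[0]])
    if np.dot(inf_inward, -body_axis) < 0:
        inf_inward = -inf_inward

    sc = _concavity_depth(mask, a_s, p_s, sup_inward, spacing, max_depth)
    ic = _concavity_depth(mask, a_i, p_i, inf_inward, spacing, max_depth)

    mean_dir = sup_n + inf_n
    mean_dir = mean_dir / np.linalg.norm(mean_dir)
    ch = _central_height(mask, mid_sup, mid_inf, mean_dir, spacing,
                         reach=max(ah, ph))

    return Morphometry(ah=ah, ph=ph, ch=ch, sc=sc, ic=ic, va=va)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

_OVERALL_HEIGHT_MODES = ("mean", "posterior")


def overall_height(m: Morphometry, mode: str = "mean") -> float:
    """Single-number vertebra height used by the crush (neighbor) rule."""
    if mode == "mean":
        return (m.ah + m.ch + m.ph) / 3.0
    if mode == "posterior":
        return m.ph
    raise ValueError(f"unknown overall-height mode {mode!r}; "
                     f"expected one of {_OVERALL_HEIGHT_MODES}")


def classify(
    m: Morphometry,
    neighbors: list[Morphometry],
    norms: ReferenceNorms,
    *,
    label: str = "",
    overall_height_mode: str = "mean",
) -> FractureCall:
    """Classify one vertebra as intact or wedge/concave/crush deformity.

    A rule fires when its ratio falls strictly below the healthy-population
    mean minus three standard deviations.  When several rules fire the
    reported deformity follows the precedence crush > wedge > concave.
    The crush rule needs at least one neighboring vertebra; with none it is
    skipped and recorded as such in the audit.
    """
    if norms is None:
        raise ValueError("reference norms are required (no silent defaults)")

    anterior_ratio = m.ah / m.ph
    middle_ratio = m.ch / m.ph
    wedge_thr = norms.anterior_ratio.lower_3sd
    concave_thr = norms.middle_ratio.lower_3sd
    crush_thr = norms.neighbor_height_ratio.lower_3sd

    wedge = anterior_ratio < wedge_thr
    concave = middle_ratio < concave_thr

    audit: dict = {
        "anterior_ratio": anterior_ratio,
        "anterior_threshold": wedge_thr,
        "middle_ratio": middle_ratio,
        "middle_threshold": concave_thr,
        "overall_height_mode": overall_height_mode,
    }

    crush = False
    if neighbors:
        own = overall_height(m, overall_height_mode)
        ref = float(np.mean([overall_height(n, overall_height_mode)
                             for n in neighbors]))
        neighbor_ratio = own / ref
        crush = neighbor_ratio < crush_thr
        audit.update(neighbor_ratio=neighbor_ratio, neighbor_threshold=crush_thr,
                     n_neighbors=len(neighbors))
    else:
        audit.update(neighbor_ratio=None, neighbor_threshold=crush_thr,
                     n_neighbors=0, crush_rule="skipped: no neighbors")

    if crush:
        deformity = "crush"
    elif wedge:
        deformity = "wedge"
    elif concave:
        deformity = "concave"
    else:
        deformity = "none"
    audit.update(wedge_fired=bool(wedge), concave_fired=bool(concave),
                 crush_fired=bool(crush))

    return FractureCall(label=label, fractured=deformity != "none",
                        deformity=deformity, audit=audit)
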