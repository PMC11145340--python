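"""Handcrafted nucleus morphometrics.

For each segmented nucleus two feature families are computed from its
binary mask and masked gray patch:

* nine geometric features derived from image moments and the convex hull
  — major/minor equivalent-ellipse axis lengths, area, orientation,
  eccentricity, ellipticity, equivalent diameter, perimeter, hull area;
* seven texture features from masked gray-level co-occurrence matrices
  (GLCM) — contrast, dissimilarity, homogeneity, entropy, angular second
  moment, roughness (perimeter / hull-perimeter), dispersion.

Conventions: coordinates are 0-based with x = column, y = row; the
orientation angle is the half-arctangent of the second central moments and
lies in (-pi/4, pi/4]; GLCMs are computed over the four standard offsets
(1,0), (1,1), (0,1), (-1,1), normalized per direction, and the six GLCM
statistics are averaged over directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "FEATURE_NAMES",
    "GLCM_DIRECTIONS",
    "NucleusRegion",
    "MomentSet",
    "GeometricFeatures",
    "TextureFeatures",
    "EmptyRegionError",
    "DegenerateGLCMError",
    "compute_moments",
    "geometric_features",
    "hull_area",
    "boundary_counts",
    "compute_glcm",
    "texture_features",
    "featurize_nucleus",
    "regions_from_mask",
    "feature_table",
]

#: Fixed column order of the 16-dimensional handcrafted feature vector.
FEATURE_NAMES = [
    "major", "minor", "area", "theta", "ecc", "ell", "dia", "per", "area_hull",
    "con", "diss", "hom", "ent", "asm", "rou", "dsip",
]

#: Pixel offsets (dx, dy) for the four GLCM directions 0/45/90/135 degrees.
GLCM_DIRECTIONS = ((1, 0), (1, 1), (0, 1), (-1, 1))


class EmptyRegionError(ValueError):
    """Raised for a nucleus mask without foreground pixels."""


class DegenerateGLCMError(ValueError):
    """Raised when a GLCM direction has no valid in-mask pixel pair."""


@dataclass
class NucleusRegion:
    """One segmented nucleus: binary mask plus quantized gray patch.

    ``gray_patch`` holds integers in [0, gray_levels) on the same grid as
    ``binary_mask``; ``centroid`` and ``offset`` are in tile coordinates
    (x, y).
    """

    binary_mask: np.ndarray
    gray_patch: np.ndarray
    gray_levels: int = 8
    centroid: tuple[float, float] = (0.0, 0.0)
    offset: tuple[int, int] = (0, 0)
    label: int = 0

    def __post_init__(self):
        self.binary_mask = np.asarray(self.binary_mask, dtype=bool)
        self.gray_patch = np.asarray(self.gray_patch)
        if self.binary_mask.shape != self.gray_patch.shape:
            raise ValueError("mask and gray patch shapes differ")
        if not self.binary_mask.any():
            raise EmptyRegionError("empty region")
        if self.gray_patch.max() >= self.gray_levels:
            raise ValueError("gray patch values must be < gray_levels")


@dataclass
class MomentSet:
    """Raw, central and area-normalized image moments up to order 2."""

    raw: dict
    central: dict
    mu20: float
    mu02: float
    mu11: float
    xbar: float
    ybar: float


@dataclass
class GeometricFeatures:
    major: float
    minor: float
    area: float
    theta: float
    ecc: float
    ell: float
    dia: float
    per: float
    area_hull: float
    nv: int = 0
    nh: int = 0
    nd1: int = 0
    nd2: int = 0
    hull_polygon: np.ndarray | None = None
    hull_perimeter: float = 0.0
    degenerate: bool = False


@dataclass
class TextureFeatures:
    con: float
    diss: float
    hom: float
    ent: float
    asm: float
    rou: float
    dsip: float
    per_direction: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# moments and geometry
# ---------------------------------------------------------------------------

def compute_moments(region_or_mask) -> MomentSet:
    """Image moments M_pq (p+q <= 2) of the binary mask.

    Returns raw moments, central moments, and the area-normalized second
    central moments used for the equivalent-ellipse axes.
    """
    mask = _mask_of(region_or_mask)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise EmptyRegionError("empty region")
    x = xs.astype(np.float64)
    y = ys.astype(np.float64)
    m00 = float(x.size)
    m10, m01 = float(x.sum()), float(y.sum())
    m11 = float((x * y).sum())
    m20, m02 = float((x * x).sum()), float((y * y).sum())
    xbar, ybar = m10 / m00, m01 / m00
    central = {
        (0, 0): m00,
        (1, 0): 0.0,
        (0, 1): 0.0,
        (1, 1): m11 - xbar * m01,
        (2, 0): m20 - xbar * m10,
        (0, 2): m02 - ybar * m01,
    }
    raw = {(0, 0): m00, (1, 0): m10, (0, 1): m01, (1, 1): m11, (2, 0): m20, (0, 2): m02}
    return MomentSet(
        raw=raw,
        central=central,
        mu20=m20 / m00 - xbar * xbar,
        mu02=m02 / m00 - ybar * ybar,
        mu11=m11 / m00 - xbar * ybar,
        xbar=xbar,
        ybar=ybar,
    )


def hull_area(mask: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Convex hull of the foreground pixel centers.

    Returns ``(area, perimeter, polygon)`` with the area by the shoelace
    formula on the hull polygon.  Collinear or singleton masks fall back to
    a zero-area degenerate polygon.
    """
    mask = _mask_of(mask)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise EmptyRegionError("empty region")
    pts = np.column_stack([xs, ys]).astype(np.float64)
    if len(pts) < 3:
        poly = pts
        return 0.0, float(np.linalg.norm(pts[-1] - pts[0]) * 2 if len(pts) == 2 else 0.0), poly
    try:
        hull = ConvexHull(pts)
    except QhullError:
        lo, hi = pts[np.argmin(pts[:, 0] + pts[:, 1])], pts[np.argmax(pts[:, 0] + pts[:, 1])]
        return 0.0, float(2.0 * np.linalg.norm(hi - lo)), np.array([lo, hi])
    poly = pts[hull.vertices]
    x, y = poly[:, 0], poly[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    perim = float(np.linalg.norm(np.diff(np.vstack([poly, poly[:1]]), axis=0), axis=1).sum())
    return float(area), perim, poly


def boundary_counts(mask: np.ndarray, diagonal_weight: float = 2.0):
    """Directional adjacency counts on the nuclear contour.

    The contour is the set of foreground pixels with at least one
    background (or out-of-image) 4-neighbor.  ``Nh``/``Nv``/``Nd1``/``Nd2``
    count unordered pairs of contour pixels adjacent along 0, 90, 45 and
    135 degrees; the perimeter is ``Nv + Nh + w (Nd1 + Nd2)`` with the
    diagonal weight ``w`` (2 by default, sqrt(2) optionally).
    """
    mask = _mask_of(mask)
    if not mask.any():
        raise EmptyRegionError("empty region")
    padded = np.pad(mask, 1)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    contour = mask & ~interior
    c = np.pad(contour, 1)
    nh = int(np.count_nonzero(c[1:-1, 1:-1] & c[1:-1, 2:]))        # (dx,dy)=(1,0)
    nv = int(np.count_nonzero(c[1:-1, 1:-1] & c[2:, 1:-1]))        # (0,1)
    nd1 = int(np.count_nonzero(c[1:-1, 1:-1] & c[:-2, 2:]))        # (1,-1), 45 deg
    nd2 = int(np.count_nonzero(c[1:-1, 1:-1] & c[2:, 2:]))         # (1,1), 135 deg
    per = nv + nh + diagonal_weight * (nd1 + nd2)
    return nv, nh, nd1, nd2, float(per), float(per)


def geometric_features(
    region_or_mask, diagonal_weight: float = 2.0
) -> GeometricFeatures:
    """The nine geometric features of one nucleus region.

    Axis lengths come from the area-normalized second central moments via
    the standard equivalent-ellipse formulas
    ``sqrt(8 (mu20 + mu02 +/- sqrt(4 mu11^2 + (mu20 - mu02)^2)))``;
    degenerate (collinear/singleton) masks clamp the minor axis to 1 px
    and fall back to ``area`` for the hull area.
    """
    mask = _mask_of(region_or_mask)
    mom = compute_moments(mask)
    area = mom.raw[(0, 0)]
    diff = mom.mu20 - mom.mu02
    root = np.sqrt(4.0 * mom.mu11 ** 2 + diff * diff)
    common = mom.mu20 + mom.mu02
    major = float(np.sqrt(max(8.0 * (common + root), 0.0)))
    minor = float(np.sqrt(max(8.0 * (common - root), 0.0)))
    degenerate = minor < 1.0
    if degenerate:
        minor = 1.0
        major = max(major, minor)
    if diff == 0.0:
        theta = 0.0 if mom.mu11 == 0.0 else float(np.sign(mom.mu11) * np.pi / 4.0)
    else:
        theta = float(0.5 * np.arctan(2.0 * mom.mu11 / diff))
    ell = minor / major
    ecc = float(np.sqrt(max(1.0 - ell * ell, 0.0)))
    dia = float(np.sqrt(4.0 * area / np.pi))
    nv, nh, nd1, nd2, per, _ = boundary_counts(mask, diagonal_weight)
    a_hull, p_hull, poly = hull_area(mask)
    hull_degenerate = a_hull <= 0.0
    if hull_degenerate:
        a_hull = area
    return GeometricFeatures(
        major=major, minor=minor, area=area, theta=theta, ecc=ecc, ell=float(ell),
        dia=dia, per=per, area_hull=float(a_hull),
        nv=nv, nh=nh, nd1=nd1, nd2=nd2,
        hull_polygon=poly, hull_perimeter=p_hull,
        degenerate=degenerate or hull_degenerate,
    )


# ---------------------------------------------------------------------------
# texture
# ---------------------------------------------------------------------------

def compute_glcm(region: NucleusRegion, direction: tuple[int, int]):
    """Masked gray-level co-occurrence counts for one (dx, dy) offset.

    Only pixel pairs with BOTH endpoints inside the nucleus mask
    contribute.  Returns ``(counts, normalized)``; raises
    :class:`DegenerateGLCMError` when no valid pair exists.
    """
    if tuple(direction) not in GLCM_DIRECTIONS:
        raise ValueError(f"direction must be one of {GLCM_DIRECTIONS}")
    dx, dy = direction
    levels = region.gray_levels
    mask = region.binary_mask
    gray = region.gray_patch.astype(np.intp)
    h, w = mask.shape
    # window of source pixels whose offset target stays inside the patch
    ys0, ys1 = max(0, -dy), h - max(0, dy)
    xs0, xs1 = max(0, -dx), w - max(0, dx)
    if ys0 >= ys1 or xs0 >= xs1:
        raise DegenerateGLCMError("degenerate GLCM")
    src_mask = mask[ys0:ys1, xs0:xs1]
    dst_mask = mask[ys0 + dy : ys1 + dy, xs0 + dx : xs1 + dx]
    valid = src_mask & dst_mask
    if not valid.any():
        raise DegenerateGLCMError("degenerate GLCM")
    i = gray[ys0:ys1, xs0:xs1][valid]
    j = gray[ys0 + dy : ys1 + dy, xs0 + dx : xs1 + dx][valid]
    counts = np.bincount(i * levels + j, minlength=levels * levels).reshape(levels, levels)
    counts = counts.astype(np.float64)
    return counts, counts / counts.sum()


def _glcm_stats(p: np.ndarray) -> dict:
    levels = p.shape[0]
    i, j = np.indices(p.shape)
    d = i - j
    nz = p > 0
    eps_mean = 1.0 / (levels * levels)
    return {
        "con": float((d * d * p).sum()),
        "diss": float((np.abs(d) * p).sum()),
        "hom": float((p / (1.0 + d * d)).sum()),
        "ent": float(-(p[nz] * np.log2(p[nz])).sum()),
        "asm": float((p * p).sum()),
        "dsip": float(((p - eps_mean) ** 2).sum()),
    }


def texture_features(
    region: NucleusRegion, geo: GeometricFeatures | None = None
) -> TextureFeatures:
    """The seven texture features, GLCM statistics averaged over the four
    directions; roughness is nucleus perimeter over hull perimeter."""
    if geo is None:
        geo = geometric_features(region.binary_mask)
    per_dir = {}
    for direction in GLCM_DIRECTIONS:
        _, p = compute_glcm(region, direction)
        per_dir[direction] = _glcm_stats(p)
    mean = {k: float(np.mean([s[k] for s in per_dir.values()])) for k in per_dir[GLCM_DIRECTIONS[0]]}
    ph, pn = geo.per, geo.hull_perimeter
    rou = ph / pn if pn > 0 and ph > 0 else 1.0
    return TextureFeatures(
        con=mean["con"], diss=mean["diss"], hom=mean["hom"], ent=mean["ent"],
        asm=mean["asm"], rou=float(rou), dsip=mean["dsip"], per_direction=per_dir,
    )


def featurize_nucleus(region: NucleusRegion, diagonal_weight: float = 2.0) -> np.ndarray:
    """The 16-dimensional handcrafted vector in :data:`FEATURE_NAMES` order."""
    geo = geometric_features(region.binary_mask, diagonal_weight)
    tex = texture_features(region, geo)
    vec = np.array([
        geo.major, geo.minor, geo.area, geo.theta, geo.ecc, geo.ell, geo.dia,
        geo.per, geo.area_hull,
        tex.con, tex.diss, tex.hom, tex.ent, tex.asm, tex.rou, tex.dsip,
    ])
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite feature value")
    return vec


# ---------------------------------------------------------------------------
# tile-level extraction
# ---------------------------------------------------------------------------

def quantize_gray(image: np.ndarray, levels: int = 8) -> np.ndarray:
    """Linearly quantize an 8-bit image to ``levels`` gray bins."""
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.mean(axis=2)
    return np.minimum((img.astype(np.float64) * levels / 256.0).astype(np.intp), levels - 1)


def regions_from_mask(
    gray_tile: np.ndarray, instance_mask: np.ndarray, gray_levels: int = 8
) -> list[NucleusRegion]:
    """Split an integer-labeled instance mask into per-nucleus regions."""
    instance_mask = np.asarray(instance_mask)
    q = quantize_gray(gray_tile, gray_levels)
    regions = []
    slices = ndimage.find_objects(instance_mask)
    for label, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        sub = instance_mask[sl] == label
        ys, xs = np.nonzero(sub)
        y0, x0 = sl[0].start, sl[1].start
        regions.append(
            NucleusRegion(
                binary_mask=sub,
                gray_patch=q[sl],
                gray_levels=gray_levels,
                centroid=(float(xs.mean() + x0), float(ys.mean() + y0)),
                offset=(int(x0), int(y0)),
                label=label,
            )
        )
    return regions


def feature_table(
    gray_tile: np.ndarray,
    instance_mask: np.ndarray,
    tile_id: str = "",
    gray_levels: int = 8,
    diagonal_weight: float = 2.0,
) -> pd.DataFrame:
    """Per-nucleus feature table for one tile.

    Nuclei too small to form a valid GLCM in every direction are skipped.
    Columns: tile_id, nucleus_id, centroid_x, centroid_y, then the 16
    features in :data:`FEATURE_NAMES` order.
    """
    rows = []
    for region in regions_from_mask(gray_tile, instance_mask, gray_levels):
        try:
            vec = featurize_nucleus(region, diagonal_weight)
        except (DegenerateGLCMError, EmptyRegionError):
            continue
        rows.append(
            {
                "tile_id": tile_id,
                "nucleus_id": region.label,
                "centroid_x": region.centroid[0],
                "centroid_y": region.centroid[1],
                **dict(zip(FEATURE_NAMES, vec)),
            }
        )
    cols = ["tile_id", "nucleus_id", "centroid_x", "centroid_y"] + FEATURE_NAMES
    return pd.DataFrame(rows, columns=cols)


def _mask_of(region_or_mask) -> np.ndarray:
    if isinstance(region_or_mask, NucleusRegion):
        return region_or_mask.binary_mask
    return np.asarray(region_or_mask, dtype=bool)
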