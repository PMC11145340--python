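"""Tissue extraction, 512-px tiling, and pluggable patch feature extraction.

Slide preparation leaves large blank glass areas, so tiles are cut only
where tissue is present: the slide (at a coarse pyramid level) is
converted RGB -> HSV, the saturation channel is Otsu-thresholded (glass
is near-white, hence unsaturated), small holes are closed with a
morphological closing, and small specks are removed by an area
threshold.  512 x 512 windows on the level-0 grid that intersect the
tissue mask form the tile index; window top-left coordinates are
recorded so tiles can be re-assembled exactly.  Edge windows overrunning
the slide are discarded.

Patch features come from a pluggable extractor interface.  The default
:class:`RandomProjectionExtractor` is a deterministic, seeded random
projection of the block-averaged tile — no pretrained weights needed —
declared width 1024; an ImageNet-pretrained CNN can be plugged in behind
the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color, filters, morphology

from .mil import PatchBag

__all__ = [
    "TissueMask",
    "TileIndex",
    "FeatureExtractor",
    "RandomProjectionExtractor",
    "tissue_mask",
    "tile",
    "crop_tiles",
    "extract_features",
]

TILE_SIZE = 512


@dataclass
class TissueMask:
    mask: np.ndarray       # bool, at pyramid level `level`
    level: int
    downsample: int        # scale factor to level 0 (2**level by default)
    area_threshold: int


@dataclass
class TileIndex:
    coords: np.ndarray     # n x 2 level-0 top-left (x, y), on the tile grid
    tile_size: int
    slide_dims: tuple[int, int]   # level-0 (width, height)

    def __len__(self):
        return len(self.coords)


def tissue_mask(
    slide_image: np.ndarray,
    level: int = 0,
    closing_radius: int = 2,
    min_area: int | None = None,
    tile_size: int = TILE_SIZE,
) -> TissueMask:
    """Otsu threshold on the HSV saturation channel plus closing.

    ``min_area`` removes connected components smaller than this many
    level-``level`` pixels; the default corresponds to 64 tiles' worth.
    An all-background image yields an empty mask rather than an error.
    """
    img = np.asarray(slide_image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("tissue_mask expects an RGB image")
    downsample = 2 ** level
    if min_area is None:
        min_area = 64 * (tile_size // downsample) ** 2
    sat = color.rgb2hsv(img[..., :3])[..., 1]
    if np.ptp(sat) < 1e-6:
        mask = np.zeros(sat.shape, dtype=bool)
    else:
        threshold = filters.threshold_otsu(sat)
        mask = sat > threshold
        mask = morphology.closing(mask, morphology.disk(closing_radius))
        labels, n = ndimage.label(mask)
        if n:
            areas = np.bincount(labels.ravel())[1:]
            keep = np.flatnonzero(areas >= max(min_area, 1)) + 1
            mask = np.isin(labels, keep)
    return TissueMask(mask=mask, level=level, downsample=downsample, area_threshold=min_area)


def tile(mask: TissueMask, slide_dims: tuple[int, int] | None = None, tile_size: int = TILE_SIZE) -> TileIndex:
    """Level-0 grid windows intersecting the tissue mask.

    ``slide_dims`` is the level-0 (width, height); by default inferred
    from the mask extent.  Windows that overrun the slide are discarded.
    """
    ds = mask.downsample
    h, w = mask.mask.shape
    if slide_dims is None:
        slide_dims = (w * ds, h * ds)
    width, height = slide_dims
    coords = []
    step = max(tile_size // ds, 1)
    for y0 in range(0, height - tile_size + 1, tile_size):
        for x0 in range(0, width - tile_size + 1, tile_size):
            ym, xm = y0 // ds, x0 // ds
            if mask.mask[ym : ym + step, xm : xm + step].any():
                coords.append((x0, y0))
    return TileIndex(
        coords=np.array(coords, dtype=np.intp).reshape(-1, 2),
        tile_size=tile_size,
        slide_dims=slide_dims,
    )


def crop_tiles(slide_image: np.ndarray, index: TileIndex) -> list[np.ndarray]:
    ts = index.tile_size
    return [np.asarray(slide_image[y : y + ts, x : x + ts]) for x, y in index.coords]


class FeatureExtractor:
    """Interface: callable tile -> feature vector of declared ``width``."""

    width: int = 1024
    deterministic: bool = True

    def __call__(self, tile_image: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class RandomProjectionExtractor(FeatureExtractor):
    """Seeded random projection of block and dark-object gray statistics.

    A stand-in for a pretrained CNN backbone whose pooled features are
    sensitive to both layout and nucleus-scale morphology.  Two groups
    of statistics are computed on the gray tile:

    * per-block (``grid x grid``): mean, standard deviation and
      dark-pixel fraction (gray < ``dark_threshold``) — spatial layout;
    * global dark-object statistics from connected components of the
      dark-pixel mask: component count, mean and spread of component
      areas, mean dark intensity, within-object pixel spread, and
      overall dark fraction — the morphology channel, replicated so it
      carries geometric weight comparable to the block group.

    The concatenated statistics are standardized with fixed constants
    and multiplied by a Gaussian matrix drawn once from the seed.
    Deterministic: the same tile always maps to the same vector, and
    distinct tiles collide with probability zero.
    """

    _MORPH_REP = 16  # replication factor of the 6 global morphology stats

    def __init__(self, width: int = 1024, grid: int = 12, seed: int = 7, dark_threshold: float = 160.0):
        self.width = width
        self.grid = grid
        self.seed = seed
        self.dark_threshold = dark_threshold
        rng = np.random.default_rng(seed)
        n_in = 3 * grid * grid + 6 * self._MORPH_REP
        self._proj = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, width))

    def _morphology_stats(self, img: np.ndarray) -> np.ndarray:
        dark = img < self.dark_threshold
        labels, n = ndimage.label(dark)
        if n == 0:
            return np.zeros(6)
        areas = np.bincount(labels.ravel())[1:].astype(np.float64)
        dark_pix = img[dark]
        within = float(np.std(dark_pix))
        return np.array(
            [
                n / 20.0,
                float(areas.mean()) / 400.0,
                float(areas.std()) / 400.0,
                float(dark_pix.mean()) / 128.0,
                within / 32.0,
                float(dark.mean()) * 20.0,
            ]
        )

    def __call__(self, tile_image: np.ndarray) -> np.ndarray:
        img = np.asarray(tile_image, dtype=np.float64)
        if img.ndim == 3:
            img = img.mean(axis=2)
        h, w = img.shape
        g = self.grid
        bh, bw = h // g, w // g
        if bh == 0 or bw == 0:
            raise ValueError(f"tile smaller than {g}x{g}")
        blocks = img[: bh * g, : bw * g].reshape(g, bh, g, bw)
        mean = blocks.mean(axis=(1, 3))
        std = blocks.std(axis=(1, 3))
        dark = (blocks < self.dark_threshold).mean(axis=(1, 3))
        flat = np.concatenate(
            [
                (mean.ravel() - 128.0) / 64.0,
                (std.ravel() - 16.0) / 16.0,
                (dark.ravel() - 0.5) * 2.0,
                np.tile(self._morphology_stats(img), self._MORPH_REP),
            ]
        )
        return flat @ self._proj


def extract_features(
    tiles: list[np.ndarray],
    index: TileIndex,
    extractor: FeatureExtractor,
    slide_id: str = "",
    label: int = -1,
) -> PatchBag:
    """Run the extractor over tiles, aligned with the tile index order."""
    if len(tiles) != len(index):
        raise ValueError("tiles/index length mismatch")
    if len(tiles) == 0:
        raise ValueError("empty tile list")
    feats = np.stack([np.asarray(extractor(t), dtype=np.float64) for t in tiles])
    if feats.shape[1] != extractor.width:
        raise ValueError(
            f"extractor returned width {feats.shape[1]}, declared {extractor.width}"
        )
    return PatchBag(slide_id=slide_id, features=feats, coordinates=index.coords.copy(), label=label)
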