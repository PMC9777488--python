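"""Slide-level gray value maps.

A whole-slide image is partitioned into 512x512 patches.  Each patch is
summarized by three numbers computed over its segmented membrane pixels:

* ``A`` — mean DAB absorbance ("gray value"),
* ``F`` — membrane pixel fraction (membrane pixels / all patch pixels),
* ``L`` — mean Lightness (CIE Luv L) of the membrane pixels.

L is carried alongside A because at very heavy staining the DAB channel
saturates (the blue channel of the sensor clips) while perceived darkness
keeps increasing; Lightness still tracks the visual gray level there.
Stacking the per-patch triples over the patch grid yields the 3-channel
GrayValueMap — a compressed slide representation small enough to feed a CNN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deconv import DEFAULT_OD, ODMatrix, deconvolve
from .segment import kmeans_luv, rgb_to_luv, select_membrane

__all__ = [
    "PATCH_SIZE",
    "PatchFeatures",
    "GrayValueMap",
    "tile_slide",
    "is_tissue",
    "patch_features",
    "build_graymap",
    "build_graymap_from_tiles",
    "slide_max_gray",
    "slide_percentile_gray",
    "patch_seed",
]

PATCH_SIZE = 512

#: Tissue heuristic: a patch is tissue when at least this fraction of pixels
#: is appreciably darker than glass (min(R,G,B) < 220).
TISSUE_MIN_FRACTION = 0.02
TISSUE_INTENSITY_THRESHOLD = 220


@dataclass
class PatchFeatures:
    A: float
    F: float
    L: float
    tissue: bool

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.A, self.F, self.L)


@dataclass
class GrayValueMap:
    """(Hp, Wp, 3) grid of per-patch (A, F, L) features."""

    grid: np.ndarray
    patch_size: int = PATCH_SIZE
    slide_id: str = ""
    tissue: np.ndarray = field(default=None)  # (Hp, Wp) bool

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3 or self.grid.shape[2] != 3:
            raise ValueError(f"grid must be (Hp, Wp, 3), got {self.grid.shape}")
        if self.tissue is None:
            # Patches with any nonzero feature count as tissue.
            self.tissue = np.any(self.grid != 0, axis=2)
        self.tissue = np.asarray(self.tissue, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape[:2]


def tile_slide(image: np.ndarray, patch: int = PATCH_SIZE):
    """Partition a slide into ``patch`` x ``patch`` tiles, row-major.

    Edge tiles are padded with white (255) to full size.  Yields
    ``(row, col, tile, padded)`` where ``padded`` flags padded tiles.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("slide must be a nonempty (H, W, 3) image")
    h, w, _ = img.shape
    n_rows = -(-h // patch)
    n_cols = -(-w // patch)
    for r in range(n_rows):
        for c in range(n_cols):
            block = img[r * patch : (r + 1) * patch, c * patch : (c + 1) * patch]
            padded = block.shape[:2] != (patch, patch)
            if padded:
                full = np.full((patch, patch, 3), 255, dtype=img.dtype)
                full[: block.shape[0], : block.shape[1]] = block
                block = full
            yield r, c, block, padded


def is_tissue(patch: np.ndarray) -> bool:
    """True when the patch contains enough non-glass pixels to segment."""
    dark = np.min(np.asarray(patch), axis=2) < TISSUE_INTENSITY_THRESHOLD
    return bool(dark.mean() >= TISSUE_MIN_FRACTION)


def patch_seed(seed: int, row: int, col: int) -> int:
    """Stable per-patch k-means seed derived from the slide seed and position."""
    return int(np.random.SeedSequence((int(seed), int(row), int(col))).generate_state(1)[0] % (2**31))


def patch_features(
    patch: np.ndarray,
    od: ODMatrix = DEFAULT_OD,
    seed: int = 0,
    *,
    kmeans_subsample: int | None = None,
) -> PatchFeatures:
    """Compute (A, F, L) for one patch.

    Non-tissue patches (glass/background) return ``(0, 0, 0)`` without
    running segmentation, so empty regions never contribute spurious signal.
    """
    if not is_tissue(patch):
        return PatchFeatures(0.0, 0.0, 0.0, tissue=False)
    amounts, _ = deconvolve(patch, od)
    dab = amounts[..., 1]
    luv = rgb_to_luv(patch)
    clusters = kmeans_luv(luv, seed=seed, subsample=kmeans_subsample)
    membrane = select_membrane(clusters, dab)
    mask = membrane.mask
    n = int(mask.sum())
    total = mask.size
    if n == 0:
        return PatchFeatures(0.0, 0.0, 0.0, tissue=True)
    return PatchFeatures(
        A=float(dab[mask].mean()),
        F=n / total,
        L=float(luv[..., 0][mask].mean()),
        tissue=True,
    )


def build_graymap(
    slide: np.ndarray,
    od: ODMatrix = DEFAULT_OD,
    seed: int = 0,
    *,
    patch: int = PATCH_SIZE,
    slide_id: str = "",
    kmeans_subsample: int | None = None,
) -> GrayValueMap:
    """Tile a slide and assemble the per-patch (A, F, L) grid."""
    h, w, _ = np.asarray(slide).shape
    n_rows, n_cols = -(-h // patch), -(-w // patch)
    grid = np.zeros((n_rows, n_cols, 3), dtype=np.float32)
    tissue = np.zeros((n_rows, n_cols), dtype=bool)
    for r, c, tile, _padded in tile_slide(slide, patch):
        pf = patch_features(
            tile, od, seed=patch_seed(seed, r, c), kmeans_subsample=kmeans_subsample
        )
        grid[r, c] = pf.as_tuple()
        tissue[r, c] = pf.tissue
    return GrayValueMap(grid=grid, patch_size=patch, slide_id=slide_id, tissue=tissue)


def build_graymap_from_tiles(
    tiles: dict,
    od: ODMatrix = DEFAULT_OD,
    seed: int = 0,
    *,
    patch: int = PATCH_SIZE,
    slide_id: str = "",
    kmeans_subsample: int | None = None,
) -> GrayValueMap:
    """Assemble a map from pre-tiled images keyed by (row, col).

    Positions missing from ``tiles`` are treated as background.  Tiles are
    processed independently, so a slide never has to exist as one image.
    """
    if not tiles:
        raise ValueError("no tiles given")
    n_rows = max(r for r, _ in tiles) + 1
    n_cols = max(c for _, c in tiles) + 1
    grid = np.zeros((n_rows, n_cols, 3), dtype=np.float32)
    tissue = np.zeros((n_rows, n_cols), dtype=bool)
    for (r, c), tile in tiles.items():
        pf = patch_features(
            tile, od, seed=patch_seed(seed, r, c), kmeans_subsample=kmeans_subsample
        )
        grid[r, c] = pf.as_tuple()
        tissue[r, c] = pf.tissue
    return GrayValueMap(grid=grid, patch_size=patch, slide_id=slide_id, tissue=tissue)


def slide_max_gray(gmap: GrayValueMap) -> float:
    """Maximum per-patch gray value A over tissue patches (GrayMax statistic).

    The clinical IHC cutoff keys on the strongest-staining fraction of the
    slide, which motivates summarizing a slide by its maximum patch gray
    value.  Returns 0 (with a warning) when the map has no tissue.
    """
    if gmap.grid.size == 0:
        raise ValueError("empty gray value map")
    if not gmap.tissue.any():
        import warnings

        warnings.warn("gray value map has no tissue patches; max gray = 0")
        return 0.0
    return float(gmap.grid[..., 0][gmap.tissue].max())


def slide_percentile_gray(gmap: GrayValueMap, q: float = 90.0) -> float:
    """Percentile variant of the slide statistic (robust alternative to max).

    ``q = 100`` reduces to :func:`slide_max_gray`.  Off by default in the
    baseline; useful when single hot patches should not dominate.
    """
    if gmap.grid.size == 0:
        raise ValueError("empty gray value map")
    if not gmap.tissue.any():
        return 0.0
    return float(np.percentile(gmap.grid[..., 0][gmap.tissue], q))
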