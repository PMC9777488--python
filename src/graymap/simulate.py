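"""Synthetic HER2 IHC data with ground truth at every stage.

Three generators, increasingly abstract:

* :func:`render_tile` / :func:`render_slide` — physically rendered tiles:
  hematoxylin-stained elliptical nuclei plus DAB membrane ring arcs, pushed
  through the Beer-Lambert forward model, with the true membrane mask and
  per-patch (A, F, L) recorded.  Staining intensity, ring completeness, and
  spatial heterogeneity depend on the IHC class.
* :func:`synth_cohort` — a fast path that draws slide-level GrayValueMaps
  directly from class-conditional (A, F, L) distributions, with FISH labels
  drawn at per-class positive rates patterned on a 228-case clinical cohort
  (0/1+: 2/26, 2+: 53/157, 3+: 45/45 positive).  A latent amplification
  level couples FISH status to staining intensity within each class, and a
  heterogeneity field plus occasional focal hot spots make the maximum patch
  value an imperfect classifier (as for real heterogeneous tumors).
* :func:`synth_fish_cases` — (HER2, CEP17) count pairs sampled from each
  ASCO/CAP region, including near-boundary points, with the intended group.

Defaults are the study conditions used by the tests and the reproduction
script; they are configuration, not claims about any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deconv import DEFAULT_OD, ODMatrix, forward_render
from .fish import FISHCase
from .maps import GrayValueMap
from .segment import rgb_to_luv

__all__ = [
    "SyntheticSpec",
    "CLASS_SPECS",
    "FISH_POSITIVE_RATES",
    "GroundTruth",
    "render_tile",
    "render_slide",
    "synth_cohort",
    "CohortSlide",
    "synth_fish_cases",
]

IHC_CLASSES = ("0/1+", "2+", "3+")

#: Per-class FISH-positive rates patterned on the clinical cohort table
#: (positives / total per IHC level).
FISH_POSITIVE_RATES = {"0/1+": 2 / 26, "2+": 53 / 157, "3+": 45 / 45}


@dataclass(frozen=True)
class SyntheticSpec:
    """Class-conditional rendering parameters for one slide/tile."""

    ihc_class: str
    membrane_amount_range: tuple[float, float]
    completeness: float  # fraction of each membrane ring actually stained
    cell_density: float = 120.0  # cells per 512x512 tile
    heterogeneity: float = 0.0  # sd of regional amount offsets (slide level)
    fish_status: int = 0
    nucleus_amount: float = 0.8

    def __post_init__(self):
        lo, hi = self.membrane_amount_range
        if lo < 0 or hi < lo:
            raise ValueError("membrane amount range must be ordered and non-negative")
        if not 0 <= self.completeness <= 1:
            raise ValueError("completeness must be in [0, 1]")


#: Default class-conditional specs: faint incomplete staining for 0/1+,
#: moderate for 2+, strong complete membranes for 3+.
CLASS_SPECS = {
    "0/1+": SyntheticSpec("0/1+", (0.1, 0.4), completeness=0.35),
    "2+": SyntheticSpec("2+", (0.5, 1.0), completeness=0.65),
    "3+": SyntheticSpec("3+", (1.2, 2.0), completeness=0.95),
}


@dataclass
class GroundTruth:
    """True membrane mask and per-patch features for a rendered tile/slide."""

    membrane_mask: np.ndarray  # (H, W) bool
    A: float
    F: float
    L: float
    membrane_amounts: np.ndarray = field(default=None, repr=False)


def _render_amount_fields(spec: SyntheticSpec, size: int, rng: np.random.Generator,
                          amount_offset: float = 0.0):
    """Lay out nuclei and membrane ring arcs as absorbance fields."""
    hema = np.zeros((size, size))
    dab = np.zeros((size, size))
    mask = np.zeros((size, size), dtype=bool)

    pitch = 38  # cell grid pitch at 512; scaled cell count via density
    n_grid = max(1, size // pitch)
    cells = [(r, c) for r in range(n_grid) for c in range(n_grid)]
    n_cells = min(len(cells), max(1, round(spec.cell_density * (size / 512.0) ** 2)))
    chosen = rng.permutation(len(cells))[:n_cells]

    lo, hi = spec.membrane_amount_range
    for idx in chosen:
        gr, gc = cells[idx]
        cy = (gr + 0.5) * pitch + rng.uniform(-4, 4)
        cx = (gc + 0.5) * pitch + rng.uniform(-4, 4)
        radius = rng.uniform(11, 15)
        y0, y1 = int(max(0, cy - radius - 3)), int(min(size, cy + radius + 4))
        x0, x1 = int(max(0, cx - radius - 3)), int(min(size, cx + radius + 4))
        if y1 <= y0 or x1 <= x0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        dist = np.hypot(dy, dx)
        # nucleus: filled inner ellipse-ish disc
        nucleus = dist <= 0.55 * radius
        hema[y0:y1, x0:x1][nucleus] = spec.nucleus_amount * rng.uniform(0.85, 1.15)
        if spec.completeness > 0:
            ring = np.abs(dist - radius) <= 1.6
            if spec.completeness < 1:
                theta = np.arctan2(dy, dx)
                start = rng.uniform(-np.pi, np.pi)
                span = 2 * np.pi * spec.completeness
                rel = np.mod(theta - start, 2 * np.pi)
                ring &= rel <= span
            amount = max(0.02, rng.uniform(lo, hi) + amount_offset)
            dab[y0:y1, x0:x1][ring] = amount
            mask[y0:y1, x0:x1] |= ring
    # mild per-pixel staining noise on stained pixels only
    stained = dab > 0
    dab[stained] = np.maximum(0.01, dab[stained] + rng.normal(0, 0.02, stained.sum()))
    nuc = hema > 0
    hema[nuc] = np.maximum(0.05, hema[nuc] + rng.normal(0, 0.03, nuc.sum()))
    return hema, dab, mask


def render_tile(
    spec: SyntheticSpec,
    seed: int,
    size: int = 512,
    od: ODMatrix = DEFAULT_OD,
    amount_offset: float = 0.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render one tile and its ground truth; deterministic given seed."""
    rng = np.random.default_rng(seed)
    hema, dab, mask = _render_amount_fields(spec, size, rng, amount_offset)
    amounts = np.stack([hema, dab, np.zeros_like(hema)], axis=-1)
    image = forward_render(amounts, od)
    if mask.any():
        luv = rgb_to_luv(image)
        gt = GroundTruth(
            membrane_mask=mask,
            A=float(dab[mask].mean()),
            F=float(mask.mean()),
            L=float(luv[..., 0][mask].mean()),
            membrane_amounts=dab,
        )
    else:
        gt = GroundTruth(membrane_mask=mask, A=0.0, F=0.0, L=0.0, membrane_amounts=dab)
    return image, gt


def render_slide(
    spec: SyntheticSpec,
    grid: tuple[int, int],
    seed: int,
    tile_size: int = 512,
    od: ODMatrix = DEFAULT_OD,
    blank_border: int = 0,
) -> tuple[np.ndarray, list]:
    """Render a grid of tiles with regional heterogeneity.

    Each tile gets a regional membrane-amount offset drawn from
    ``N(0, heterogeneity)``; ``blank_border`` adds that many rings of white
    tiles.  Returns the assembled image and per-tile
    ``(row, col, GroundTruth)`` records (blank tiles included with empty
    ground truth).
    """
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError("grid must be at least 1x1")
    rng = np.random.default_rng(seed)
    total_r, total_c = rows + 2 * blank_border, cols + 2 * blank_border
    slide = np.full((total_r * tile_size, total_c * tile_size, 3), 255, dtype=np.uint8)
    records = []
    for r in range(total_r):
        for c in range(total_c):
            inner = (
                blank_border <= r < blank_border + rows
                and blank_border <= c < blank_border + cols
            )
            if not inner:
                records.append((r, c, GroundTruth(np.zeros((tile_size, tile_size), bool), 0.0, 0.0, 0.0)))
                continue
            offset = float(rng.normal(0.0, spec.heterogeneity)) if spec.heterogeneity else 0.0
            tile, gt = render_tile(
                spec, seed=int(rng.integers(2**31)), size=tile_size, od=od, amount_offset=offset
            )
            slide[r * tile_size : (r + 1) * tile_size, c * tile_size : (c + 1) * tile_size] = tile
            records.append((r, c, gt))
    return slide, records


# ---------------------------------------------------------------------------
# Fast cohort path: draw GrayValueMaps directly.
# ---------------------------------------------------------------------------

@dataclass
class CohortSlide:
    slide_id: str
    gmap: GrayValueMap
    ihc_class: int  # 0 = 0/1+, 1 = 2+, 2 = 3+
    ihc_score: str  # 4-level clinical score string
    fish_label: int

    @property
    def ihc_name(self) -> str:
        return IHC_CLASSES[self.ihc_class]


_A_RANGES = {0: (0.10, 0.40), 1: (0.50, 1.00), 2: (1.20, 2.00)}
_F_RANGES = {0: (0.010, 0.050), 1: (0.050, 0.130), 2: (0.120, 0.220)}
#: probability that a slide carries a focal hot spot one class up
_HOTSPOT_PROB = {0: 0.20, 1: 0.35, 2: 0.0}


def _smooth_field(shape, rng, sd):
    """Coarse random multiplier field, bilinearly upsampled, mean ~= 1."""
    if sd == 0:
        return np.ones(shape)
    coarse = rng.normal(0.0, sd, size=(4, 4))
    from skimage.transform import resize

    return 1.0 + resize(coarse, shape, order=1, anti_aliasing=False)


def synth_cohort(
    n_per_class: int,
    fish_rates: dict | None = None,
    seed: int = 0,
    grid: tuple[int, int] = (16, 16),
    heterogeneity: float = 0.22,
) -> list[CohortSlide]:
    """Generate a slide cohort of GrayValueMaps with IHC and FISH labels.

    Per slide: an elliptical tissue blob on a ``grid`` patch lattice; a
    latent amplification level u in [0, 1] sets the slide's base A and F
    within the class range (FISH-positive slides draw u from the upper part
    of the range, FISH-negative from the lower, so gene status correlates
    with staining within class); a smooth regional field times the base plus
    optional focal hot spots give intra-slide heterogeneity; L decreases
    linearly with A.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rates = dict(FISH_POSITIVE_RATES if fish_rates is None else fish_rates)
    rng = np.random.default_rng(seed)
    slides: list[CohortSlide] = []
    hp, wp = grid
    for cls_idx, cls_name in enumerate(IHC_CLASSES):
        for i in range(n_per_class):
            fish = int(rng.random() < rates[cls_name])
            u = rng.uniform(0.40, 1.0) if fish else rng.uniform(0.0, 0.80)
            a_lo, a_hi = _A_RANGES[cls_idx]
            f_lo, f_hi = _F_RANGES[cls_idx]
            a_base = a_lo + u * (a_hi - a_lo)
            f_base = f_lo + u * (f_hi - f_lo)

            # elliptical tissue blob
            cy, cx = hp / 2 + rng.uniform(-1, 1), wp / 2 + rng.uniform(-1, 1)
            ry, rx = rng.uniform(0.28, 0.42) * hp, rng.uniform(0.28, 0.42) * wp
            yy, xx = np.mgrid[0:hp, 0:wp]
            tissue = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
            if not tissue.any():
                tissue[hp // 2, wp // 2] = True

            fld = _smooth_field((hp, wp), rng, heterogeneity)
            A = np.clip(a_base * fld, 0.02, None)
            F = np.clip(f_base * fld, 0.002, 0.30)
            if rng.random() < _HOTSPOT_PROB[cls_idx]:
                # focal region stained like the next class up
                hy, hx = rng.integers(0, hp), rng.integers(0, wp)
                spot = (np.abs(yy - hy) <= 1) & (np.abs(xx - hx) <= 1) & tissue
                nxt_lo, nxt_hi = _A_RANGES[min(cls_idx + 1, 2)]
                A[spot] = rng.uniform(nxt_lo, nxt_hi)
            L = np.clip(97.0 - 22.0 * A + rng.normal(0, 1.5, (hp, wp)), 20.0, 100.0)

            gridded = np.zeros((hp, wp, 3), dtype=np.float32)
            gridded[..., 0] = np.where(tissue, A, 0.0)
            gridded[..., 1] = np.where(tissue, F, 0.0)
            gridded[..., 2] = np.where(tissue, L, 0.0)

            if cls_idx == 0:
                score = "1+" if rng.random() < 0.8 else "0"
            else:
                score = cls_name
            slides.append(
                CohortSlide(
                    slide_id=f"synth-{cls_idx}-{i:03d}",
                    gmap=GrayValueMap(gridded, slide_id=f"synth-{cls_idx}-{i:03d}", tissue=tissue),
                    ihc_class=cls_idx,
                    ihc_score=score,
                    fish_label=fish,
                )
            )
    return slides


_GROUP_BOXES = {
    # group: (ratio_lo, ratio_hi, copies_lo, copies_hi)
    "G1": (2.0, 6.0, 4.0, 12.0),
    "G2": (2.0, 4.0, 1.0, 3.99),
    "G3": (0.5, 1.99, 6.0, 12.0),
    "G4": (0.5, 1.99, 4.0, 5.99),
    "G5": (0.2, 1.99, 0.5, 3.99),
}


def synth_fish_cases(n: int, seed: int = 0) -> list[tuple[FISHCase, str]]:
    """Sample (case, intended group) pairs covering all five ASCO/CAP regions.

    Groups cycle round-robin; every fifth case per group is snapped near a
    region boundary (just inside) to exercise the decision edges.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    groups = list(_GROUP_BOXES)
    out = []
    for i in range(n):
        g = groups[i % len(groups)]
        rlo, rhi, clo, chi = _GROUP_BOXES[g]
        ratio = rng.uniform(rlo, rhi)
        copies = rng.uniform(clo, chi)
        if i % 5 == 4:  # near-boundary sample, kept inside the region
            ratio = rlo if g in ("G1", "G2") else rhi
            copies = clo if g in ("G1", "G3", "G4") else chi
        cep17 = copies / ratio
        out.append((FISHCase(her2_copies=copies, cep17_copies=cep17), g))
    return out
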