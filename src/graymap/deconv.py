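"""Beer-Lambert staining model and Ruifrok color deconvolution.

A brightfield IHC slide is modelled as white light (``I0 = 255`` per channel)
attenuated by stains according to the Beer-Lambert law::

    I_c = I0_c * 10 ** (-(A @ OD)_c)

where ``A`` is the per-pixel vector of stain amounts (absorbances) and ``OD``
is the normalized optical-density matrix whose rows are the unit absorption
vectors of the stains.  For HER2 IHC there are two chemical stains —
hematoxylin (blue, nuclei) and DAB (brown, membrane-bound HER2 receptor) —
and the third row of ``OD`` completes the basis as the normalized cross
product of the first two.  Inverting the model recovers the stain amounts::

    A = -log10(I / 255) @ OD^-1

The second channel of ``A`` is the DAB absorbance used downstream as the
membrane "gray value".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidStainBasisError",
    "ODMatrix",
    "HEMATOXYLIN_OD",
    "DAB_OD",
    "DEFAULT_OD",
    "build_od_matrix",
    "deconvolve",
    "forward_render",
]

#: Published unit absorption vectors (R, G, B optical densities).
HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
DAB_OD = (0.268, 0.570, 0.776)

_I0 = 255.0


class InvalidStainBasisError(ValueError):
    """Raised when stain vectors cannot form an invertible OD basis."""


@dataclass(frozen=True)
class ODMatrix:
    """Normalized 3x3 optical-density matrix.

    Rows are unit stain absorption vectors: hematoxylin, DAB, and the
    residual channel (normalized cross product of the first two).
    """

    matrix: np.ndarray
    inverse: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise InvalidStainBasisError(f"OD matrix must be 3x3, got {m.shape}")
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise InvalidStainBasisError(f"OD rows must have unit norm, got {norms}")
        try:
            inv = np.linalg.inv(m)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - inv of unit rows
            raise InvalidStainBasisError("OD matrix is singular") from exc
        if not np.all(np.isfinite(inv)) or np.linalg.cond(m) > 1e8:
            raise InvalidStainBasisError("OD matrix is numerically singular")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "inverse", inv)

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.matrix[0]

    @property
    def dab(self) -> np.ndarray:
        return self.matrix[1]

    @property
    def residual(self) -> np.ndarray:
        return self.matrix[2]

    def to_json_dict(self) -> dict:
        return {"rows": self.matrix.tolist()}

    @classmethod
    def from_json_dict(cls, d: dict) -> "ODMatrix":
        return cls(np.asarray(d["rows"], dtype=float))


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise InvalidStainBasisError(f"{what} stain vector is zero")
    return v / n


def build_od_matrix(
    hema: tuple | np.ndarray = HEMATOXYLIN_OD,
    dab: tuple | np.ndarray = DAB_OD,
) -> ODMatrix:
    """Build the normalized OD matrix from two stain vectors.

    Rows 1-2 are the unit-normalized inputs; row 3 is the unit-normalized
    cross product of rows 1 and 2, so the basis spans RGB optical-density
    space even though only two chemical stains are present.

    Raises
    ------
    InvalidStainBasisError
        If either vector is zero or the two are collinear.
    """
    h = _unit(np.asarray(hema, dtype=float).reshape(3), "hematoxylin")
    d = _unit(np.asarray(dab, dtype=float).reshape(3), "DAB")
    cross = np.cross(h, d)
    n = np.linalg.norm(cross)
    if n < 1e-9:
        raise InvalidStainBasisError("stain vectors are collinear")
    return ODMatrix(np.stack([h, d, cross / n]))


#: Default basis built from the published hematoxylin/DAB vectors.
DEFAULT_OD = build_od_matrix()


def deconvolve(
    image: np.ndarray,
    od: ODMatrix = DEFAULT_OD,
    *,
    clip_negative: bool = True,
) -> tuple[np.ndarray, dict]:
    """Recover per-pixel stain amounts from an RGB image.

    Parameters
    ----------
    image : (H, W, 3) array
        8-bit RGB tile (transmitted intensities, white = 255).
    od : ODMatrix
        Stain basis; channel order of the output follows its rows
        (hematoxylin, DAB, residual).
    clip_negative : bool
        Clip out-of-gamut negative amounts to zero (amounts are physical
        absorbances).  The count of clipped entries is reported in metadata.

    Returns
    -------
    amounts : (H, W, 3) float64 array
        Stain absorbances; channel 1 is DAB.
    meta : dict
        ``n_clipped_intensity`` — pixels with intensity floored at 1 before
        the log; ``n_clipped_negative`` — negative amounts clipped to 0.
    """
    arr = np.asarray(image)
    img = arr.astype(float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got shape {img.shape}")
    # The log is undefined at I = 0.  For quantized detector images the
    # darkest representable non-zero level is 1, so intensities are floored
    # there; continuous (float) images are floored only at a tiny positive
    # value so the inversion stays exact.
    floor = 1.0 if np.issubdtype(arr.dtype, np.integer) else 1e-12
    n_floor = int(np.count_nonzero(img < floor))
    absorbance = -np.log10(np.clip(img, floor, None) / _I0)
    amounts = absorbance @ od.inverse
    n_neg = int(np.count_nonzero(amounts < 0))
    if clip_negative:
        np.clip(amounts, 0.0, None, out=amounts)
    return amounts, {"n_clipped_intensity": n_floor, "n_clipped_negative": n_neg}


def forward_render(
    amounts: np.ndarray,
    od: ODMatrix = DEFAULT_OD,
    *,
    integer: bool = True,
) -> np.ndarray:
    """Render stain amounts to a transmitted-light RGB image.

    ``I_c = 255 * 10**(-(amounts @ OD)_c)``, rounded half-even to 8-bit when
    ``integer`` is True (bit-stable fixtures); ``integer=False`` returns the
    un-quantized float image for exact round-trip work.
    """
    a = np.asarray(amounts, dtype=float)
    if a.shape[-1] != 3:
        raise ValueError("amounts must have 3 stain channels")
    if np.any(a < 0):
        raise ValueError("stain amounts must be non-negative")
    transmitted = _I0 * np.power(10.0, -(a @ od.matrix))
    if not integer:
        # un-quantized path: left unclipped so the inversion is exact even
        # for basis amounts whose mixed absorbance goes negative
        return transmitted
    return np.clip(np.rint(transmitted), 0, 255).astype(np.uint8)
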