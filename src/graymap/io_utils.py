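"""File formats and provenance: TSV manifests, float TIFF maps, PNG masks.

Formats are deliberately boring: tab-separated UTF-8 manifests with a header,
32-bit float multi-channel TIFF for gray value maps (with a TSV sidecar of
grid geometry and per-channel ranges), 8-bit PNG for masks and previews, and
JSON for configs/models/provenance.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .maps import GrayValueMap

__all__ = [
    "ManifestError",
    "read_manifest",
    "write_manifest",
    "save_graymap",
    "load_graymap",
    "save_stain_amounts",
    "load_od_config",
    "save_mask_png",
    "cluster_summary_tsv",
    "graymap_preview_png",
    "write_report",
    "write_provenance",
    "ihc_score_to_class",
]

IHC_SCORE_TOKENS = ("0", "1+", "2+", "3+")
FISH_TOKENS = ("negative", "positive", "NA")
MANIFEST_COLUMNS = ["slide_id", "path", "ihc_score", "fish_status", "fold_id"]


class ManifestError(ValueError):
    pass


def ihc_score_to_class(score: str) -> int:
    """Collapse the 4-level clinical score to the 3 evaluated levels."""
    return {"0": 0, "1+": 0, "2+": 1, "3+": 2}[score]


def read_manifest(path) -> pd.DataFrame:
    """Read and validate a slide manifest (strict TSV, header required)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest column(s) {missing}")
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        if row.ihc_score not in IHC_SCORE_TOKENS:
            raise ManifestError(
                f"{path}:{lineno}: unknown ihc_score {row.ihc_score!r}; "
                f"allowed: {IHC_SCORE_TOKENS}"
            )
        if row.fish_status not in FISH_TOKENS:
            raise ManifestError(
                f"{path}:{lineno}: unknown fish_status {row.fish_status!r}; "
                f"allowed: {FISH_TOKENS}"
            )
        try:
            int(row.fold_id)
        except ValueError:
            raise ManifestError(f"{path}:{lineno}: fold_id {row.fold_id!r} is not an integer")
    if df["slide_id"].duplicated().any():
        dup = df.loc[df["slide_id"].duplicated(), "slide_id"].iloc[0]
        raise ManifestError(f"{path}: duplicate slide_id {dup!r}")
    df["fold_id"] = df["fold_id"].astype(int)
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    pd.DataFrame(df)[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def save_graymap(gmap: GrayValueMap, path) -> None:
    """Write a map as float32 TIFF plus a ``.tsv`` sidecar next to it."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(gmap.grid, dtype=np.float32), photometric="rgb")
    hp, wp = gmap.shape
    sidecar = pd.DataFrame(
        {
            "slide_id": [gmap.slide_id],
            "Hp": [hp],
            "Wp": [wp],
            "patch_size": [gmap.patch_size],
            "A_min": [float(gmap.grid[..., 0].min())],
            "A_max": [float(gmap.grid[..., 0].max())],
            "F_min": [float(gmap.grid[..., 1].min())],
            "F_max": [float(gmap.grid[..., 1].max())],
            "L_min": [float(gmap.grid[..., 2].min())],
            "L_max": [float(gmap.grid[..., 2].max())],
        }
    )
    sidecar.to_csv(path.with_suffix(path.suffix + ".tsv"), sep="\t", index=False)


def load_graymap(path, slide_id: str = "", patch_size: int = 512) -> GrayValueMap:
    grid = tifffile.imread(Path(path))
    sidecar = Path(path).with_suffix(Path(path).suffix + ".tsv")
    if sidecar.exists():
        meta = pd.read_csv(sidecar, sep="\t")
        slide_id = slide_id or str(meta["slide_id"].iloc[0])
        patch_size = int(meta["patch_size"].iloc[0])
    return GrayValueMap(grid, patch_size=patch_size, slide_id=slide_id)


def save_stain_amounts(amounts: np.ndarray, path) -> None:
    """Write per-pixel stain absorbances as 3-channel 32-bit float TIFF."""
    arr = np.asarray(amounts, dtype=np.float32)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("stain amounts must be (H, W, 3)")
    tifffile.imwrite(Path(path), arr, photometric="rgb")


def load_od_config(path):
    """Load a stain basis from a 3x3 TSV (no header) or JSON {"rows": ...}."""
    from .deconv import build_od_matrix

    p = Path(path)
    if p.suffix == ".json":
        rows = np.asarray(json.loads(p.read_text())["rows"], dtype=float)
    else:
        rows = pd.read_csv(p, sep="\t", header=None).to_numpy(dtype=float)
    if rows.shape != (3, 3):
        raise ValueError(f"{path}: OD config must be 3 rows x 3 columns, got {rows.shape}")
    return build_od_matrix(rows[0], rows[1])


def cluster_summary_tsv(clusters, dab: np.ndarray, path) -> None:
    """Per-cluster summary (Luv center, pixel count, mean DAB) as TSV."""
    labels = clusters.labels.ravel()
    k = clusters.centers.shape[0]
    counts = np.bincount(labels, minlength=k)
    sums = np.bincount(labels, weights=np.asarray(dab, float).ravel(), minlength=k)
    with np.errstate(invalid="ignore"):
        mean_dab = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    pd.DataFrame(
        {
            "cluster": np.arange(k),
            "L": clusters.centers[:, 0],
            "u": clusters.centers[:, 1],
            "v": clusters.centers[:, 2],
            "n_pixels": counts,
            "mean_dab": mean_dab,
        }
    ).to_csv(Path(path), sep="\t", index=False)


def save_mask_png(mask: np.ndarray, path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def graymap_preview_png(gmap: GrayValueMap, path) -> None:
    """8-bit preview with per-channel min-max scaling."""
    g = np.asarray(gmap.grid, dtype=float)
    out = np.zeros_like(g)
    for c in range(3):
        lo, hi = g[..., c].min(), g[..., c].max()
        if hi > lo:
            out[..., c] = (g[..., c] - lo) / (hi - lo)
    iio.imwrite(Path(path), (out * 255).astype(np.uint8))


def write_report(report: dict, path) -> None:
    """Metric report as JSON plus a flat TSV twin."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    flat = pd.json_normalize(json.loads(path.read_text()), sep=".")
    flat.T.to_csv(path.with_suffix(".tsv"), sep="\t", header=False)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_provenance(path, config: dict, seed: int, stages: list[str]) -> None:
    """Machine-readable run record: config hash, seed, stage list, versions."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=_jsonable).encode()
    record = {
        "config_hash": hashlib.sha256(blob).hexdigest(),
        "config": config,
        "seed": seed,
        "stages": stages,
        "versions": {
            "graymap": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    with open(Path(path), "w") as fh:
        json.dump(record, fh, indent=2, default=_jsonable)
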