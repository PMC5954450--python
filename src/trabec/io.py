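"""File formats: TIFF stacks, Newick trees, trait CSVs, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import tifffile

from .volume import BinaryVolume, GrayVolume

__all__ = [
    "write_binary_tiff",
    "read_gray_tiff",
    "read_binary_tiff",
    "write_tree",
    "read_tree",
    "write_trait_table",
    "read_trait_table",
    "TRAIT_COLUMNS",
    "PUBLISHED_COLUMN_MAP",
]

TRAIT_COLUMNS = ["species", "lifestyle", "vl", "DA", "ConnD", "TbTh", "TbSp", "BVTV", "BSBV"]

#: column mapping for per-specimen tables that write the parameters with
#: their slashed print names
PUBLISHED_COLUMN_MAP = {
    "BV/TV": "BVTV",
    "BS/BV": "BSBV",
    "Tb.Th": "TbTh",
    "Tb.Sp": "TbSp",
    "Conn.D": "ConnD",
}


def write_binary_tiff(vol: BinaryVolume, path: str | Path, sidecar: dict | None = None) -> None:
    """Write a binary volume as an 8-bit 0/255 multi-page TIFF.

    The voxel size, provenance and any extra metadata go to a ``.json``
    sidecar next to the stack.
    """
    path = Path(path)
    tifffile.imwrite(path, (vol.data.astype(np.uint8) * 255), photometric="minisblack")
    meta = {"voxel_size_mm": vol.voxel_size, "provenance": _jsonable(vol.provenance)}
    if sidecar:
        meta.update(_jsonable(sidecar))
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _voxel_size_for(path: Path, voxel_size_mm: float | None) -> float:
    if voxel_size_mm is not None:
        return voxel_size_mm
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "voxel_size_mm" in meta:
            return float(meta["voxel_size_mm"])
    raise ValueError(
        f"voxel size for {path} not given and no sidecar found; it is never guessed"
    )


def read_gray_tiff(path: str | Path, voxel_size_mm: float | None = None) -> GrayVolume:
    path = Path(path)
    data = tifffile.imread(path)
    return GrayVolume(data=data, voxel_size=_voxel_size_for(path, voxel_size_mm))


def read_binary_tiff(path: str | Path, voxel_size_mm: float | None = None) -> BinaryVolume:
    path = Path(path)
    data = tifffile.imread(path)
    return BinaryVolume(
        data=data > 0,
        voxel_size=_voxel_size_for(path, voxel_size_mm),
        provenance={"source": str(path)},
    )


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_trait_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in TRAIT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)


def read_trait_table(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a trait CSV, optionally renaming columns to the core schema.

    ``column_map`` defaults to the published print-name mapping (``BV/TV``
    -> ``BVTV`` etc.); unknown columns pass through untouched.
    """
    df = pd.read_csv(path)
    df = df.rename(columns=PUBLISHED_COLUMN_MAP if column_map is None else column_map)
    if "species" not in df.columns:
        raise ValueError("trait table needs a 'species' column")
    return df
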