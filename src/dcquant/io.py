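"""File formats: multi-page TIFF stacks, truth sidecars, TSV/CSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .stacks import BinaryMask3D, VoxelStack


def write_stack(path: str | Path, stack: VoxelStack) -> None:
    """Write a stack as a multi-page float32 TIFF (one page per z-plane)."""
    tifffile.imwrite(str(path), stack.data.astype(np.float32))


def read_stack(
    path: str | Path,
    spacing: tuple[float, float, float] = (0.2, 0.1, 0.1),
    channel: str = "",
) -> VoxelStack:
    """Read a single- or multi-page TIFF as a stack (single pages become nz=1)."""
    data = tifffile.imread(str(path)).astype(float)
    if data.ndim == 2:
        data = data[None]
    return VoxelStack(data, spacing=spacing, channel=channel)


def write_mask(path: str | Path, mask: BinaryMask3D) -> None:
    """Write a binary mask as 8-bit TIFF (255 = inside)."""
    tifffile.imwrite(str(path), (mask.data.astype(np.uint8)) * 255)


def read_mask(path: str | Path, provenance: str = "") -> BinaryMask3D:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return BinaryMask3D(data > 0, provenance=provenance)


def write_sidecar(path: str | Path, fields: dict) -> None:
    """Flat key=value text sidecar for params and truth records."""
    with open(path, "w") as fh:
        for k, v in fields.items():
            fh.write(f"{k}={v}\n")


def read_sidecar(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or "=" not in line:
            continue
        k, _, v = line.partition("=")
        out[k] = v
    return out


def write_counts(path: str | Path, counts: pd.DataFrame, genes: pd.DataFrame) -> None:
    """Joined TSV: gene_id, chrom, start, then one column per sample."""
    merged = genes.merge(counts.reset_index(), on="gene_id")
    merged.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of :func:`write_counts`; returns (counts, gene table)."""
    df = pd.read_csv(path, sep="\t")
    meta_cols = [c for c in ("gene_id", "chrom", "start") if c in df.columns]
    genes = df[meta_cols].copy()
    counts = df.drop(columns=[c for c in meta_cols if c != "gene_id"]).set_index("gene_id")
    counts.index.name = "gene_id"
    return counts, genes


def read_dge(path: str | Path) -> pd.DataFrame:
    """Read a TSV differential-expression table."""
    return pd.read_csv(path, sep="\t")


def write_table(path: str | Path, frame: pd.DataFrame, sep: str = "\t", append: bool = False) -> None:
    """Write (or append rows to) a tidy results table."""
    path = Path(path)
    header = not (append and path.exists())
    frame.to_csv(path, sep=sep, index=False, mode="a" if append else "w", header=header)


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV (chrom, length in bp) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return {str(r.chrom): int(r.length) for r in df.itertuples()}
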