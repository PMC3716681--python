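"""Readers and writers for the plain-text formats the pipeline exchanges.

All coordinates are 0-based half-open internally; every writer states the
convention in a header comment. 1-based inclusive input is accepted only
behind an explicit ``one_based=True`` and converted on read. Malformed lines
raise :class:`FileFormatError` naming the file and line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FileFormatError
from .grid import BinGrid
from .simulate import DepthTrack

__all__ = [
    "COORD_HEADER",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_depth",
    "write_depth",
    "write_grid",
    "read_grid",
    "read_table",
    "write_table",
]

COORD_HEADER = "# coords: 0-based half-open"


def _open_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_chrom_sizes(path) -> list[tuple[str, int]]:
    out = []
    for lineno, line in _open_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise FileFormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            out.append((parts[0], int(parts[1])))
        except ValueError:
            raise FileFormatError(f"{path}:{lineno}: non-integer length {parts[1]!r}") from None
    return out


def write_chrom_sizes(chromosomes, path) -> None:
    with open(path, "w") as fh:
        for name, length in chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_bed(path, extra_cols: tuple[str, ...] = (), one_based: bool = False) -> pd.DataFrame:
    """Read BED3 plus any named extra columns.

    With ``one_based=True`` the input is treated as 1-based inclusive and
    converted to 0-based half-open (start -= 1).
    """
    cols = ["chrom", "start", "end", *extra_cols]
    rows = []
    for lineno, line in _open_lines(path):
        parts = line.split("\t")
        if len(parts) < len(cols):
            raise FileFormatError(
                f"{path}:{lineno}: expected >= {len(cols)} columns, got {len(parts)}"
            )
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise FileFormatError(f"{path}:{lineno}: non-integer coordinates") from None
        if one_based:
            start -= 1
        if start < 0 or end <= start:
            raise FileFormatError(
                f"{path}:{lineno}: invalid interval [{start}, {end})"
            )
        rows.append((parts[0], start, end, *parts[3 : len(cols)]))
    df = pd.DataFrame(rows, columns=cols)
    for c in extra_cols:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            pass  # non-numeric annotation column, keep as strings
    return df


def write_bed(df: pd.DataFrame, path, cols=None) -> None:
    cols = cols or list(df.columns)
    with open(path, "w") as fh:
        fh.write(COORD_HEADER + "\n")
        df[cols].to_csv(fh, sep="\t", header=False, index=False)


def write_depth(track: DepthTrack, grid: BinGrid, path) -> None:
    chrom_idx = grid.chrom_of_bins()
    names = np.array(grid.chrom_names)
    starts = grid.bin_starts()
    df = pd.DataFrame(
        {
            "chrom": names[chrom_idx],
            "start": starts,
            "end": starts + grid.bin_size,
            "depth": track.depth,
            "excluded": track.excluded.astype(int),
        }
    )
    with open(path, "w") as fh:
        fh.write(COORD_HEADER + f"\n# individual: {track.individual_id}\n# stage: {track.stage}\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_depth(path, grid: BinGrid, individual_id: str | None = None) -> DepthTrack:
    stage = "raw"
    ind = individual_id
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# individual:"):
                ind = line.split(":", 1)[1].strip()
            if line.startswith("# stage:"):
                stage = line.split(":", 1)[1].strip()
    df = read_bed(path, extra_cols=("depth", "excluded"))
    if len(df) != grid.n_bins:
        raise FileFormatError(
            f"{path}: {len(df)} bins but grid has {grid.n_bins}"
        )
    return DepthTrack(
        ind or Path(path).stem,
        df["depth"].to_numpy(dtype=float),
        df["excluded"].to_numpy(dtype=int).astype(bool),
        stage,
    )


def write_grid(grid: BinGrid, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_chrom_sizes(grid.chromosomes, out / "chrom.sizes")
    chrom_idx = grid.chrom_of_bins()
    names = np.array(grid.chrom_names)
    starts = grid.bin_starts()
    base = pd.DataFrame(
        {"chrom": names[chrom_idx], "start": starts, "end": starts + grid.bin_size}
    )
    for col, arr in (("gc", grid.gc), ("mask", grid.masked_frac)):
        df = base.copy()
        df["value"] = arr
        write_bed(df, out / f"{col}.bed")
    par = pd.DataFrame(
        [(grid.x_name, s, e) for s, e in grid.par_regions], columns=["chrom", "start", "end"]
    )
    write_bed(par, out / "par.bed") if len(par) else (out / "par.bed").write_text(COORD_HEADER + "\n")
    with open(out / "meta.tsv", "w") as fh:
        fh.write(f"bin_size\t{grid.bin_size}\n")
        fh.write("x_chrom\t" + (grid.x_name or ".") + "\n")


def read_grid(in_dir) -> BinGrid:
    d = Path(in_dir)
    chroms = read_chrom_sizes(d / "chrom.sizes")
    meta = dict(
        line.split("\t") for line in (d / "meta.tsv").read_text().strip().split("\n")
    )
    bin_size = int(meta["bin_size"])
    x_name = meta.get("x_chrom", ".")
    gc = read_bed(d / "gc.bed", extra_cols=("value",))["value"].to_numpy(dtype=float)
    mask = read_bed(d / "mask.bed", extra_cols=("value",))["value"].to_numpy(dtype=float)
    par_path = d / "par.bed"
    par_df = read_bed(par_path) if par_path.read_text().strip() != COORD_HEADER else pd.DataFrame(
        columns=["chrom", "start", "end"]
    )
    return BinGrid(
        chromosomes=tuple((n, l) for n, l in chroms),
        bin_size=bin_size,
        gc=gc,
        masked_frac=mask,
        is_x=tuple(n == x_name for n, _ in chroms),
        par_regions=tuple((int(s), int(e)) for s, e in par_df[["start", "end"]].itertuples(index=False)),
    )


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path, coord_header: bool = False) -> None:
    with open(path, "w") as fh:
        if coord_header:
            fh.write(COORD_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False)
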