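"""Readers and writers for genotype, occurrence, and raster files.

Supported formats:

* GenePop 4.x (``.gen``) — the de-facto exchange format for SSR data:
  a title line, one locus name per line (or comma-separated), ``POP``
  markers delimiting populations, and per individual
  ``id ,  aaabbb aaabbb ...`` rows with 2- or 3-digit allele encoding
  (auto-detected). ``000000``/``0000`` encodes a missing genotype.
* Wide CSV genotype tables with two allele columns per locus plus
  id/population/lon/lat columns, described by a :class:`CsvDialect`.
* CSV occurrence tables with lon/lat headers.
* Single-band georeferenced ESRI ASCII grids (see :mod:`landgen.raster`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import Raster, read_ascii_grid, write_ascii_grid
from .types import MISSING, GenotypeMatrix, OccurrenceSet


class ParseError(ValueError):
    """Malformed input file; message includes the offending line number."""


class ConfigError(ValueError):
    """A column mapping or option does not match the data."""


# ----------------------------------------------------------------------
# GenePop
# ----------------------------------------------------------------------

def _split_genepop_genotype(tok: str, digits: int, lineno: int) -> tuple[int, int]:
    if len(tok) != 2 * digits or not tok.isdigit():
        raise ParseError(f"line {lineno}: bad genotype token {tok!r}")
    a, b = int(tok[:digits]), int(tok[digits:])
    if (a == 0) != (b == 0):
        raise ParseError(f"line {lineno}: half-missing genotype {tok!r}")
    return a, b


def read_genepop(path: str | Path) -> GenotypeMatrix:
    """Parse a GenePop file into a :class:`GenotypeMatrix`.

    Populations are named ``pop1 .. popN`` in file order unless individual
    ids carry a site prefix, in which case the id of the last individual in
    each POP block names the population (GenePop convention).
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ParseError("line 1: file too short for GenePop format")
    # locus names: either one per line, or comma-separated on line 2
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        part = [t.strip() for t in lines[i].split(",") if t.strip()]
        locus_names.extend(part)
        i += 1
    if i == len(lines):
        raise ParseError(f"line {len(lines)}: no POP marker found")
    n_loci = len(locus_names)
    if n_loci == 0:
        raise ParseError("line 2: no locus names before first POP")

    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    blocks: list[list[int]] = []  # row indices per POP block
    digits: int | None = None
    for lineno0 in range(i, len(lines)):
        line = lines[lineno0].strip()
        lineno = lineno0 + 1
        if not line:
            continue
        if line.upper() == "POP":
            blocks.append([])
            continue
        if "," not in line:
            raise ParseError(f"line {lineno}: expected 'id , genotypes'")
        ind_id, _, geno = line.partition(",")
        toks = geno.split()
        if len(toks) != n_loci:
            raise ParseError(
                f"line {lineno}: {len(toks)} genotypes for {n_loci} loci"
            )
        if digits is None:
            width = len(toks[0])
            if width not in (4, 6):
                raise ParseError(f"line {lineno}: unknown allele encoding "
                                 f"width {width}")
            digits = width // 2
        row = [_split_genepop_genotype(t, digits, lineno) for t in toks]
        ids.append(ind_id.strip())
        rows.append(row)
        blocks[-1].append(len(rows) - 1)
        pops.append("")  # filled below

    # Population naming: ids written as "POPLABEL:ID" carry their site code
    # (our writer's convention); otherwise blocks are named pop1..popN.
    for b, block in enumerate(blocks):
        prefixes = {ids[r].partition(":")[0] for r in block if ":" in ids[r]}
        if len(prefixes) == 1 and all(":" in ids[r] for r in block):
            label = prefixes.pop()
            for r in block:
                pops[r] = label
                ids[r] = ids[r].partition(":")[2]
        else:
            for r in block:
                pops[r] = f"pop{b + 1}"
    # unique-ify individual ids if the file reused the population name
    if len(set(ids)) != len(ids):
        counts: dict[str, int] = {}
        for k, v in enumerate(ids):
            counts[v] = counts.get(v, 0) + 1
            ids[k] = f"{v}_{counts[v]}"

    calls = np.array(rows, dtype=np.int64).reshape(len(rows), n_loci, 2)
    return GenotypeMatrix(
        individual_ids=ids, population_labels=pops, calls=calls,
        locus_names=locus_names,
    )


def write_genepop(G: GenotypeMatrix, path: str | Path, title: str = "landgen export") -> None:
    """Write a GenotypeMatrix as a 3-digit GenePop file (coordinates are
    not representable in GenePop and are dropped; use CSV to keep them)."""
    if G.calls.max(initial=0) > 999:
        raise ValueError("allele codes exceed 3-digit GenePop encoding")
    out = [title]
    out.extend(G.locus_names)
    current = object()
    for i in range(G.n_individuals):
        pop = G.population_labels[i]
        if pop != current:
            out.append("POP")
            current = pop
        geno = " ".join(f"{a:03d}{b:03d}" for a, b in G.calls[i])
        out.append(f"{pop}:{G.individual_ids[i]} , {geno}")
    Path(path).write_text("\n".join(out) + "\n")


# ----------------------------------------------------------------------
# CSV genotype tables
# ----------------------------------------------------------------------

@dataclass
class CsvDialect:
    """Column mapping for wide genotype CSVs.

    ``locus_columns`` maps locus name -> (allele-1 column, allele-2 column).
    If empty, columns ending in ``suffix_1``/``suffix_2`` are auto-paired.
    """

    id_col: str = "id"
    pop_col: str = "pop"
    lon_col: str | None = "lon"
    lat_col: str | None = "lat"
    suffix_1: str = "_1"
    suffix_2: str = "_2"
    locus_columns: dict[str, tuple[str, str]] = field(default_factory=dict)


def _detect_locus_columns(columns: list[str], d: CsvDialect) -> dict[str, tuple[str, str]]:
    loci: dict[str, tuple[str, str]] = {}
    for c in columns:
        if c.endswith(d.suffix_1):
            name = c[: -len(d.suffix_1)]
            c2 = name + d.suffix_2
            if c2 in columns:
                loci[name] = (c, c2)
    if not loci:
        raise ConfigError("no locus column pairs found; configure locus_columns")
    return loci


def read_genotype_csv(path: str | Path, dialect: CsvDialect | None = None) -> GenotypeMatrix:
    """Read a wide CSV genotype table (two allele columns per locus)."""
    d = dialect or CsvDialect()
    df = pd.read_csv(path)
    for col in (d.id_col, d.pop_col):
        if col not in df.columns:
            raise ConfigError(f"mapped column {col!r} not in {list(df.columns)}")
    loci = d.locus_columns or _detect_locus_columns(list(df.columns), d)
    for name, (c1, c2) in loci.items():
        for c in (c1, c2):
            if c not in df.columns:
                raise ConfigError(f"locus {name!r}: column {c!r} missing")

    n = len(df)
    calls = np.zeros((n, len(loci), 2), dtype=np.int64)
    for j, (name, (c1, c2)) in enumerate(loci.items()):
        for s, c in enumerate((c1, c2)):
            col = df[c].fillna(0)
            try:
                calls[:, j, s] = np.asarray(col, dtype=float).astype(np.int64)
            except (TypeError, ValueError) as exc:
                raise ParseError(f"non-numeric allele in column {c!r}: {exc}") from exc

    coords = None
    if d.lon_col and d.lat_col and d.lon_col in df.columns and d.lat_col in df.columns:
        coords = df[[d.lon_col, d.lat_col]].to_numpy(dtype=float)
    return GenotypeMatrix(
        individual_ids=[str(x) for x in df[d.id_col]],
        population_labels=[str(x) for x in df[d.pop_col]],
        calls=calls,
        locus_names=list(loci),
        coordinates=coords,
    )


def write_genotype_csv(G: GenotypeMatrix, path: str | Path, dialect: CsvDialect | None = None) -> None:
    d = dialect or CsvDialect()
    data: dict[str, object] = {d.id_col: G.individual_ids, d.pop_col: G.population_labels}
    if G.coordinates is not None and d.lon_col and d.lat_col:
        data[d.lon_col] = G.coordinates[:, 0]
        data[d.lat_col] = G.coordinates[:, 1]
    for j, name in enumerate(G.locus_names):
        data[name + d.suffix_1] = G.calls[:, j, 0]
        data[name + d.suffix_2] = G.calls[:, j, 1]
    pd.DataFrame(data).to_csv(path, index=False)


# ----------------------------------------------------------------------
# Occurrences and rasters
# ----------------------------------------------------------------------

def read_occurrences(
    path: str | Path,
    lon_col: str = "lon",
    lat_col: str = "lat",
    source_col: str | None = "source",
    dedup_cell_size: float | None = None,
) -> OccurrenceSet:
    """Read a lon/lat CSV; optionally keep one point per grid cell."""
    df = pd.read_csv(path)
    for col in (lon_col, lat_col):
        if col not in df.columns:
            raise ConfigError(f"column {col!r} not in {list(df.columns)}")
    sources = (
        [str(s) for s in df[source_col]]
        if source_col and source_col in df.columns
        else []
    )
    occ = OccurrenceSet(points=df[[lon_col, lat_col]].to_numpy(float), sources=sources)
    if dedup_cell_size is not None:
        occ = occ.deduplicate_cells(dedup_cell_size)
    return occ


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["lon", "lat", "source"])
        for (lon, lat), src in zip(occ.points, occ.sources):
            w.writerow([repr(float(lon)), repr(float(lat)), src])


def read_raster(path: str | Path) -> Raster:
    return read_ascii_grid(path)


def write_raster(raster: Raster, path: str | Path) -> None:
    write_ascii_grid(raster, path)
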