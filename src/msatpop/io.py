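"""Genotype-matrix CSV and GenePop interchange formats.

The CSV layout is ``individual,site,region,<locus1>,<locus2>,...`` with
genotype cells written as ``a1/a2`` (tract lengths in bp, smaller first)
or ``NA`` for missing calls.  Write-then-read is an identity, NA cells
included.  GenePop export uses the standard 3-digit diploid encoding
(``021024``; ``000000`` for missing), one POP block per population.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .matrix import META_COLUMNS, GenotypeMatrix


def write_genotype_csv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = gm.df.copy()
    for locus in gm.loci:
        df[locus] = df[locus].map(
            lambda c: "NA" if c is None else f"{c[0]}/{c[1]}"
        )
    df.index.name = "individual"
    df.to_csv(path)


def _parse_cell(cell: str, locus: str, indiv: str) -> tuple[int, int] | None:
    cell = cell.strip()
    if cell in ("NA", "", "nan"):
        return None
    try:
        a, b = cell.split("/")
        return (int(a), int(b))
    except ValueError as exc:
        raise ValueError(
            f"individual {indiv!r}, locus {locus}: cannot parse genotype {cell!r}"
        ) from exc


def read_genotype_csv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col="individual", dtype=str, keep_default_na=False)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate individual IDs: {dupes}")
    loci = [c for c in df.columns if c not in META_COLUMNS]
    out = df[list(META_COLUMNS)].copy()
    for locus in loci:
        out[locus] = [
            _parse_cell(cell, locus, indiv)
            for indiv, cell in df[locus].items()
        ]
    return GenotypeMatrix(out)


def export_genepop(
    gm: GenotypeMatrix,
    path: str | Path,
    group_by: str = "region",
    title: str = "msatpop export",
) -> None:
    """Write a GenePop 4.x file, one POP block per population.

    Alleles are encoded as 3-digit bp lengths, so every allele must be
    below 1000 bp; missing calls become ``000000``.
    """
    loci = gm.loci
    for locus in loci:
        for call in gm.df[locus]:
            if call is not None and max(call) > 999:
                raise ValueError(
                    f"locus {locus}: allele {max(call)} not encodable as 3 digits"
                )
    labels = gm.labels(group_by)
    lines = [title]
    lines.extend(loci)
    for pop in gm.populations(group_by):
        lines.append("POP")
        for indiv in gm.df.index[labels == pop]:
            cells = []
            for locus in loci:
                call = gm.df.at[indiv, locus]
                cells.append(
                    "000000" if call is None else f"{call[0]:03d}{call[1]:03d}"
                )
            lines.append(f"{indiv} ,  " + " ".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")
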