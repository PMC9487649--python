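"""Microsatellite genotype tables and the proportion-of-shared-alleles similarity.

A genotype table holds, for each individual and each locus, a multiset of
exactly ``ploidy`` allele codes (or a missing marker).  The similarity between
two individuals is the proportion of shared alleles: at each locus typed in
both, the overlap of the two allele multisets divided by the ploidy, averaged
over the commonly typed loci.  Microsatellite loci carry relatively few
alleles, so distinct pairs of individuals frequently collide on the same
similarity value — the source of tied distances downstream.
"""

from __future__ import annotations

import io
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenotypeParseError, NoSharedLociError
from .proximity import ProximityMatrix

__all__ = [
    "GenotypeTable",
    "read_genotype_table",
    "write_genotype_table",
    "shared_allele_similarity",
]

DEFAULT_MISSING = ("NA", "0", "")

Cell = tuple[str, ...] | None


@dataclass
class GenotypeTable:
    """Individuals x loci table of allele multisets.

    ``cells[i][j]`` is a tuple of exactly ``ploidy`` allele codes for
    individual ``i`` at locus ``j``, or ``None`` when the locus was not typed.
    """

    individuals: list[str]
    loci: list[str]
    cells: list[list[Cell]]
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise ValueError("ploidy must be a positive integer")
        if len(set(self.individuals)) != len(self.individuals):
            raise GenotypeParseError("duplicate individual labels")
        if len(set(self.loci)) != len(self.loci):
            raise GenotypeParseError("duplicate locus labels")
        if len(self.cells) != len(self.individuals):
            raise GenotypeParseError("cell rows do not match individuals")
        for ind, row in zip(self.individuals, self.cells):
            if len(row) != len(self.loci):
                raise GenotypeParseError(f"row {ind!r} does not match loci")
            for loc, cell in zip(self.loci, row):
                if cell is not None and len(cell) != self.ploidy:
                    raise GenotypeParseError(
                        f"cell ({ind!r}, {loc!r}) has {len(cell)} allele(s), "
                        f"expected ploidy {self.ploidy}"
                    )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def _as_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    path = Path(source)
    if path.exists():
        return path.read_text()
    text = str(source)
    if "\n" in text:
        return text
    raise GenotypeParseError(f"no such file: {source}")


def read_genotype_table(
    source,
    dialect: str = "joined",
    ploidy: int = 2,
    missing: tuple[str, ...] = DEFAULT_MISSING,
    sep: str = "/",
) -> GenotypeTable:
    """Parse a genotype CSV.

    Dialects
    --------
    ``joined``
        One column per locus; alleles joined by ``sep`` ("152/154").  A cell
        equal to a missing marker means the locus was not typed.
    ``two_column``
        ``ploidy`` columns per locus, headed ``Locus.1 .. Locus.k``.  A cell
        is missing when all of its allele columns hold a missing marker;
        a partially missing cell is a parse error.

    The first column is the individual label in both dialects.
    """
    df = pd.read_csv(io.StringIO(_as_text(source)), dtype=str, index_col=0)
    individuals = [str(x) for x in df.index]
    if len(set(individuals)) != len(individuals):
        raise GenotypeParseError("duplicate individual labels")
    miss = {m.strip() for m in missing}

    if dialect == "joined":
        loci = [str(c) for c in df.columns]
        cells: list[list[Cell]] = []
        for ind in individuals:
            row: list[Cell] = []
            for loc in loci:
                raw = df.loc[ind, loc]
                tok = "" if pd.isna(raw) else str(raw).strip()
                if tok in miss:
                    row.append(None)
                    continue
                alleles = tuple(a.strip() for a in tok.split(sep))
                if len(alleles) != ploidy or any(a in miss for a in alleles):
                    raise GenotypeParseError(
                        f"cell ({ind!r}, {loc!r}) = {tok!r}: expected "
                        f"{ploidy} allele codes joined by {sep!r}"
                    )
                row.append(alleles)
            cells.append(row)
        return GenotypeTable(individuals, loci, cells, ploidy)

    if dialect == "two_column":
        pat = re.compile(r"^(.*)\.(\d+)$")
        groups: dict[str, list[str]] = {}
        for col in map(str, df.columns):
            m = pat.match(col)
            if not m:
                raise GenotypeParseError(
                    f"column {col!r} does not follow the Locus.k convention"
                )
            groups.setdefault(m.group(1), []).append(col)
        loci = list(groups)
        for loc, cols in groups.items():
            if len(cols) != ploidy:
                raise GenotypeParseError(
                    f"locus {loc!r} has {len(cols)} allele columns, "
                    f"expected ploidy {ploidy}"
                )
        cells = []
        for ind in individuals:
            row = []
            for loc in loci:
                toks = []
                for col in groups[loc]:
                    raw = df.loc[ind, col]
                    toks.append("" if pd.isna(raw) else str(raw).strip())
                n_miss = sum(t in miss for t in toks)
                if n_miss == ploidy:
                    row.append(None)
                elif n_miss == 0:
                    row.append(tuple(toks))
                else:
                    raise GenotypeParseError(
                        f"cell ({ind!r}, {loc!r}) is partially missing: {toks}"
                    )
            cells.append(row)
        return GenotypeTable(individuals, loci, cells, ploidy)

    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotype_table(
    table: GenotypeTable,
    dest,
    dialect: str = "joined",
    missing_marker: str = "NA",
    sep: str = "/",
) -> None:
    """Write a genotype table as CSV in either dialect (inverse of the reader)."""
    if dialect == "joined":
        cols = table.loci
        data = [
            [missing_marker if c is None else sep.join(c) for c in row]
            for row in table.cells
        ]
    elif dialect == "two_column":
        cols = [f"{loc}.{k + 1}" for loc in table.loci for k in range(table.ploidy)]
        data = [
            [
                (missing_marker if c is None else c[k])
                for c in row
                for k in range(table.ploidy)
            ]
            for row in table.cells
        ]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.DataFrame(data, index=table.individuals, columns=cols)
    df.index.name = "id"
    text = df.to_csv()
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)


def shared_allele_similarity(table: GenotypeTable) -> ProximityMatrix:
    """Proportion-of-shared-alleles similarity between all individual pairs.

    For individuals a, b:  s(a, b) = mean over loci typed in both of
    ``sum_alleles min(count_a, count_b) / ploidy``.  Loci missing in either
    individual are skipped (pairwise-complete); a pair with no commonly
    typed locus raises :class:`NoSharedLociError`.
    """
    n = table.n_individuals
    if n < 2:
        raise ValueError("need at least 2 individuals")
    counts = [
        [None if c is None else Counter(c) for c in row] for row in table.cells
    ]
    s = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            per_locus = []
            for loc in range(table.n_loci):
                ca, cb = counts[i][loc], counts[j][loc]
                if ca is None or cb is None:
                    continue
                shared = sum(min(ca[a], cb[a]) for a in ca)
                per_locus.append(shared / table.ploidy)
            if not per_locus:
                raise NoSharedLociError(
                    f"individuals {table.individuals[i]!r} and "
                    f"{table.individuals[j]!r} share no typed locus"
                )
            s[i, j] = s[j, i] = float(np.mean(per_locus))
    return ProximityMatrix(list(table.individuals), s, "similarity", None)
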