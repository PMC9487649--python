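"""Generators for matrices and genotype tables with controlled tie structure.

Ties in proximity arise because distances are stated at a limited number of
decimal digits, so different pairs collide on the same printed value.  The
generators here reproduce that mechanism directly: values are drawn from (or
planted on) coarse decimal grids, never duplicated post hoc.  Planted
designs additionally have an analytically known number of alternative
binary dendrograms, so every pipeline stage can be validated without any
external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path

import numpy as np

from .genotypes import GenotypeTable
from .proximity import ProximityMatrix, round_half_away

__all__ = [
    "TieDesign",
    "planted_tie_matrix",
    "random_grid_matrix",
    "random_genotype_table",
    "fixture_intro_chain",
    "fixture_nested_tie",
    "generate_survey_set",
]


def _double_factorial(k: int) -> int:
    out = 1
    while k > 1:
        out *= k
        k -= 2
    return out


# within-block distance patterns (all values < the default separation)
#   equilateral k : all pairwise distances 1 -> (2k-3)!! alternative trees
#   chain        : d(A,B)=d(B,C)=1, d(A,C)=2 -> 2 alternative trees
#   singleton    : one item, no tie -> 1 tree
_CHAIN = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])


@dataclass(frozen=True)
class TieDesign:
    """Blueprint of a distance matrix with a known dendrogram count.

    ``blocks`` is a list of ``("equilateral", k)``, ``("chain", 3)`` or
    ``("singleton", 1)`` specs.  Blocks are separated by an ultrametric
    ladder of inter-block distances ``separation * (1 + max(i, j))`` — all
    strictly larger than any within-block value — so each block resolves
    independently and the total number of alternative binary dendrograms is
    the product of the per-block counts.  ``seed`` (optional) shuffles the
    leaf order, which must not change any count.
    """

    blocks: tuple[tuple[str, int], ...]
    separation: float = 10.0
    precision_p: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("a TieDesign needs at least one block")
        for kind, size in self.blocks:
            if kind == "equilateral" and size >= 2:
                continue
            if kind == "chain" and size == 3:
                continue
            if kind == "singleton" and size == 1:
                continue
            raise ValueError(f"invalid block spec ({kind!r}, {size})")
        if self.separation <= 2.0:
            raise ValueError("separation must exceed every within-block value (2)")

    @property
    def expected_tree_count(self) -> int:
        out = 1
        for kind, size in self.blocks:
            if kind == "equilateral":
                out *= _double_factorial(2 * size - 3)
            elif kind == "chain":
                out *= 2
        return out


def _block_values(kind: str, size: int) -> np.ndarray:
    if kind == "equilateral":
        v = np.full((size, size), 1.0)
        np.fill_diagonal(v, 0.0)
        return v
    if kind == "chain":
        return _CHAIN.copy()
    return np.zeros((1, 1))


def planted_tie_matrix(design: TieDesign) -> tuple[ProximityMatrix, int]:
    """Materialize a :class:`TieDesign` as a distance matrix.

    Returns the matrix together with its exact number of alternative binary
    dendrograms (the product of the per-block counts).
    """
    sizes = [size for _, size in design.blocks]
    n = sum(sizes)
    V = np.zeros((n, n))
    offsets = np.cumsum([0] + sizes)
    for b, (kind, size) in enumerate(design.blocks):
        lo, hi = offsets[b], offsets[b + 1]
        V[lo:hi, lo:hi] = _block_values(kind, size)
        for b2 in range(b + 1, len(design.blocks)):
            lo2, hi2 = offsets[b2], offsets[b2 + 1]
            d = design.separation * (1 + b2)
            V[lo:hi, lo2:hi2] = d
            V[lo2:hi2, lo:hi] = d
    labels = [f"x{i + 1}" for i in range(n)]
    if design.seed is not None:
        order = np.random.default_rng(design.seed).permutation(n)
        V = V[np.ix_(order, order)]
        labels = [labels[i] for i in order]
    V = round_half_away(V, design.precision_p)
    m = ProximityMatrix(labels, V, "distance", design.precision_p)
    return m, design.expected_tree_count


def random_grid_matrix(
    n: int,
    grid_step: float = 0.1,
    value_range: tuple[float, float] = (0.1, 1.0),
    seed: int = 0,
) -> ProximityMatrix:
    """Distance matrix with off-diagonal values drawn from a coarse lattice.

    Values are sampled uniformly from ``{k * grid_step}`` intersected with
    ``value_range``; the coarser the lattice, the more likely two pairs
    collide on the same distance.  ``precision_p`` is the number of decimals
    of ``grid_step``; reproducible for a given seed.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    p = max(0, -Decimal(str(grid_step)).as_tuple().exponent)
    lo, hi = value_range
    k_lo = int(np.ceil(round(lo / grid_step, 9)))
    k_hi = int(np.floor(round(hi / grid_step, 9)))
    if k_hi < k_lo:
        raise ValueError(f"no lattice point of step {grid_step} in {value_range}")
    rng = np.random.default_rng(seed)
    V = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    vals = rng.integers(k_lo, k_hi + 1, size=len(iu[0])) * grid_step
    V[iu] = vals
    V = V + V.T
    V = round_half_away(V, p)
    labels = [f"x{i + 1}" for i in range(n)]
    return ProximityMatrix(labels, V, "distance", p)


def random_genotype_table(
    n_individuals: int = 10,
    n_loci: int = 30,
    alleles_per_locus: int = 4,
    ploidy: int = 2,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeTable:
    """Random microsatellite-style genotype table.

    Allele codes are drawn uniformly from each locus's allele set.  The
    defaults mirror a typical study scale (tens of individuals, ~30 loci)
    with few alleles per locus, which makes shared-allele similarities
    collide — the tie mechanism this package studies.  Reproducible for a
    given seed.
    """
    if alleles_per_locus < 1:
        raise ValueError("alleles_per_locus must be >= 1")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    individuals = [f"ind{i + 1:02d}" for i in range(n_individuals)]
    loci = [f"L{j + 1:02d}" for j in range(n_loci)]
    # microsatellite-style codes: fragment lengths stepping by the repeat unit
    codes = [
        [str(150 + 10 * j + 2 * a) for a in range(alleles_per_locus)]
        for j in range(n_loci)
    ]
    cells = []
    for _ in individuals:
        row = []
        for j in range(n_loci):
            if missing_rate and rng.random() < missing_rate:
                row.append(None)
            else:
                row.append(tuple(rng.choice(codes[j]) for _ in range(ploidy)))
        cells.append(row)
    return GenotypeTable(individuals, loci, cells, ploidy)


def fixture_intro_chain() -> ProximityMatrix:
    """The minimal tied instance: d(A,B) = d(B,C) = 1, d(A,C) = 2.

    B is equidistant from A and C, so it can cluster with either: two binary
    dendrograms exist, while the multidendrogram fuses all three at height 1
    with tie band [1, 2].  Stated at one decimal so the A-C average (1.5)
    is exact at the working precision.
    """
    return ProximityMatrix(
        ["A", "B", "C"],
        np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]]),
        "distance",
        1,
    )


def fixture_nested_tie() -> ProximityMatrix:
    """SYNTHETIC stand-in for a mid-dendrogram tie between formed clusters.

    Ten taxa at four decimal digits: two pairs resolve first (heights 0.5 and
    0.6), then taxon t5 is exactly 1.0459 from both pairs while the pairs sit
    1.1112 apart — a tie *between clusters*, not raw items, giving exactly 2
    binary dendrograms and a multidendrogram node with band
    [1.0459, 1.1112].  Five further taxa join above the tie at distinct
    heights.  This is generated data emulating the structure of a published
    grasspea case, not a transcription of it.
    """
    n = 10
    V = np.zeros((n, n))
    V[0, 1] = 0.5
    V[2, 3] = 0.6
    for j in (0, 1, 2, 3):
        V[4, j] = 1.0459
    for i in (0, 1):
        for j in (2, 3):
            V[i, j] = 1.1112
    for k in range(5, 10):  # later taxa join tie-free at 1.3, 1.4, ...
        V[k, :k] = 1.3 + 0.1 * (k - 5)
    V = V + V.T
    np.fill_diagonal(V, 0.0)
    labels = [f"t{i + 1}" for i in range(n)]
    return ProximityMatrix(labels, round_half_away(V, 4), "distance", 4)


_TIED_DESIGNS: tuple[tuple[tuple[str, int], ...], ...] = (
    (("chain", 3), ("singleton", 1), ("singleton", 1)),
    (("equilateral", 3), ("singleton", 1)),
    (("equilateral", 3), ("chain", 3)),
    (("equilateral", 4), ("singleton", 1)),
    (("chain", 3), ("chain", 3)),
    (("equilateral", 3), ("equilateral", 3)),
)


def _ladder_matrix(n: int, step: float = 0.5) -> ProximityMatrix:
    """Tie-free control: the ultrametric d(i, j) = step * max(i, j)."""
    idx = np.arange(n)
    V = step * np.maximum.outer(idx, idx).astype(float)
    np.fill_diagonal(V, 0.0)
    p = max(0, -Decimal(str(step)).as_tuple().exponent)
    return ProximityMatrix([f"x{i + 1}" for i in range(n)], V, "distance", p)


def generate_survey_set(
    out_dir,
    n_matrices: int = 50,
    n_tied: int = 20,
    seed: int = 0,
):
    """Write a survey-ready directory: matrix CSVs plus a manifest.

    ``n_tied`` matrices are planted designs with a known count >= 2; the rest
    are tie-free ladder ultrametrics (count 1).  Entries are shuffled so tie
    status is not inferable from position.  Returns
    ``(manifest_path, expected)`` where ``expected`` maps id ->
    (has_tie, exact_count).
    """
    if not 0 <= n_tied <= n_matrices:
        raise ValueError("need 0 <= n_tied <= n_matrices")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    entries = []
    for k in range(n_matrices):
        tied = k < n_tied
        if tied:
            blocks = _TIED_DESIGNS[int(rng.integers(len(_TIED_DESIGNS)))]
            m, count = planted_tie_matrix(
                TieDesign(blocks, seed=int(rng.integers(2**31 - 1)))
            )
        else:
            m = _ladder_matrix(int(rng.integers(5, 9)))
            count = 1
        entries.append((f"m{k + 1:03d}", m, tied, count))
    order = rng.permutation(len(entries))
    lines = ["id,path,kind,transform,precision"]
    expected = {}
    from .proximity import write_proximity_matrix

    for pos in order:
        sid, m, tied, count = entries[pos]
        fname = f"{sid}.csv"
        write_proximity_matrix(m, out / fname, format="csv")
        lines.append(f"{sid},{fname},distance,none,auto")
        expected[sid] = (tied, count)
    manifest = out / "manifest.csv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest, expected
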