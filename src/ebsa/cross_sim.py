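"""Tetrad meiosis simulation and single-locus phenotype models.

Meiosis of the heterozygous A×B diploid is simulated with a four-strand
bivalent model: each chromosome pair replicates into four chromatids (two
parent-A sisters, two parent-B sisters); crossover count per bivalent is
Poisson with mean twice the genetic length in Morgans (so each meiotic
product sees the map length in expectation); crossover positions are
uniform along the physical chromosome; each crossover exchanges distal
segments between one uniformly chosen chromatid of each homolog.  No
chromatid or crossover interference.  This reproduces the classical
tetrad statistics — every marker segregates 2:2 within a tetrad, and the
two-point recombination fraction follows Haldane's map function
r = (1 - exp(-2d))/2.

The expression phenotype is controlled by a single trans-acting repressor
locus: a haploid spore that inherits the repressor parent's allele at the
causal marker is "off"; all other spores are "on".  Among expressors the
level can be modulated by the parental origin of a linked cis region
(expressors carrying the designated parent's cis context express
``cis_boost`` times the base level), with optional lognormal noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .marker_io import REF_A, MarkerMap

PARENT_A = "A"
PARENT_B = "B"
ON = "on"
OFF = "off"


@dataclass
class GeneticMap:
    """Genetic lengths per chromosome, or a constant cM/kb rate.

    ``morgans`` gives per-chromosome lengths directly; otherwise
    ``cm_per_kb`` is applied to the physical length of each chromosome.
    Yeast averages roughly 0.35 cM/kb.
    """

    morgans: dict[str, float] | None = None
    cm_per_kb: float | None = 0.35

    def chrom_morgans(self, chrom: str, length_bp: int) -> float:
        if self.morgans is not None:
            length = self.morgans.get(chrom, 0.0)
        elif self.cm_per_kb is not None:
            length = self.cm_per_kb * (length_bp / 1000.0) / 100.0
        else:
            length = 0.0
        if length < 0:
            raise ValueError(f"negative genetic length for {chrom}")
        return length


@dataclass
class SegregantGenome:
    """Per-marker parental origin of one haploid spore ('A' or 'B')."""

    origins: np.ndarray

    def __post_init__(self) -> None:
        self.origins = np.asarray(self.origins, dtype="U1")

    def __len__(self) -> int:
        return len(self.origins)


@dataclass
class Tetrad:
    """The four meiotic products of one diploid meiosis."""

    spores: list[SegregantGenome]

    def __post_init__(self) -> None:
        if len(self.spores) != 4:
            raise ValueError("a tetrad has exactly four spores")

    def origin_matrix(self) -> np.ndarray:
        """(4, n_markers) array of 'A'/'B'."""
        return np.stack([s.origins for s in self.spores])

    def is_two_two(self) -> bool:
        """True iff every marker segregates 2 A : 2 B across the spores."""
        return bool((np.sum(self.origin_matrix() == PARENT_A, axis=0) == 2).all())


@dataclass
class PhenotypeModel:
    """Single-locus trans-repressor model of a binary expression phenotype.

    Parameters
    ----------
    causal_marker
        Index into the marker map of the repressor locus.
    repressor_parent
        Which parent carries the repressing allele ('A' or 'B').
    dominance
        Whether the repressor allele represses in the heterozygous
        diploid ('dominant') or not ('recessive').
    base_level
        Expression level of an expressing spore, in arbitrary units.
    cis_region
        Optional (first, last) marker-index range (inclusive) of the
        cis-regulatory context linked to the expressed locus.
    cis_parent, cis_boost
        Expressors whose entire cis region derives from ``cis_parent``
        express ``cis_boost`` x ``base_level``.
    noise_sigma
        Sigma of multiplicative lognormal noise on the level (0 = none).
    """

    causal_marker: int
    repressor_parent: str = PARENT_A
    dominance: str = "dominant"
    base_level: float = 100.0
    cis_region: tuple[int, int] | None = None
    cis_parent: str = PARENT_A
    cis_boost: float = 1.0
    noise_sigma: float = 0.0

    def validate(self, n_markers: int) -> None:
        if not 0 <= self.causal_marker < n_markers:
            raise ValueError(f"causal_marker {self.causal_marker} out of range")
        if self.repressor_parent not in (PARENT_A, PARENT_B):
            raise ValueError("repressor_parent must be 'A' or 'B'")
        if self.dominance not in ("dominant", "recessive"):
            raise ValueError("dominance must be 'dominant' or 'recessive'")
        if self.cis_region is not None:
            lo, hi = self.cis_region
            if not (0 <= lo <= hi < n_markers):
                raise ValueError(f"cis_region {self.cis_region} out of range")
        if self.cis_boost < 0:
            raise ValueError("cis_boost must be >= 0")


@dataclass
class Phenotype:
    state: str  # ON | OFF
    level: float


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def _meiose_chromosome(
    positions: np.ndarray, length_bp: int, morgans: float, rng: np.random.Generator
) -> np.ndarray:
    """Return a (4, n_markers) origin matrix for one chromosome's tetrad.

    Crossovers are processed in position order; exchanging distal
    segments between chromatids i and j at x is equivalent to swapping
    their current origin labels for all markers beyond x.
    """
    n_co = rng.poisson(2.0 * morgans)
    labels = np.array([PARENT_A, PARENT_A, PARENT_B, PARENT_B], dtype="U1")
    out = np.empty((4, positions.size), dtype="U1")
    if n_co == 0:
        out[:] = labels[:, None]
    else:
        xs = np.sort(rng.uniform(0, length_bp, size=n_co))
        homolog_a = rng.integers(0, 2, size=n_co)       # chromatid 0 or 1
        homolog_b = 2 + rng.integers(0, 2, size=n_co)   # chromatid 2 or 3
        # piecewise-constant fill between successive crossover points
        cut = np.searchsorted(positions, xs, side="right")
        prev = 0
        for k in range(n_co):
            out[:, prev:cut[k]] = labels[:, None]
            i, j = homolog_a[k], homolog_b[k]
            labels[i], labels[j] = labels[j], labels[i]
            prev = cut[k]
        out[:, prev:] = labels[:, None]
    # independent assortment: random orientation of chromatids into spores
    return out[rng.permutation(4)]


def simulate_tetrad(
    marker_map: MarkerMap,
    gmap: GeneticMap,
    seed: int | np.random.Generator,
) -> Tetrad:
    """Simulate one meiosis of the A×B diploid into a four-spore tetrad."""
    if len(marker_map) == 0:
        raise ValueError("marker map is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    origins = np.empty((4, len(marker_map)), dtype="U1")
    positions = marker_map.positions(REF_A)
    for chrom in marker_map.chroms(REF_A):
        idx = marker_map.chrom_markers(chrom, REF_A)
        length = marker_map.chrom_length(chrom, REF_A)
        morgans = gmap.chrom_morgans(chrom, length)
        origins[:, idx] = _meiose_chromosome(positions[idx], length, morgans, rng)
    return Tetrad([SegregantGenome(origins[i]) for i in range(4)])


def simulate_cross(
    marker_map: MarkerMap,
    gmap: GeneticMap,
    n_tetrads: int,
    seed: int | np.random.Generator,
) -> list[Tetrad]:
    """Simulate ``n_tetrads`` independent meioses (deterministic per seed)."""
    if n_tetrads < 1:
        raise ValueError("n_tetrads must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [simulate_tetrad(marker_map, gmap, rng) for _ in range(n_tetrads)]


# ---------------------------------------------------------------------------
# phenotype
# ---------------------------------------------------------------------------


def assign_phenotype(
    spore: SegregantGenome,
    model: PhenotypeModel,
    rng: np.random.Generator | None = None,
) -> Phenotype:
    """Binary expression call (and level) for one haploid spore.

    The repressor acts in trans, so a haploid carrying the repressor
    parent's allele at the causal marker is off regardless of dominance
    (dominance only matters in the heterozygous diploid).
    """
    model.validate(len(spore))
    if spore.origins[model.causal_marker] == model.repressor_parent:
        return Phenotype(OFF, 0.0)
    level = model.base_level
    if model.cis_region is not None:
        lo, hi = model.cis_region
        if (spore.origins[lo : hi + 1] == model.cis_parent).all():
            level *= model.cis_boost
    if model.noise_sigma > 0:
        if rng is None:
            raise ValueError("noise_sigma > 0 requires an rng")
        level *= float(np.exp(rng.normal(0.0, model.noise_sigma)))
    return Phenotype(ON, level)


def diploid_phenotype(model: PhenotypeModel) -> str:
    """Expression state of the heterozygous A/B diploid.

    With a dominant repressor allele present the heterozygote is off;
    with a recessive repressor it expresses.
    """
    return OFF if model.dominance == "dominant" else ON


def phenotype_cross(
    tetrads: Sequence[Tetrad],
    model: PhenotypeModel,
    rng: np.random.Generator | None = None,
) -> list[list[Phenotype]]:
    """Phenotype every spore, keeping the tetrad grouping."""
    return [[assign_phenotype(s, model, rng) for s in t.spores] for t in tetrads]


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------


def genotype_frame(tetrads: Sequence[Tetrad], marker_map: MarkerMap) -> pd.DataFrame:
    """Markers x spores matrix of parental origins ('A'/'B')."""
    cols = {}
    for t_i, tet in enumerate(tetrads):
        for s_i, spore in enumerate(tet.spores):
            cols[f"t{t_i}_s{s_i}"] = spore.origins
    out = marker_map.df[["chrom_a", "pos_a"]].copy()
    return pd.concat([out, pd.DataFrame(cols)], axis=1)


def write_genotypes_tsv(
    tetrads: Sequence[Tetrad], marker_map: MarkerMap, path: str | Path
) -> Path:
    path = Path(path)
    genotype_frame(tetrads, marker_map).to_csv(path, sep="\t", index=False)
    return path


def write_phenotypes_tsv(
    phenotypes: Sequence[Sequence[Phenotype]], path: str | Path
) -> Path:
    rows = [
        (f"t{t_i}_s{s_i}", p.state, p.level)
        for t_i, tet in enumerate(phenotypes)
        for s_i, p in enumerate(tet)
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=["spore", "state", "level"]).to_csv(
        path, sep="\t", index=False
    )
    return path
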