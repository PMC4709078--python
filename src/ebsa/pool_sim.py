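"""Phenotype-defined pools and pooled-sequencing allele counts.

Segregants are binned into an expressing and a non-expressing pool (the
equimolar-DNA pooling of a bulked segregant design).  Pooled short-read
sequencing at each SNP is emulated marker-by-marker: read depth is
Poisson around the mean coverage (a fixed-depth mode exists for exact
tests), each read derives from a uniformly chosen pool member (optional
weights model pipetting inaccuracy), reads whose true allele does not
match the mapping reference are lost with probability ``ref_bias``
(alignment failure of diverged reads), and surviving reads report the
wrong allele with probability ``error_rate``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cross_sim import ON, PARENT_B, Phenotype, SegregantGenome
from .marker_io import COUNT_COLUMNS, REF_A, REF_B, AlleleCountTable, MarkerMap

logger = logging.getLogger("ebsa")

EXPRESSING = "expressing"
NON_EXPRESSING = "non_expressing"


@dataclass
class Pool:
    """A labelled set of spore indices pooled for sequencing."""

    label: str
    members: list[int]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pool {self.label!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"pool {self.label!r} has duplicate members")


@dataclass
class SeqModel:
    """Pooled-sequencing emulation parameters.

    coverage: mean reads per marker per pool (Poisson unless
    ``fixed_depth``); error_rate: per-read probability of reporting the
    other allele; ref_bias: per-read probability that a read carrying
    the non-mapped-reference allele is lost.
    """

    coverage: float = 50.0
    error_rate: float = 0.002
    ref_bias: float = 0.0
    fixed_depth: bool = False
    weights: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        for name in ("error_rate", "ref_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def pool_by_phenotype(
    spore_ids: Sequence[int], phenotypes: Sequence[Phenotype | str]
) -> tuple[Pool, Pool]:
    """Partition spores into (expressing, non_expressing) pools.

    Raises if either pool would be empty — mapping is impossible when
    the phenotype does not segregate.
    """
    if len(spore_ids) != len(phenotypes):
        raise ValueError("every spore needs a phenotype call")
    states = [p.state if isinstance(p, Phenotype) else p for p in phenotypes]
    on_ids = [s for s, st in zip(spore_ids, states) if st == ON]
    off_ids = [s for s, st in zip(spore_ids, states) if st != ON]
    if not on_ids or not off_ids:
        raise ValueError(
            "all spores share one phenotype state; pooling is uninformative"
        )
    return Pool(EXPRESSING, on_ids), Pool(NON_EXPRESSING, off_ids)


def simulate_pool_counts(
    pools: Sequence[Pool],
    marker_map: MarkerMap,
    spore_genomes: Sequence[SegregantGenome],
    model: SeqModel,
    reference: str = REF_A,
    seed: int | np.random.Generator = 0,
) -> AlleleCountTable:
    """Simulate pooled read counts at every marker for each pool.

    Reads are mapped against ``reference``; ``ref_bias`` drops reads
    whose true allele belongs to the other parent.  Sequencing error is
    applied to the reported allele of surviving reads.  Deterministic
    given the seed.
    """
    if reference not in (REF_A, REF_B):
        raise ValueError(f"unknown reference {reference!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_markers = len(marker_map)
    if model.coverage == 0:
        logger.warning("coverage is 0; emitting empty count table")
        return AlleleCountTable(pd.DataFrame(columns=COUNT_COLUMNS))

    frames = []
    for pool in pools:
        genomes = np.stack([spore_genomes[i].origins for i in pool.members])
        is_b = genomes == PARENT_B  # (members, markers)
        if model.weights is not None:
            w = np.asarray([model.weights[i] for i in pool.members], dtype=float)
            if (w < 0).any() or w.sum() == 0:
                raise ValueError("pool weights must be non-negative, not all zero")
            p_b = (w[:, None] * is_b).sum(axis=0) / w.sum()
        else:
            p_b = is_b.mean(axis=0)

        if model.fixed_depth:
            depth = np.full(n_markers, int(round(model.coverage)))
        else:
            depth = rng.poisson(model.coverage, size=n_markers)
        true_b = rng.binomial(depth, p_b)
        true_a = depth - true_b
        # reference-mapping bias: non-reference reads are lost
        if model.ref_bias > 0:
            if reference == REF_A:
                true_b = rng.binomial(true_b, 1.0 - model.ref_bias)
            else:
                true_a = rng.binomial(true_a, 1.0 - model.ref_bias)
        # sequencing error: surviving reads mis-report their allele
        if model.error_rate > 0:
            a_to_b = rng.binomial(true_a, model.error_rate)
            b_to_a = rng.binomial(true_b, model.error_rate)
            n_a = true_a - a_to_b + b_to_a
            n_b = true_b - b_to_a + a_to_b
        else:
            n_a, n_b = true_a, true_b
        frames.append(
            pd.DataFrame(
                {
                    "marker": np.arange(n_markers),
                    "pool": pool.label,
                    "n_a": n_a,
                    "n_b": n_b,
                    "reference": reference,
                }
            )
        )
    return AlleleCountTable(pd.concat(frames, ignore_index=True))
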