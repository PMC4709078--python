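"""Tests of phenotype inheritance: 2:2 tetrad segregation and dominance.

A binary phenotype controlled by a single Mendelian locus segregates
2 on : 2 off in every four-spore tetrad, and 1:1 across all spores of a
cross.  The 2:2 check is structural (every tetrad must fit); the 1:1
check is an exact two-sided binomial test, appropriate at tetrad-
dissection sample sizes (tens of spores).  Dominance is read from the
heterozygous diploid: the parent whose phenotype the diploid matches
carries the dominant allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy.stats import binomtest

from .cross_sim import ON, Phenotype

logger = logging.getLogger("ebsa")


@dataclass
class SegregationReport:
    """Per-tetrad on:off counts plus cross-wide segregation statistics."""

    tetrad_counts: list[tuple[int, int]]  # (n_on, n_off) per tetrad
    fraction_two_two: float
    single_locus_consistent: bool  # all tetrads 2:2
    n_on: int
    n_total: int
    binomial_p: float  # exact two-sided p for 1:1 across all spores

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tetrad": range(len(self.tetrad_counts)),
                "n_on": [c[0] for c in self.tetrad_counts],
                "n_off": [c[1] for c in self.tetrad_counts],
                "is_two_two": [c == (2, 2) for c in self.tetrad_counts],
            }
        )


def _state(call: Phenotype | str) -> str:
    return call.state if isinstance(call, Phenotype) else call


def tetrad_segregation_test(
    tetrad_phenotypes: Sequence[Sequence[Phenotype | str]],
) -> SegregationReport:
    """Score each tetrad's on:off ratio and test 1:1 spore segregation.

    The two-sided binomial p-value follows the minimum-likelihood
    convention: the sum of probabilities of all outcomes no more likely
    than the observed one, under Binomial(n, 1/2).  At the most central
    outcome (e.g. 14 of 28) every outcome qualifies and p = 1.
    """
    counts: list[tuple[int, int]] = []
    for i, tet in enumerate(tetrad_phenotypes):
        if len(tet) != 4:
            raise ValueError(f"tetrad {i} has {len(tet)} spores, expected 4")
        n_on = sum(1 for c in tet if _state(c) == ON)
        counts.append((n_on, 4 - n_on))
    n_total = 4 * len(counts)
    n_on_total = sum(c[0] for c in counts)
    n_two_two = sum(1 for c in counts if c == (2, 2))
    p = binomtest(n_on_total, n_total, 0.5, alternative="two-sided").pvalue
    report = SegregationReport(
        tetrad_counts=counts,
        fraction_two_two=n_two_two / len(counts),
        single_locus_consistent=n_two_two == len(counts),
        n_on=n_on_total,
        n_total=n_total,
        binomial_p=float(p),
    )
    logger.info(
        "segregation: %d/%d tetrads 2:2; %d/%d spores on; binomial p=%.4g",
        n_two_two, len(counts), n_on_total, n_total, p,
    )
    return report


def dominance_test(
    diploid_state: str, parent_a_state: str, parent_b_state: str
) -> str:
    """Call the dominant parent from the heterozygote's phenotype.

    Returns 'A' or 'B': the parent whose expression state the diploid
    matches.  Parents with identical states are uninformative.
    """
    if parent_a_state == parent_b_state:
        raise ValueError("parents share the same state; dominance is uninformative")
    if diploid_state == parent_a_state:
        return "A"
    if diploid_state == parent_b_state:
        return "B"
    raise ValueError(f"diploid state {diploid_state!r} matches neither parent")


def write_report_tsv(report: SegregationReport, path: str | Path) -> Path:
    path = Path(path)
    report.to_frame().to_csv(path, sep="\t", index=False)
    return path
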