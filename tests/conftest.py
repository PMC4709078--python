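"""Shared fixtures: small marker maps and deterministic RNG helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ebsa.marker_io import MARKER_COLUMNS, MarkerMap

BASES = "ACGT"


def make_map(
    positions_by_chrom: dict[str, list[int]],
    lengths: dict[str, int] | None = None,
    offset_b: int = 0,
    rng: np.random.Generator | None = None,
) -> MarkerMap:
    """Build a MarkerMap from explicit positions (refB = refA + offset)."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for chrom, positions in positions_by_chrom.items():
        for p in positions:
            ref = int(rng.integers(0, 4))
            alt = (ref + int(rng.integers(1, 4))) % 4
            rows.append((chrom, p, chrom, p + offset_b, BASES[ref], BASES[alt]))
    df = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    lengths = lengths or {
        c: max(ps) + 1000 for c, ps in positions_by_chrom.items()
    }
    return MarkerMap(df, genome_lengths={"refA": lengths, "refB": dict(lengths)})


def random_map(n_markers: int, seed: int, n_chroms: int = 2) -> MarkerMap:
    """A random sorted marker map spread over a few chromosomes."""
    rng = np.random.default_rng(seed)
    per = np.array_split(np.arange(n_markers), n_chroms)
    positions = {}
    for i, chunk in enumerate(per):
        pos = np.sort(rng.choice(np.arange(1000, 500_000), size=len(chunk), replace=False))
        positions[f"chr{i + 1}"] = [int(p) for p in pos]
    return make_map(positions, rng=rng)


@pytest.fixture
def two_marker_map() -> MarkerMap:
    """Two terminal markers on one 100 kb chromosome."""
    return make_map({"chr1": [1, 100_000]}, lengths={"chr1": 100_000})


@pytest.fixture
def small_map() -> MarkerMap:
    return make_map(
        {"chr1": [1000, 5000, 9000], "chr2": [2000, 4000]},
        lengths={"chr1": 10_000, "chr2": 6_000},
    )
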