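"""Pooled allele-frequency profiles and concordant-region calling.

The mapping criterion of expression-guided bulked segregant analysis is
exact fixation, not a windowed statistic: the causal locus must be
inherited exclusively from the non-repressor parent in every expressing
segregant and from the repressor parent in every non-expressing
segregant.  A marker is *concordant* when the pooled frequency of the
non-repressor parent's allele is >= 1 - epsilon in the expressing pool
and <= epsilon in the non-expressing pool; candidate regions are maximal
runs of at least ``min_snps`` concordant markers on one chromosome.  A
run may bridge up to ``max_gap`` consecutive non-concordant markers —
no-calls from low depth, or isolated sub-threshold markers produced by
sequencing-error reads at finite coverage.  Genuine recombination
breakpoints discord over long marker stretches and still terminate
runs; the bridge only absorbs single-marker noise, keeping the truly
fixed interval intact as one region.

Allele frequencies are reported the way a dual-reference mapping
produces them: as the frequency of the NON-mapped-reference parent's
allele in each pool.  Mapping one pool against both parental references
yields two estimates of the same pool frequency with opposite
reference-bias direction; the default ``combine`` mode pools the read
counts across orientations (a depth-weighted frequency), which is the
efficient estimator and cancels mapping bias to first order.  A
``strict`` mode instead demands concordance under every orientation
separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .marker_io import REF_A, AlleleCountTable, MarkerMap

AF_COLUMNS = ["marker", "pool", "af", "depth", "reference"]

CONCORDANT, NOCALL, DISCORDANT = 1, 0, -1


@dataclass
class AFProfile:
    """Per-(marker, pool, reference) allele frequencies.

    ``af`` is the frequency of the non-mapped-reference parent's allele
    (reads supporting parent B when mapped to refA, and vice versa);
    NaN flags no-calls where depth is below the cutoff.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in AF_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"AF profile missing columns: {missing}")
        self.df = self.df[AF_COLUMNS].reset_index(drop=True)
        ok = self.df["af"].isna() | self.df["af"].between(0.0, 1.0)
        if not ok.all():
            raise ValueError("allele frequencies must lie in [0, 1]")

    def select(self, pool: str) -> "AFProfile":
        return AFProfile(self.df[self.df["pool"] == pool].copy())

    def references(self) -> list[str]:
        return sorted(self.df["reference"].unique())

    def freq_b(self, reference: str) -> pd.Series:
        """Frequency of the parent-B allele, indexed by marker."""
        sub = self.df[self.df["reference"] == reference]
        s = sub.set_index("marker")["af"]
        return s if reference == REF_A else 1.0 - s


@dataclass
class CandidateRegion:
    """A maximal interval of pool-opposite fixation (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    n_markers: int
    mean_af_expressing: float | None = None
    mean_af_nonexpressing: float | None = None
    marker_indices: list[int] = field(default_factory=list)
    contains_causal: bool | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"region end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def compute_af(counts: AlleleCountTable, min_depth: int = 10) -> AFProfile:
    """Allele-frequency profile from pooled read counts.

    AF is the fraction of reads supporting the non-mapped-reference
    parent's allele; markers with depth below ``min_depth`` are flagged
    as no-calls (NaN).
    """
    df = counts.df.copy()
    depth = (df["n_a"] + df["n_b"]).to_numpy(dtype=float)
    alt = np.where(df["reference"] == REF_A, df["n_b"], df["n_a"]).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(depth > 0, alt / depth, np.nan)
    af = np.where(depth < min_depth, np.nan, af)
    out = pd.DataFrame(
        {
            "marker": df["marker"],
            "pool": df["pool"],
            "af": af,
            "depth": depth.astype(int),
            "reference": df["reference"],
        }
    )
    return AFProfile(out)


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


def _marker_status(
    af_expr: AFProfile,
    af_nonexpr: AFProfile,
    repressor_parent: str,
    epsilon: float,
    n_markers: int,
    mode: str = "combine",
) -> np.ndarray:
    """Per-marker status in {CONCORDANT, NOCALL, DISCORDANT}.

    ``combine`` pools read counts across mapping orientations into one
    depth-weighted frequency per pool before applying the epsilon test.
    ``strict`` requires the test to pass under every orientation where
    both pools are called, and flags a marker discordant as soon as any
    called orientation fails.
    """
    refs = sorted(set(af_expr.references()) & set(af_nonexpr.references()))
    if not refs:
        raise ValueError("profiles share no mapping reference")
    status = np.full(n_markers, NOCALL, dtype=int)
    if mode == "combine":
        f_e = _freq_nonrep(af_expr, repressor_parent, n_markers)
        f_n = _freq_nonrep(af_nonexpr, repressor_parent, n_markers)
        called = ~np.isnan(f_e) & ~np.isnan(f_n)
        conc = called & (f_e >= 1.0 - epsilon) & (f_n <= epsilon)
        status[conc] = CONCORDANT
        status[called & ~conc] = DISCORDANT
        return status
    if mode != "strict":
        raise ValueError(f"unknown mode {mode!r}")
    any_called = np.zeros(n_markers, dtype=bool)
    any_discordant = np.zeros(n_markers, dtype=bool)
    all_concordant = np.ones(n_markers, dtype=bool)
    for ref in refs:
        fb_e = af_expr.freq_b(ref).reindex(range(n_markers))
        fb_n = af_nonexpr.freq_b(ref).reindex(range(n_markers))
        if repressor_parent == "A":
            f_e, f_n = fb_e.to_numpy(), fb_n.to_numpy()
        else:
            f_e, f_n = 1.0 - fb_e.to_numpy(), 1.0 - fb_n.to_numpy()
        called = ~np.isnan(f_e) & ~np.isnan(f_n)
        conc = called & (f_e >= 1.0 - epsilon) & (f_n <= epsilon)
        any_called |= called
        any_discordant |= called & ~conc
        all_concordant &= ~called | conc
    status[any_called & all_concordant] = CONCORDANT
    status[any_discordant] = DISCORDANT
    return status


def call_concordant_regions(
    af_expr: AFProfile,
    af_nonexpr: AFProfile,
    marker_map: MarkerMap,
    repressor_parent: str = "A",
    epsilon: float = 0.02,
    min_snps: int = 2,
    max_gap: int = 2,
    causal_marker: int | None = None,
    mode: str = "combine",
) -> list[CandidateRegion]:
    """Call maximal runs of concordant markers per chromosome.

    Both profiles must cover the same marker set.  Region boundaries are
    SNP-bounded: the refA positions of the first and last concordant
    marker of the run.  ``max_gap`` is the largest number of consecutive
    non-concordant markers (no-call or sub-threshold) a run may bridge.
    ``contains_causal`` is positional: true when the causal marker's
    position falls within the region span on the same chromosome.
    """
    me = set(af_expr.df["marker"])
    mn = set(af_nonexpr.df["marker"])
    if me != mn:
        raise ValueError("expressing/non-expressing profiles cover different markers")
    n_markers = len(marker_map)
    status = _marker_status(
        af_expr, af_nonexpr, repressor_parent, epsilon, n_markers, mode
    )

    fnr_e = _freq_nonrep(af_expr, repressor_parent, n_markers)
    fnr_n = _freq_nonrep(af_nonexpr, repressor_parent, n_markers)
    positions = marker_map.positions(REF_A)

    causal_chrom = causal_pos = None
    if causal_marker is not None:
        causal_chrom = marker_map.df["chrom_a"][causal_marker]
        causal_pos = int(positions[causal_marker])

    regions: list[CandidateRegion] = []
    for chrom in marker_map.chroms(REF_A):
        idx = marker_map.chrom_markers(chrom, REF_A)
        run: list[int] = []
        gap = 0
        for m in idx:
            if status[m] == CONCORDANT:
                if run and gap > max_gap:
                    _close_run(regions, run, chrom, positions, fnr_e, fnr_n,
                               min_snps, causal_chrom, causal_pos)
                    run = []
                run.append(int(m))
                gap = 0
            else:  # no-call or sub-threshold: bridgeable up to max_gap
                gap += 1
        _close_run(regions, run, chrom, positions, fnr_e, fnr_n,
                   min_snps, causal_chrom, causal_pos)
    for i, r in enumerate(regions, start=1):
        r.name = f"region_{i}"
    return regions


def _freq_nonrep(
    profile: AFProfile, repressor_parent: str, n_markers: int
) -> np.ndarray:
    """Depth-weighted frequency of the non-repressor allele per marker.

    Pools the called read counts across mapping orientations; no-call
    orientations contribute nothing, and markers with no called
    orientation are NaN.
    """
    num = np.zeros(n_markers)
    den = np.zeros(n_markers)
    for ref in profile.references():
        sub = profile.df[profile.df["reference"] == ref].set_index("marker")
        fb = sub["af"].reindex(range(n_markers)).to_numpy()
        if ref != REF_A:
            fb = 1.0 - fb
        depth = sub["depth"].reindex(range(n_markers)).to_numpy(dtype=float)
        called = ~np.isnan(fb)
        num[called] += fb[called] * depth[called]
        den[called] += depth[called]
    with np.errstate(invalid="ignore", divide="ignore"):
        fb_comb = np.where(den > 0, num / den, np.nan)
    return fb_comb if repressor_parent == "A" else 1.0 - fb_comb


def _close_run(
    regions: list[CandidateRegion],
    run: list[int],
    chrom: str,
    positions: np.ndarray,
    fnr_e: np.ndarray,
    fnr_n: np.ndarray,
    min_snps: int,
    causal_chrom: str | None,
    causal_pos: int | None,
) -> None:
    if len(run) < min_snps:
        return
    start, end = int(positions[run[0]]), int(positions[run[-1]])
    contains = None
    if causal_pos is not None:
        contains = chrom == causal_chrom and start <= causal_pos <= end
    regions.append(
        CandidateRegion(
            chrom=chrom,
            start=start,
            end=end,
            n_markers=len(run),
            mean_af_expressing=float(np.nanmean(fnr_e[run])),
            mean_af_nonexpressing=float(np.nanmean(fnr_n[run])),
            marker_indices=list(run),
            contains_causal=contains,
        )
    )


# ---------------------------------------------------------------------------
# plotting / tracks
# ---------------------------------------------------------------------------


def af_difference_track(
    af_expr: AFProfile,
    af_nonexpr: AFProfile,
    marker_map: MarkerMap,
    repressor_parent: str = "A",
    window: int = 11,
) -> pd.DataFrame:
    """Windowed allele-frequency-difference track, for plotting only.

    Rolling mean (per chromosome, ``window`` markers) of the difference
    in non-repressor allele frequency between the pools.  The region
    caller does not use this track; the mapping criterion is exact
    fixation.
    """
    n = len(marker_map)
    delta = _freq_nonrep(af_expr, repressor_parent, n) - _freq_nonrep(
        af_nonexpr, repressor_parent, n
    )
    out = marker_map.df[["chrom_a", "pos_a"]].copy()
    out["delta_af"] = delta
    out["delta_af_smooth"] = (
        out.groupby("chrom_a", sort=False)["delta_af"]
        .transform(lambda s: s.rolling(window, center=True, min_periods=1).mean())
    )
    return out


def plot_af_profiles(
    af_expr: AFProfile,
    af_nonexpr: AFProfile,
    marker_map: MarkerMap,
    path: str | Path,
    reference: str = REF_A,
    regions: list[CandidateRegion] | None = None,
) -> Path:
    """Per-chromosome scatter of pool allele frequencies (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = marker_map.chroms(REF_A)
    positions = marker_map.positions(REF_A)
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(10, 1.6 * len(chroms)), sharex=False, squeeze=False
    )
    for ax, chrom in zip(axes[:, 0], chroms):
        idx = marker_map.chrom_markers(chrom, REF_A)
        for prof, color, label in (
            (af_expr, "tab:red", "expressing"),
            (af_nonexpr, "tab:blue", "non-expressing"),
        ):
            sub = prof.df[prof.df["reference"] == reference].set_index("marker")
            af = sub["af"].reindex(idx)
            ax.scatter(positions[idx], af, s=4, color=color, label=label, alpha=0.6)
        if regions:
            for r in regions:
                if r.chrom == chrom:
                    ax.axvspan(r.start, r.end, color="gold", alpha=0.3)
        ax.set_ylim(-0.05, 1.05)
        ax.set_ylabel(chrom, fontsize=7)
    axes[0, 0].legend(fontsize=7, loc="upper right")
    axes[-1, 0].set_xlabel("position (bp)")
    fig.suptitle(f"pool allele frequencies (mapped to {reference})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def write_af_tsv(profile: AFProfile, path: str | Path) -> Path:
    profile.df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_af_tsv(path: str | Path) -> AFProfile:
    return AFProfile(pd.read_csv(path, sep="\t"))
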