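"""Expression analytics over differential-expression and variant tables.

The trans-factor dependence logic is pure set algebra over thresholded
DE calls: a gene differentially expressed between the two wildtype
strains but *not* between the corresponding factor-deletion strains is
factor-dependent, because removing the factor removes the interstrain
difference.  Around that core sit the companion analytics: on/off
"extreme expressor" classification, TSS-proximal SNP fractions, promoter
SNP-density ranking, synonymous/nonsynonymous SNP classification over
coding sequences, and two empirical-CDF summaries (distance from an
expression line of best fit, and cumulative differential-expression
magnitude).

Adjusted p-values are consumed as given (the negative-binomial DE test
itself is upstream of this package); a Benjamini-Hochberg helper exists
for tables that supply raw p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.stats import linregress
from statsmodels.distributions.empirical_distribution import ECDF
from statsmodels.stats.multitest import multipletests

from .marker_io import AnnotationSet, MarkerMap

logger = logging.getLogger("ebsa")

#: the seven strain comparisons of the study design: wildtype-vs-wildtype,
#: deletion-vs-deletion, each deletion vs its wildtype, each allele-swap
#: vs its wildtype, and swap-vs-swap.
COMPARISONS = (
    "wtA_vs_wtB",
    "delA_vs_delB",
    "wtA_vs_delA",
    "wtB_vs_delB",
    "wtA_vs_swapA",
    "wtB_vs_swapB",
    "swapA_vs_swapB",
)

DE_COLUMNS = ["gene", "comparison", "mean_a", "mean_b", "log2fc", "padj"]

#: default thresholds for protein-coding DE calls
DEFAULT_PADJ = 0.0005
DEFAULT_MIN_MEAN = 100.0


def validate_de_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    if not table["padj"].between(0, 1).all():
        raise ValueError("padj outside [0, 1]")
    if (table[["mean_a", "mean_b"]] < 0).to_numpy().any():
        raise ValueError("negative expression means")
    return table


# ---------------------------------------------------------------------------
# DE calling and dependence set logic
# ---------------------------------------------------------------------------


def call_de(
    table: pd.DataFrame,
    comparison: str,
    padj_max: float = DEFAULT_PADJ,
    min_mean: float = DEFAULT_MIN_MEAN,
) -> set[str]:
    """Genes differentially expressed in one comparison.

    A gene is called iff padj <= ``padj_max`` and its average expression
    across the two compared conditions is >= ``min_mean`` normalized
    read counts.
    """
    validate_de_table(table)
    sub = table[table["comparison"] == comparison]
    if sub.empty:
        present = sorted(table["comparison"].unique())
        raise ValueError(f"comparison {comparison!r} not in table; present: {present}")
    avg = (sub["mean_a"] + sub["mean_b"]) / 2.0
    hit = (sub["padj"] <= padj_max) & (avg >= min_mean)
    return set(sub.loc[hit, "gene"])


@dataclass
class DependenceClass:
    """Partition of the gene universe by trans-factor dependence."""

    dependent: set[str]      # DE between wildtypes but not between deletions
    deletion_only: set[str]  # DE only between the deletion strains
    independent: set[str]    # everything else

    @property
    def counts(self) -> dict[str, int]:
        return {
            "dependent": len(self.dependent),
            "deletion_only": len(self.deletion_only),
            "independent": len(self.independent),
        }

    def label_of(self, gene: str) -> str:
        if gene in self.dependent:
            return "dependent"
        if gene in self.deletion_only:
            return "deletion_only"
        return "independent"

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, "dependent") for g in sorted(self.dependent)]
        rows += [(g, "deletion_only") for g in sorted(self.deletion_only)]
        rows += [(g, "independent") for g in sorted(self.independent)]
        return pd.DataFrame(rows, columns=["gene", "class"])


def dependence_classes(
    de_wt: set[str], de_del: set[str], universe: set[str]
) -> DependenceClass:
    """Classify genes by whether their interstrain DE requires the factor.

    dependent = de_wt \\ de_del; deletion_only = de_del \\ de_wt; the
    remainder of the universe (including the wt∩del overlap) is
    independent of the factor.
    """
    if not de_wt <= universe or not de_del <= universe:
        raise ValueError("DE sets must be subsets of the universe")
    dependent = de_wt - de_del
    deletion_only = de_del - de_wt
    independent = universe - dependent - deletion_only
    return DependenceClass(dependent, deletion_only, independent)


# ---------------------------------------------------------------------------
# on/off extreme-expressor classification
# ---------------------------------------------------------------------------

ON_IN_A = "on_in_A_off_in_B"
ON_IN_B = "on_in_B_off_in_A"
BOTH_ON = "both_on"
BOTH_OFF = "both_off"


@dataclass
class OnOffCall:
    state: str
    on_min: float
    off_max: float


def classify_on_off(
    expr_a: float, expr_b: float, on_min: float = 100.0, off_max: float = 10.0
) -> OnOffCall:
    """Four-way on/off call for one transcript at stated count cutoffs.

    A strain is "on" at >= ``on_min`` normalized reads and "off" at
    <= ``off_max``; intermediate levels count as on for the purpose of
    excluding the transcript from the extreme (on/off) class.
    """
    if on_min <= off_max:
        raise ValueError("on_min must exceed off_max")
    a_off = expr_a <= off_max
    b_off = expr_b <= off_max
    if a_off and b_off:
        state = BOTH_OFF
    elif expr_a >= on_min and b_off:
        state = ON_IN_A
    elif expr_b >= on_min and a_off:
        state = ON_IN_B
    else:
        state = BOTH_ON
    return OnOffCall(state, on_min, off_max)


def on_off_table(
    expr: pd.DataFrame, on_min: float = 100.0, off_max: float = 10.0
) -> pd.DataFrame:
    """Vectorized on/off calls for a (gene, expr_a, expr_b) table."""
    calls = [
        classify_on_off(a, b, on_min, off_max).state
        for a, b in zip(expr["expr_a"], expr["expr_b"])
    ]
    out = expr[["gene"]].copy()
    out["state"] = calls
    return out


def on_off_sweep(
    expr: pd.DataFrame,
    on_grid: Sequence[float],
    off_grid: Sequence[float],
) -> pd.DataFrame:
    """Extreme-expressor counts across a threshold grid.

    Returns one row per (on_min, off_max) pair with the number of
    transcripts called on in exactly one strain — the sweep behind an
    "on/off transcript assessment at varying cutoffs".
    """
    rows = []
    for on_min in on_grid:
        for off_max in off_grid:
            if on_min <= off_max:
                continue
            tab = on_off_table(expr, on_min, off_max)
            n_extreme = int(tab["state"].isin([ON_IN_A, ON_IN_B]).sum())
            rows.append((on_min, off_max, n_extreme))
    return pd.DataFrame(rows, columns=["on_min", "off_max", "n_extreme"])


# ---------------------------------------------------------------------------
# SNPs near transcription start sites
# ---------------------------------------------------------------------------


def snp_near_tss(
    markers: MarkerMap,
    annotations: AnnotationSet,
    transcripts: Iterable[str],
    window: int = 50,
) -> float:
    """Fraction of transcripts with a SNP within ``window`` bp of the TSS.

    The window is inclusive on both boundaries and symmetric around the
    TSS.  Transcripts without an annotated TSS are skipped with a
    warning.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    transcripts = list(transcripts)
    hits = tss_snp_hits(markers, annotations, transcripts, window)
    n = 0
    for t in transcripts:
        row = annotations.genes[annotations.genes["gene"] == t]
        if row.empty or pd.isna(row["tss"].iloc[0]):
            continue
        n += 1
    return len(hits) / n if n else float("nan")


def tss_snp_hits(
    markers: MarkerMap,
    annotations: AnnotationSet,
    transcripts: Iterable[str],
    window: int = 50,
) -> set[str]:
    """The subset of transcripts with >= 1 SNP within the TSS window."""
    genes = annotations.genes.set_index("gene")
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in markers.chroms():
        idx = markers.chrom_markers(chrom)
        by_chrom[chrom] = np.sort(markers.positions()[idx])
    hits: set[str] = set()
    for t in transcripts:
        if t not in genes.index:
            logger.warning("transcript %s has no annotation; skipped", t)
            continue
        row = genes.loc[t]
        if pd.isna(row["tss"]):
            logger.warning("transcript %s has no TSS; skipped", t)
            continue
        pos = by_chrom.get(row["chrom"])
        if pos is None:
            continue
        tss = int(row["tss"])
        lo = np.searchsorted(pos, tss - window, side="left")
        hi = np.searchsorted(pos, tss + window, side="right")
        if hi > lo:
            hits.add(t)
    return hits


# ---------------------------------------------------------------------------
# promoter SNP density
# ---------------------------------------------------------------------------


def promoter_snp_density(
    markers: MarkerMap, annotations: AnnotationSet
) -> pd.DataFrame:
    """SNP count and density per intergenic (promoter) region, ranked.

    Rank 1 is the most SNP-dense promoter; ties break by density, then
    region name, for determinism.  Zero-length regions are excluded with
    a warning.
    """
    ig = annotations.intergenic
    rows = []
    for row in ig.itertuples(index=False):
        length = row.end - row.start + 1
        if length <= 0:
            logger.warning("zero-length region %s excluded", row.region)
            continue
        idx = markers.chrom_markers(row.chrom)
        pos = markers.positions()[idx]
        n = int(((pos >= row.start) & (pos <= row.end)).sum())
        rows.append((row.region, row.chrom, row.start, row.end, n, length, 1000.0 * n / length))
    out = pd.DataFrame(
        rows,
        columns=["region", "chrom", "start", "end", "n_snps", "length_bp", "snps_per_kb"],
    )
    out = out.sort_values(
        ["n_snps", "snps_per_kb", "region"], ascending=[False, False, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def promoter_snp_histogram(
    density_table: pd.DataFrame, bins: int | Sequence[float] = 10
) -> pd.DataFrame:
    """Histogram of promoters by SNP count (promoters per bin)."""
    counts, edges = np.histogram(density_table["n_snps"], bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "n_promoters": counts}
    )


# ---------------------------------------------------------------------------
# synonymous / nonsynonymous SNP classification
# ---------------------------------------------------------------------------


def nonsyn_density(
    markers: MarkerMap,
    annotations: AnnotationSet,
    genes: Iterable[str],
) -> pd.DataFrame:
    """Per-gene synonymous/nonsynonymous SNP counts and nonsyn density.

    Each SNP inside a gene's CDS is classified by translating the
    reference and alternate codon under the standard genetic code
    (premature stops count as nonsynonymous).  CDS are assumed
    intronless and contiguous, stored in genome (+ strand) orientation;
    minus-strand genes are reverse-complemented before codon lookup.
    Density is nonsynonymous SNPs per kb of CDS.
    """
    gene_table = annotations.genes.set_index("gene")
    rows = []
    for g in genes:
        if g not in annotations.cds:
            logger.warning("gene %s has no CDS sequence; skipped", g)
            continue
        cds_plus = annotations.cds[g].upper()
        if len(cds_plus) % 3 != 0:
            raise ValueError(f"CDS of {g} not a multiple of 3")
        row = gene_table.loc[g]
        chrom, start, end, strand = row["chrom"], int(row["start"]), int(row["end"]), row["strand"]
        if end - start + 1 != len(cds_plus):
            raise ValueError(f"CDS length of {g} disagrees with its interval")
        idx = markers.chrom_markers(chrom)
        pos = markers.positions()[idx]
        inside = idx[(pos >= start) & (pos <= end)]
        n_syn = n_nonsyn = 0
        for m in inside:
            p = int(markers.positions()[m])
            ref_base = markers.df["allele_a"][m]
            alt_base = markers.df["allele_b"][m]
            # offset within the coding sequence, strand-aware
            if strand == "+":
                off = p - start
                ref, alt = ref_base, alt_base
                seq = cds_plus
            else:
                off = end - p
                ref = str(Seq(ref_base).complement())
                alt = str(Seq(alt_base).complement())
                seq = str(Seq(cds_plus).reverse_complement())
            if seq[off] != ref:
                logger.warning(
                    "gene %s pos %d: CDS base %s != marker allele_a %s; skipped",
                    g, p, seq[off], ref,
                )
                continue
            c0 = 3 * (off // 3)
            codon_ref = seq[c0 : c0 + 3]
            codon_alt = codon_ref[: off % 3] + alt + codon_ref[off % 3 + 1 :]
            if str(Seq(codon_ref).translate()) == str(Seq(codon_alt).translate()):
                n_syn += 1
            else:
                n_nonsyn += 1
        rows.append((g, n_syn, n_nonsyn, len(cds_plus), 1000.0 * n_nonsyn / len(cds_plus)))
    return pd.DataFrame(
        rows, columns=["gene", "n_syn", "n_nonsyn", "cds_len", "nonsyn_per_kb"]
    )


# ---------------------------------------------------------------------------
# CDF statistics
# ---------------------------------------------------------------------------


@dataclass
class DistanceCDF:
    """Distances of a gene subset from an expression line of best fit."""

    distances: pd.Series  # indexed by gene
    ecdf: Callable[[np.ndarray], np.ndarray]
    slope: float
    intercept: float


def bestfit_distance_cdf(
    expr_x: pd.Series,
    expr_y: pd.Series,
    subset: Iterable[str],
    method: str = "ols",
    pseudocount: float = 1.0,
) -> DistanceCDF:
    """Empirical CDF of subset genes' distances from the X~Y best fit.

    The line is fitted on log2(count + pseudocount) of *all* genes (the
    subset is highlighted against the genome-wide trend); each subset
    gene's distance is its absolute vertical OLS residual, or its
    orthogonal (total-least-squares) distance with ``method='orthogonal'``.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset is empty")
    common = expr_x.index.intersection(expr_y.index)
    x = np.log2(expr_x.loc[common].to_numpy(dtype=float) + pseudocount)
    y = np.log2(expr_y.loc[common].to_numpy(dtype=float) + pseudocount)
    if np.allclose(x, x[0]):
        raise ValueError("constant X expression; line of best fit undefined")
    missing = [g for g in subset if g not in common]
    if missing:
        logger.warning("%d subset genes missing from expression tables", len(missing))
    subset = [g for g in subset if g in common]
    loc = pd.Index(common).get_indexer(subset)
    if method == "ols":
        fit = linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        dist_all = np.abs(y - (slope * x + intercept))
    elif method == "orthogonal":
        # total least squares via the principal axis of the centred cloud
        xm, ym = x.mean(), y.mean()
        cov = np.cov(x - xm, y - ym)
        evals, evecs = np.linalg.eigh(cov)
        direction = evecs[:, np.argmax(evals)]
        slope = float(direction[1] / direction[0])
        intercept = float(ym - slope * xm)
        dist_all = np.abs(y - slope * x - intercept) / np.sqrt(1 + slope**2)
    else:
        raise ValueError(f"unknown method {method!r}")
    distances = pd.Series(dist_all[loc], index=subset)
    return DistanceCDF(distances, ECDF(distances.to_numpy()), slope, intercept)


def cumulative_de(
    table: pd.DataFrame,
    comparisons: Sequence[str],
    subset: Iterable[str],
) -> tuple[dict[str, Callable], pd.DataFrame]:
    """Per-comparison empirical CDFs of |log2 fold change| over a subset.

    Returns the ECDF per comparison plus a stochastic-dominance summary:
    for each ordered pair, the signed area between the CDFs, equal to
    the difference of mean |log2FC| (positive when the second comparison
    is right-shifted, i.e. shows larger expression changes).
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset is empty")
    validate_de_table(table)
    mags: dict[str, np.ndarray] = {}
    for comp in comparisons:
        sub = table[table["comparison"] == comp].set_index("gene")
        missing = [g for g in subset if g not in sub.index]
        if missing:
            logger.warning("%d genes missing from %s; excluded", len(missing), comp)
        present = [g for g in subset if g in sub.index]
        if not present:
            raise ValueError(f"no subset genes present in comparison {comp!r}")
        mags[comp] = np.abs(sub.loc[present, "log2fc"].to_numpy(dtype=float))
    ecdfs = {comp: ECDF(v) for comp, v in mags.items()}
    rows = []
    comps = list(comparisons)
    for i, a in enumerate(comps):
        for b in comps[i + 1 :]:
            rows.append((a, b, float(np.mean(mags[b]) - np.mean(mags[a]))))
    summary = pd.DataFrame(rows, columns=["comparison_a", "comparison_b", "signed_area"])
    return ecdfs, summary


def adjust_pvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjustment for tables supplying raw p-values."""
    return multipletests(pvalues, method="fdr_bh")[1]


def write_cdf_tsv(ecdfs: Mapping[str, Callable], path) -> None:
    """Dump ECDF support points (x, F(x)) per comparison as TSV."""
    rows = []
    for comp, f in ecdfs.items():
        xs = np.sort(np.asarray(f.x[1:], dtype=float))  # drop the -inf sentinel
        for x in xs:
            rows.append((comp, x, float(f(x))))
    pd.DataFrame(rows, columns=["comparison", "x", "cdf"]).to_csv(
        path, sep="\t", index=False
    )
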