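"""Seeded end-to-end scenario generation with recorded ground truth.

A scenario emulates the study design of a two-parent yeast cross mapped
by expression-guided bulked segregant analysis: a 16-chromosome genome
with true S. cerevisiae chromosome lengths, a biallelic SNP scaffold at
~1 marker / 2 kb, a single dominant trans-repressor locus on the left
arm of chromosome VIII, seven dissected tetrads (28 segregants) pooled
14 + 14 by expression, pooled sequencing against both parental
references, and differential-expression tables for the seven strain
comparisons with planted factor-dependence structure (including an
extreme on/off transcript whose promoter is the most SNP-dense
intergenic region and carries a TSS-proximal SNP).

Everything is deterministic given the master seed; every stage draws
from its own child stream of that seed.  The ground-truth record (causal
marker, planted gene labels) is always part of the bundle.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cross_sim, pool_sim
from .cross_sim import GeneticMap, PhenotypeModel, Tetrad
from .expr_dependence import COMPARISONS, DE_COLUMNS
from .marker_io import (
    MARKER_COLUMNS,
    REF_A,
    REF_B,
    AlleleCountTable,
    AnnotationSet,
    MarkerMap,
    write_annotation_gff,
    write_counts_tsv,
    write_marker_table,
)

#: S. cerevisiae chromosome lengths (bp), the genome shape being emulated
YEAST_CHROM_LENGTHS: dict[str, int] = {
    "chrI": 230218, "chrII": 813184, "chrIII": 316620, "chrIV": 1531933,
    "chrV": 576874, "chrVI": 270161, "chrVII": 1090940, "chrVIII": 562643,
    "chrIX": 439888, "chrX": 745751, "chrXI": 666816, "chrXII": 1078177,
    "chrXIII": 924431, "chrXIV": 784333, "chrXV": 1091291, "chrXVI": 948066,
}

_BASES = np.array(list("ACGT"))


@dataclass
class ScenarioConfig:
    """All knobs of one synthetic study, with study-shaped defaults."""

    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: dict(YEAST_CHROM_LENGTHS)
    )
    marker_spacing_bp: float = 2000.0  # mean spacing (Poisson process)
    cm_per_kb: float = 0.35
    # causal trans-repressor locus (left arm of chromosome VIII)
    causal_chrom: str = "chrVIII"
    causal_pos: int = 50_000
    repressor_parent: str = "A"
    dominance: str = "dominant"
    base_level: float = 100.0
    # cis context of the expressed locus (promoter of the on/off gene)
    cis_boost: float = 2.0
    cis_parent: str = "A"
    expressed_chrom: str = "chrXII"
    expressed_pos: int = 400_000
    n_promoter_snps: int = 21
    # cross and sequencing
    n_tetrads: int = 7
    coverage: float = 50.0
    error_rate: float = 0.002
    ref_bias: float = 0.05
    fixed_depth: bool = False
    # annotations / DE tables
    include_annotations: bool = True
    include_de: bool = True
    n_genes: int = 6000
    n_wt_de: int = 1207
    n_dependent: int = 822
    n_deletion_only: int = 200
    asym_ratio: float = 3.0  # background-A deletion responders vs background-B
    n_swap_responders: int = 3
    n_extreme: int = 62
    de_padj_max: float = 0.0005
    de_min_mean: float = 100.0
    on_min: float = 100.0
    off_max: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if not self.chromosome_lengths:
            raise ValueError("no chromosomes configured")
        if any(l <= 0 for l in self.chromosome_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.causal_chrom not in self.chromosome_lengths:
            raise ValueError(f"causal chromosome {self.causal_chrom!r} unknown")
        if not 1 <= self.causal_pos <= self.chromosome_lengths[self.causal_chrom]:
            raise ValueError("causal locus beyond chromosome end")
        if self.n_tetrads < 1:
            raise ValueError("n_tetrads must be >= 1")
        if self.include_de:
            if self.n_genes < 1:
                raise ValueError("n_genes must be >= 1")
            if self.n_dependent > self.n_wt_de:
                raise ValueError("n_dependent cannot exceed n_wt_de")
            if self.n_wt_de + self.n_deletion_only > self.n_genes:
                raise ValueError("planted DE sets exceed the gene universe")
            if self.n_extreme > self.n_dependent:
                raise ValueError("n_extreme cannot exceed n_dependent")
            if self.n_swap_responders > self.n_dependent:
                raise ValueError("n_swap_responders cannot exceed n_dependent")


@dataclass
class ScenarioBundle:
    """A fully generated scenario plus its ground truth."""

    config: ScenarioConfig
    marker_map: MarkerMap
    genetic_map: GeneticMap
    annotations: AnnotationSet | None
    tetrads: list[Tetrad]
    phenotypes: list[list[cross_sim.Phenotype]]
    model: PhenotypeModel
    pools: tuple[pool_sim.Pool, pool_sim.Pool]
    counts: dict[str, AlleleCountTable]
    de_table: pd.DataFrame | None
    truth: dict

    @property
    def spores(self) -> list[cross_sim.SegregantGenome]:
        return [s for t in self.tetrads for s in t.spores]


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    # child stream per stage: one master seed, fixed stage offsets
    return np.random.default_rng([seed, stage])


# ---------------------------------------------------------------------------
# marker map and annotations
# ---------------------------------------------------------------------------


def generate_marker_map(
    config: ScenarioConfig,
    rng: np.random.Generator,
    planted: dict[str, list[int]] | None = None,
) -> MarkerMap:
    """Poisson-spaced biallelic markers with order-preserving refB offsets.

    ``planted`` maps chromosome -> extra marker positions to insert
    (e.g. a dense promoter cluster).
    """
    rows = []
    for chrom, length in config.chromosome_lengths.items():
        n_expected = int(length / config.marker_spacing_bp * 1.5) + 10
        gaps = rng.exponential(config.marker_spacing_bp, size=n_expected)
        pos = 1000 + np.cumsum(gaps).astype(np.int64)
        pos = pos[pos <= length - 1000]
        if planted and chrom in planted:
            pos = np.concatenate([pos, np.asarray(planted[chrom], dtype=np.int64)])
        pos = np.unique(pos)
        offset = int(rng.integers(-500, 501))
        ref = rng.integers(0, 4, size=pos.size)
        alt = (ref + rng.integers(1, 4, size=pos.size)) % 4
        for p, r, a in zip(pos, ref, alt):
            rows.append((chrom, int(p), chrom, int(p) + offset, _BASES[r], _BASES[a]))
    df = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    lengths = {
        REF_A: dict(config.chromosome_lengths),
        REF_B: {c: l + 500 for c, l in config.chromosome_lengths.items()},
    }
    return MarkerMap(df, genome_lengths=lengths)


def generate_annotations(
    config: ScenarioConfig, rng: np.random.Generator
) -> AnnotationSet:
    """Tile intronless genes (999-bp CDS) separated by intergenic gaps."""
    gene_len, gap = 999, 500
    gene_rows, ig_rows, cds = [], [], {}
    gid = 0
    for chrom, length in config.chromosome_lengths.items():
        cursor = 1 + gap
        prev_gene = ""
        while cursor + gene_len - 1 <= length - gap and gid < config.n_genes:
            name = f"g{gid:05d}"
            start, end = cursor, cursor + gene_len - 1
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end
            gene_rows.append((name, chrom, start, end, strand, tss))
            ig_rows.append(
                (f"ig_{name}", chrom, start - gap, start - 1, prev_gene, name)
            )
            seq = "".join(_BASES[rng.integers(0, 4, size=gene_len)])
            cds[name] = seq
            prev_gene = name
            gid += 1
            cursor = end + 1 + gap
        if gid >= config.n_genes:
            break
    genes = pd.DataFrame(
        gene_rows, columns=["gene", "chrom", "start", "end", "strand", "tss"]
    )
    intergenic = pd.DataFrame(
        ig_rows, columns=["region", "chrom", "start", "end", "left_gene", "right_gene"]
    )
    return AnnotationSet(genes=genes, intergenic=intergenic, cds=cds)


def _nearest_gene(annotations: AnnotationSet, chrom: str, pos: int) -> pd.Series:
    sub = annotations.genes[annotations.genes["chrom"] == chrom]
    if sub.empty:
        raise ValueError(f"no genes on {chrom}")
    i = (sub["start"] - pos).abs().idxmin()
    return annotations.genes.loc[i]


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------


def generate_de_tables(
    config: ScenarioConfig,
    truth_labels: dict[str, set],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Seven-comparison DE tables realising planted dependence labels.

    Planted DE genes receive Padj ~ padj_max * Beta(2, 8) (well below
    threshold) and condition means bounded away from the min-mean
    filter; everything else receives Padj above threshold.  Dependent
    genes are DE between wildtypes but not between deletions; the
    deletion response is asymmetric between backgrounds (all dependent
    genes respond to the background-A deletion, a 1/asym_ratio subset to
    the background-B deletion); only the swap responders shift upon
    allele interconversion.
    """
    genes = sorted(truth_labels["universe"])
    dependent = truth_labels["dependent"]
    overlap = truth_labels["overlap"]
    deletion_only = truth_labels["deletion_only"]
    extreme = truth_labels.get("extreme", set())
    extreme_on_in_b = truth_labels.get("extreme_on_in_b", set())
    swap = truth_labels.get("swap_responders", set())
    responders_b = truth_labels.get("responders_b", set())
    if dependent & deletion_only or overlap & deletion_only:
        raise ValueError("contradictory planted labels")

    de_sets = {
        "wtA_vs_wtB": dependent | overlap,
        "delA_vs_delB": overlap | deletion_only,
        "wtA_vs_delA": set(dependent),
        "wtB_vs_delB": set(responders_b),
        "wtA_vs_swapA": set(swap),
        "wtB_vs_swapB": set(swap),
        "swapA_vs_swapB": (dependent | overlap) - swap,
    }

    n = len(genes)
    base = np.exp(rng.normal(np.log(300.0), 1.0, size=n))
    gene_index = {g: i for i, g in enumerate(genes)}
    frames = []
    for comp in COMPARISONS:
        de = de_sets[comp]
        is_de = np.array([g in de for g in genes])
        lfc = rng.normal(0.0, 0.05, size=n)
        sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        lfc = np.where(is_de, sign * (1.0 + np.exp(rng.normal(0.0, 0.5, size=n))), lfc)
        mean_a = base.copy()
        # keep planted DE genes clear of the min-mean filter
        floor = config.de_min_mean + np.exp(rng.normal(np.log(150.0), 0.5, size=n))
        mean_a = np.where(is_de, np.maximum(mean_a, floor), mean_a)
        mean_b = mean_a * np.power(2.0, lfc)
        # the filter uses the average: lift mean_a so min(mean) >= floor
        mean_a = np.where(is_de & (mean_b < floor), mean_a * floor / mean_b, mean_a)
        mean_b = mean_a * np.power(2.0, lfc)
        padj = np.where(
            is_de,
            config.de_padj_max * rng.beta(2.0, 8.0, size=n),
            config.de_padj_max + (1 - config.de_padj_max) * rng.beta(2.0, 2.0, size=n),
        )
        if comp == "wtA_vs_wtB" and extreme:
            # extreme expressors: off in one strain, on in the other
            for g in extreme:
                i = gene_index[g]
                lo = float(rng.uniform(0.0, config.off_max * 0.5))
                hi = float(
                    config.on_min * 2 + np.exp(rng.normal(np.log(200.0), 0.5))
                )
                if g in extreme_on_in_b:
                    mean_a[i], mean_b[i] = lo, hi
                else:
                    mean_a[i], mean_b[i] = hi, lo
                with np.errstate(divide="ignore"):
                    lfc[i] = np.log2((mean_b[i] + 1) / (mean_a[i] + 1))
        frames.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "comparison": comp,
                    "mean_a": mean_a,
                    "mean_b": mean_b,
                    "log2fc": lfc,
                    "padj": padj,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[DE_COLUMNS]


def _plant_gene_labels(config: ScenarioConfig, rng: np.random.Generator) -> dict:
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    perm = rng.permutation(config.n_genes)
    dependent = {genes[i] for i in perm[: config.n_dependent]}
    overlap = {
        genes[i] for i in perm[config.n_dependent : config.n_wt_de]
    }
    deletion_only = {
        genes[i]
        for i in perm[config.n_wt_de : config.n_wt_de + config.n_deletion_only]
    }
    dep_sorted = sorted(dependent)
    extreme = set(dep_sorted[: config.n_extreme])
    extreme_on_in_b = set(sorted(extreme)[: (config.n_extreme + 1) // 2])
    swap = set(dep_sorted[: config.n_swap_responders])
    n_resp_b = int(round(config.n_dependent / config.asym_ratio))
    responders_b = set(dep_sorted[:n_resp_b])
    return {
        "universe": set(genes),
        "dependent": dependent,
        "overlap": overlap,
        "deletion_only": deletion_only,
        "extreme": extreme,
        "extreme_on_in_b": extreme_on_in_b,
        "swap_responders": swap,
        "responders_b": responders_b,
    }


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------


def generate_scenario(config: ScenarioConfig | None = None) -> ScenarioBundle:
    """Generate a complete, internally consistent scenario bundle."""
    config = config or ScenarioConfig()
    config.validate()
    seed = config.seed

    annotations = None
    planted: dict[str, list[int]] = {}
    aqy2_like = None
    promoter: tuple[str, int, int] | None = None
    if config.include_annotations:
        annotations = generate_annotations(config, _stage_rng(seed, 1))
        # the expressed on/off locus: most SNP-dense promoter + TSS SNP
        gene = _nearest_gene(annotations, config.expressed_chrom, config.expressed_pos)
        aqy2_like = gene["gene"]
        ig = annotations.intergenic
        row = ig[ig["right_gene"] == aqy2_like].iloc[0]
        promoter = (row["chrom"], int(row["start"]), int(row["end"]))
        rng_p = _stage_rng(seed, 2)
        span = np.arange(promoter[1], promoter[2] + 1)
        n_plant = min(config.n_promoter_snps, span.size)
        pos = rng_p.choice(span, size=n_plant, replace=False)
        pos = set(int(p) for p in pos)
        pos.add(int(gene["tss"]))  # a SNP within 50 bp of the TSS
        planted[promoter[0]] = sorted(pos)

    marker_map = generate_marker_map(config, _stage_rng(seed, 3), planted)

    # causal marker: the marker nearest the configured locus
    idx = marker_map.chrom_markers(config.causal_chrom)
    pos_all = marker_map.positions()
    causal_marker = int(idx[np.argmin(np.abs(pos_all[idx] - config.causal_pos))])

    cis_region = None
    if promoter is not None:
        pid = marker_map.chrom_markers(promoter[0])
        in_prom = pid[(pos_all[pid] >= promoter[1]) & (pos_all[pid] <= promoter[2])]
        if in_prom.size:
            cis_region = (int(in_prom.min()), int(in_prom.max()))

    model = PhenotypeModel(
        causal_marker=causal_marker,
        repressor_parent=config.repressor_parent,
        dominance=config.dominance,
        base_level=config.base_level,
        cis_region=cis_region,
        cis_parent=config.cis_parent,
        cis_boost=config.cis_boost,
    )

    gmap = GeneticMap(cm_per_kb=config.cm_per_kb)
    tetrads = cross_sim.simulate_cross(
        marker_map, gmap, config.n_tetrads, _stage_rng(seed, 4)
    )
    phenotypes = cross_sim.phenotype_cross(tetrads, model)
    spores = [s for t in tetrads for s in t.spores]
    flat_phen = [p for tet in phenotypes for p in tet]
    pools = pool_sim.pool_by_phenotype(list(range(len(spores))), flat_phen)

    seq_model = pool_sim.SeqModel(
        coverage=config.coverage,
        error_rate=config.error_rate,
        ref_bias=config.ref_bias,
        fixed_depth=config.fixed_depth,
    )
    counts = {
        REF_A: pool_sim.simulate_pool_counts(
            pools, marker_map, spores, seq_model, REF_A, _stage_rng(seed, 5)
        ),
        REF_B: pool_sim.simulate_pool_counts(
            pools, marker_map, spores, seq_model, REF_B, _stage_rng(seed, 6)
        ),
    }

    de_table = None
    truth: dict = {
        "causal_marker": causal_marker,
        "causal_chrom": config.causal_chrom,
        "causal_pos": int(pos_all[causal_marker]),
        "repressor_parent": config.repressor_parent,
        "n_expressing": len(pools[0].members),
        "n_non_expressing": len(pools[1].members),
    }
    if config.include_de:
        labels = _plant_gene_labels(config, _stage_rng(seed, 7))
        de_table = generate_de_tables(config, labels, _stage_rng(seed, 8))
        truth.update(
            {k: sorted(v) for k, v in labels.items() if k != "universe"}
        )
        truth["n_genes"] = config.n_genes
    if aqy2_like is not None:
        truth["expressed_gene"] = aqy2_like
        truth["promoter"] = list(promoter)

    return ScenarioBundle(
        config=config,
        marker_map=marker_map,
        genetic_map=gmap,
        annotations=annotations,
        tetrads=tetrads,
        phenotypes=phenotypes,
        model=model,
        pools=pools,
        counts=counts,
        de_table=de_table,
        truth=truth,
    )


def write_bundle(bundle: ScenarioBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle component as flat text files plus truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["markers"] = write_marker_table(
        bundle.marker_map, outdir / "markers.tsv", "tsv"
    )
    paths["markers_vcf"] = write_marker_table(
        bundle.marker_map, outdir / "markers.vcf", "vcf"
    )
    paths["genotypes"] = cross_sim.write_genotypes_tsv(
        bundle.tetrads, bundle.marker_map, outdir / "genotypes.tsv"
    )
    paths["phenotypes"] = cross_sim.write_phenotypes_tsv(
        bundle.phenotypes, outdir / "phenotypes.tsv"
    )
    for ref, counts in bundle.counts.items():
        paths[f"counts_{ref}"] = write_counts_tsv(
            counts, outdir / f"counts_{ref}.tsv"
        )
    if bundle.annotations is not None:
        paths["annotations"] = write_annotation_gff(
            bundle.annotations, outdir / "annotations.gff3"
        )
    if bundle.de_table is not None:
        p = outdir / "de_tables.tsv"
        bundle.de_table.to_csv(p, sep="\t", index=False)
        paths["de_tables"] = p
    cfg = asdict(bundle.config)
    truth_path = outdir / "ground_truth.json"
    with open(truth_path, "w") as fh:
        json.dump({"config": cfg, "truth": bundle.truth}, fh, indent=1, sort_keys=True)
    paths["ground_truth"] = truth_path
    return paths
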