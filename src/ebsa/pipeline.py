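"""End-to-end orchestration: pooled mapping run and dependence run.

Stages hand off through flat TSV/BED/JSON files so each is runnable and
inspectable on its own; a JSON manifest records the config snapshot,
seeds, SHA-256 checksums of every output, stage timings and library
versions for reproducibility audits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .af_scan import AFProfile, compute_af, call_concordant_regions, write_af_tsv
from .expr_dependence import (
    COMPARISONS,
    bestfit_distance_cdf,
    call_de,
    cumulative_de,
    dependence_classes,
    write_cdf_tsv,
)
from .marker_io import (
    REF_A,
    REF_B,
    read_counts_tsv,
    read_marker_table,
    write_regions_bed,
)
from .pool_sim import EXPRESSING, NON_EXPRESSING, pool_by_phenotype
from .segregation_stats import tetrad_segregation_test, write_report_tsv
from .synthetic_data import ScenarioConfig, ScenarioBundle, generate_scenario

logger = logging.getLogger("ebsa")


@dataclass
class ScanParams:
    min_depth: int = 10
    epsilon: float = 0.02
    min_snps: int = 2
    max_gap: int = 2


@dataclass
class DependenceParams:
    padj_max: float = 0.0005
    min_mean: float = 100.0
    wt_comparison: str = "wtA_vs_wtB"
    del_comparison: str = "delA_vs_delB"


@dataclass
class RunConfig:
    """One pipeline run: a synthetic scenario or user-supplied files."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    inputs: dict[str, str] = field(default_factory=dict)
    scan: ScanParams = field(default_factory=ScanParams)
    dependence: DependenceParams = field(default_factory=DependenceParams)
    outdir: str = "ebsa_out"


def load_config(path: str | Path | None, seed: int | None = None) -> RunConfig:
    """Load a YAML run config; missing keys fall back to defaults."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(
        scenario=ScenarioConfig(**raw.get("scenario", {})),
        inputs=raw.get("inputs", {}) or {},
        scan=ScanParams(**raw.get("scan", {})),
        dependence=DependenceParams(**raw.get("dependence", {})),
        outdir=raw.get("outdir", "ebsa_out"),
    )
    if seed is None:
        seed = raw.get("seed")
    if seed is not None:
        cfg.scenario.seed = int(seed)
    return cfg


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    outputs: dict[str, dict]  # name -> {path, sha256}
    timings: dict[str, float]
    versions: dict[str, str]

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
        return path


def _manifest(config: RunConfig, outputs: dict[str, Path], timings: dict) -> RunManifest:
    return RunManifest(
        config=dataclasses.asdict(config),
        seed=config.scenario.seed,
        outputs={
            name: {"path": str(p), "sha256": _sha256(p)} for name, p in outputs.items()
        },
        timings={k: round(v, 6) for k, v in timings.items()},
        versions={
            "ebsa": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    )


class _Timer:
    def __init__(self) -> None:
        self.timings: dict[str, float] = {}

    def stage(self, name: str):
        timer = self

        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("[%s] start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timer.timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    logger.error("[%s] failed: %s", name, exc)
                else:
                    logger.info("[%s] done (%.2fs)", name, timer.timings[name])
                return False

        return _Ctx()


# ---------------------------------------------------------------------------
# eBSA run
# ---------------------------------------------------------------------------


@dataclass
class EbsaResult:
    regions: list
    report: object
    manifest: RunManifest
    bundle: ScenarioBundle | None = None


def run_ebsa(config: RunConfig, outdir: str | Path | None = None) -> EbsaResult:
    """Pool by phenotype, quantify allele frequencies, call the region.

    With no ``inputs`` the scenario generator supplies the cross; with
    user files (``markers``, ``counts_refA``/``counts_refB`` and
    ``phenotypes``, where consecutive groups of four phenotype rows form
    one tetrad) the same stages run on real data.
    """
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timer = _Timer()
    outputs: dict[str, Path] = {}

    bundle = None
    causal = None
    if config.inputs:
        with timer.stage("ingest"):
            marker_map = read_marker_table(config.inputs["markers"], "tsv")
            counts = {}
            for ref, key in ((REF_A, "counts_refA"), (REF_B, "counts_refB")):
                if key in config.inputs:
                    counts[ref] = read_counts_tsv(config.inputs[key])
            if not counts:
                raise ValueError("no count tables supplied")
            phen = pd.read_csv(config.inputs["phenotypes"], sep="\t")
            states = list(phen["state"])
            tetrad_states = [states[i : i + 4] for i in range(0, len(states), 4)]
    else:
        with timer.stage("generate"):
            bundle = generate_scenario(config.scenario)
            marker_map = bundle.marker_map
            counts = bundle.counts
            tetrad_states = [[p.state for p in tet] for tet in bundle.phenotypes]
            states = [s for tet in tetrad_states for s in tet]
            causal = bundle.truth["causal_marker"]

    with timer.stage("pool"):
        pools = pool_by_phenotype(list(range(len(states))), states)
        logger.info(
            "pools: %d expressing, %d non-expressing",
            len(pools[0].members), len(pools[1].members),
        )

    with timer.stage("af"):
        frames = [
            compute_af(tab, min_depth=config.scan.min_depth).df
            for tab in counts.values()
        ]
        profile = AFProfile(pd.concat(frames, ignore_index=True))
        af_expr = profile.select(EXPRESSING)
        af_nonexpr = profile.select(NON_EXPRESSING)
        outputs["af"] = write_af_tsv(profile, outdir / "allele_frequencies.tsv")

    with timer.stage("scan"):
        regions = call_concordant_regions(
            af_expr,
            af_nonexpr,
            marker_map,
            repressor_parent=config.scenario.repressor_parent,
            epsilon=config.scan.epsilon,
            min_snps=config.scan.min_snps,
            max_gap=config.scan.max_gap,
            causal_marker=causal,
        )
        outputs["regions"] = write_regions_bed(regions, outdir / "regions.bed")
        for r in regions:
            logger.info(
                "region %s:%d-%d (%d SNPs, %.1f kb)",
                r.chrom, r.start, r.end, r.n_markers, r.length / 1000,
            )

    with timer.stage("segtest"):
        report = tetrad_segregation_test(tetrad_states)
        outputs["segregation"] = write_report_tsv(report, outdir / "segregation.tsv")

    manifest = _manifest(config, outputs, timer.timings)
    outputs["manifest"] = manifest.write(outdir / "manifest.json")
    return EbsaResult(regions=regions, report=report, manifest=manifest, bundle=bundle)


# ---------------------------------------------------------------------------
# dependence run
# ---------------------------------------------------------------------------


@dataclass
class DependenceResult:
    classes: object
    de_wt: set
    de_del: set
    manifest: RunManifest


def run_dependence(config: RunConfig, outdir: str | Path | None = None) -> DependenceResult:
    """Threshold DE calls, classify dependence, emit CDF summaries."""
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timer = _Timer()
    outputs: dict[str, Path] = {}

    with timer.stage("load_de"):
        if "de_tables" in config.inputs:
            table = pd.read_csv(config.inputs["de_tables"], sep="\t")
        else:
            bundle = generate_scenario(config.scenario)
            if bundle.de_table is None:
                raise ValueError("scenario generated without DE tables")
            table = bundle.de_table

    dep = config.dependence
    with timer.stage("call_de"):
        universe = set(table["gene"])
        de_wt = call_de(table, dep.wt_comparison, dep.padj_max, dep.min_mean)
        de_del = call_de(table, dep.del_comparison, dep.padj_max, dep.min_mean)

    with timer.stage("classify"):
        classes = dependence_classes(de_wt, de_del, universe)
        p = outdir / "dependence_classes.tsv"
        classes.to_frame().to_csv(p, sep="\t", index=False)
        outputs["classes"] = p
        logger.info("dependence counts: %s", classes.counts)

    with timer.stage("cdf"):
        if classes.dependent:
            wt = table[table["comparison"] == dep.wt_comparison].set_index("gene")
            dist = bestfit_distance_cdf(
                wt["mean_a"], wt["mean_b"], sorted(classes.dependent)
            )
            p = outdir / "bestfit_distances.tsv"
            dist.distances.rename("distance").to_frame().to_csv(p, sep="\t")
            outputs["distances"] = p
            comps = [c for c in COMPARISONS if c in set(table["comparison"])]
            ecdfs, summary = cumulative_de(table, comps, sorted(classes.dependent))
            p = outdir / "cumulative_de_cdf.tsv"
            write_cdf_tsv(ecdfs, p)
            outputs["cdf"] = p
            p = outdir / "cdf_shift_summary.tsv"
            summary.to_csv(p, sep="\t", index=False)
            outputs["cdf_summary"] = p
        else:
            logger.warning("dependent set empty; CDF stage skipped")

    manifest = _manifest(config, outputs, timer.timings)
    outputs["manifest"] = manifest.write(outdir / "dependence_manifest.json")
    return DependenceResult(
        classes=classes, de_wt=de_wt, de_del=de_del, manifest=manifest
    )
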