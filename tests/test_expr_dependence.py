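"""DE thresholding, dependence set logic, variant and CDF analytics."""

import numpy as np
import pandas as pd
import pytest

from ebsa.expr_dependence import (
    BOTH_OFF,
    BOTH_ON,
    ON_IN_A,
    ON_IN_B,
    adjust_pvalues,
    bestfit_distance_cdf,
    call_de,
    classify_on_off,
    cumulative_de,
    dependence_classes,
    nonsyn_density,
    on_off_sweep,
    on_off_table,
    promoter_snp_density,
    snp_near_tss,
)
from ebsa.marker_io import MARKER_COLUMNS, AnnotationSet, MarkerMap

from conftest import make_map

# independent oracle: hand-written standard genetic code
CODON_TABLE = {}
_bases = "TCAG"
_aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_b1, _b2, _b3) in enumerate(
    (b1, b2, b3) for b1 in _bases for b2 in _bases for b3 in _bases
):
    CODON_TABLE[_b1 + _b2 + _b3] = _aas[_i]


def de_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene", "comparison", "mean_a", "mean_b", "log2fc", "padj"]
    )


class TestCallDE:
    @pytest.mark.parametrize(
        "padj,mean_a,mean_b,included",
        [
            (0.0004, 150, 150, True),
            (0.0004, 50, 50, False),    # below the mean filter
            (0.0006, 150, 150, False),  # above the padj cutoff
            (0.0005, 100, 100, True),   # inclusive boundaries
            (0.0004, 30, 180, True),    # the filter uses the average
        ],
    )
    def test_threshold_rule(self, padj, mean_a, mean_b, included):
        table = de_frame([["g1", "wtA_vs_wtB", mean_a, mean_b, 1.0, padj]])
        hit = call_de(table, "wtA_vs_wtB", padj_max=0.0005, min_mean=100)
        assert ("g1" in hit) == included

    def test_missing_comparison_lists_available(self):
        table = de_frame([["g1", "wtA_vs_wtB", 10, 10, 0, 0.5]])
        with pytest.raises(ValueError, match="delA_vs_delB"):
            call_de(table, "delA_vs_delB")

    def test_threshold_sweep_is_monotone(self):
        rng = np.random.default_rng(0)
        table = de_frame(
            [[f"g{i}", "wtA_vs_wtB", 200, 200, 0.0, rng.uniform()] for i in range(200)]
        )
        sizes = [
            len(call_de(table, "wtA_vs_wtB", padj_max=p, min_mean=0))
            for p in (0.5, 0.1, 0.01, 0.001)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestDependenceClasses:
    def test_printed_sizes(self):
        # 1207 wildtype-DE genes with 385 also DE between deletions
        universe = {f"g{i}" for i in range(2000)}
        genes = sorted(universe)
        de_wt = set(genes[:1207])
        de_del = set(genes[822:1207]) | set(genes[1500:1600])
        classes = dependence_classes(de_wt, de_del, universe)
        assert len(de_wt & de_del) == 385
        assert len(classes.dependent) == 822

    def test_empty_wt_set(self):
        classes = dependence_classes(set(), {"g1"}, {"g1", "g2"})
        assert classes.dependent == set()
        assert classes.deletion_only == {"g1"}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_membership(self, seed):
        rng = np.random.default_rng(seed)
        universe = {f"g{i}" for i in range(150)}
        de_wt = {g for g in universe if rng.random() < 0.3}
        de_del = {g for g in universe if rng.random() < 0.3}
        classes = dependence_classes(de_wt, de_del, universe)
        for g in universe:  # brute-force label per gene
            if g in de_wt and g not in de_del:
                expected = "dependent"
            elif g in de_del and g not in de_wt:
                expected = "deletion_only"
            else:
                expected = "independent"
            assert classes.label_of(g) == expected
        # partition + the Venn identity |dependent| + |overlap| = |de_wt|
        assert len(classes.dependent) + len(de_wt & de_del) == len(de_wt)
        total = classes.dependent | classes.deletion_only | classes.independent
        assert total == universe
        assert not classes.dependent & classes.deletion_only

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            dependence_classes({"x"}, set(), {"g1"})


class TestOnOff:
    @pytest.mark.parametrize(
        "a,b,state",
        [
            (500, 3, ON_IN_A),
            (3, 500, ON_IN_B),
            (0, 0, BOTH_OFF),
            (500, 500, BOTH_ON),
            (50, 3, BOTH_ON),   # intermediate level: not an extreme expressor
            (100, 10, ON_IN_A),  # inclusive thresholds
        ],
    )
    def test_four_way_rule(self, a, b, state):
        assert classify_on_off(a, b, on_min=100, off_max=10).state == state

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError, match="on_min"):
            classify_on_off(1, 1, on_min=5, off_max=10)

    def test_sweep_counts_extremes(self):
        expr = pd.DataFrame(
            {"gene": ["a", "b", "c"], "expr_a": [500, 0, 300], "expr_b": [2, 0, 400]}
        )
        sweep = on_off_sweep(expr, on_grid=[100, 400], off_grid=[5, 50])
        row = sweep[(sweep.on_min == 100) & (sweep.off_max == 5)].iloc[0]
        assert row.n_extreme == 1


class TestTssSnps:
    def _ann(self):
        genes = pd.DataFrame(
            {
                "gene": ["g1", "g2", "g3"],
                "chrom": ["chr1"] * 3,
                "start": [1000, 3000, 5000],
                "end": [1999, 3999, 5999],
                "strand": ["+", "+", "-"],
                "tss": [1000, 3000, 5999],
            }
        )
        return AnnotationSet(genes=genes)

    def test_window_inclusive_both_sides(self):
        ann = self._ann()
        m = make_map({"chr1": [960, 3050, 7000]})
        # 1000-960 = 40 <= 50 counted; 3050-3000 = 50 exactly counted
        assert snp_near_tss(m, ann, ["g1"], window=50) == 1.0
        assert snp_near_tss(m, ann, ["g2"], window=50) == 1.0
        assert snp_near_tss(m, ann, ["g3"], window=50) == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_fraction_matches_pairwise_scan(self, seed):
        rng = np.random.default_rng(seed)
        starts = np.arange(1000, 41_000, 2000)
        genes = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(len(starts))],
                "chrom": "chr1",
                "start": starts,
                "end": starts + 999,
                "strand": "+",
                "tss": starts,
            }
        )
        ann = AnnotationSet(genes=genes)
        m = make_map({"chr1": sorted(rng.choice(range(500, 45_000), 60, replace=False).tolist())})
        names = list(genes["gene"])
        got = snp_near_tss(m, ann, names, window=50)
        pos = m.positions()
        want = np.mean(
            [any(abs(int(t) - p) <= 50 for p in pos) for t in genes["tss"]]
        )
        assert got == pytest.approx(want)


class TestPromoterDensity:
    def _regions(self, spans):
        return AnnotationSet(
            genes=pd.DataFrame(
                columns=["gene", "chrom", "start", "end", "strand", "tss"]
            ),
            intergenic=pd.DataFrame(
                [(f"ig{i}", "chr1", s, e, "", "") for i, (s, e) in enumerate(spans)],
                columns=["region", "chrom", "start", "end", "left_gene", "right_gene"],
            ),
        )

    def test_densest_promoter_ranks_first(self):
        # one region with 21 SNPs, others sparse
        dense = list(range(10_000, 10_420, 20))  # 21 SNPs
        sparse = [30_000, 30_100, 50_000]
        m = make_map({"chr1": sorted(dense + sparse)})
        ann = self._regions([(9_900, 10_500), (29_000, 31_000), (49_000, 51_000)])
        table = promoter_snp_density(m, ann)
        assert table.iloc[0]["region"] == "ig0"
        assert table.iloc[0]["n_snps"] == 21
        assert table.iloc[0]["rank"] == 1

    def test_zero_snp_region_ranks_last(self):
        m = make_map({"chr1": [10_000]})
        ann = self._regions([(9_000, 11_000), (20_000, 21_000)])
        table = promoter_snp_density(m, ann)
        last = table.iloc[-1]
        assert last["n_snps"] == 0 and last["snps_per_kb"] == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_counts_match_interval_overlap_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        positions = sorted(rng.choice(range(1, 100_000), 200, replace=False).tolist())
        m = make_map({"chr1": positions})
        spans = []
        cursor = 1
        for _ in range(15):
            start = cursor + int(rng.integers(0, 2000))
            end = start + int(rng.integers(100, 5000))
            spans.append((start, end))
            cursor = end + 1
        ann = self._regions(spans)
        table = promoter_snp_density(m, ann).set_index("region")
        for i, (s, e) in enumerate(spans):
            want = sum(s <= p <= e for p in positions)
            assert table.loc[f"ig{i}", "n_snps"] == want

    def test_zero_length_region_excluded(self, caplog):
        m = make_map({"chr1": [100]})
        ann = self._regions([(5, 5), (50, 200)])
        # a 1 bp region has positive length; force degenerate via end<start guard
        ann.intergenic.loc[0, "end"] = 4
        ann.intergenic.loc[0, "start"] = 5
        with caplog.at_level("WARNING", logger="ebsa"):
            table = promoter_snp_density(m, ann)
        assert "excluded" in caplog.text and len(table) == 1


def _gene_annotation(chrom, start, cds, strand="+"):
    end = start + len(cds) - 1
    genes = pd.DataFrame(
        {
            "gene": ["g1"],
            "chrom": [chrom],
            "start": [start],
            "end": [end],
            "strand": [strand],
            "tss": [start if strand == "+" else end],
        }
    )
    return AnnotationSet(genes=genes, cds={"g1": cds})


def _snp_map(chrom, snps):
    rows = [(chrom, p, chrom, p, ref, alt) for p, ref, alt in snps]
    df = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    return MarkerMap(df)


class TestNonsynDensity:
    def test_wobble_change_is_synonymous(self):
        ann = _gene_annotation("chr1", 1001, "AAAGGG")
        m = _snp_map("chr1", [(1003, "A", "G")])  # AAA -> AAG, Lys -> Lys
        out = nonsyn_density(m, ann, ["g1"]).iloc[0]
        assert (out.n_syn, out.n_nonsyn) == (1, 0)

    def test_second_position_change_is_nonsynonymous(self):
        ann = _gene_annotation("chr1", 1001, "AAAGGG")
        m = _snp_map("chr1", [(1002, "A", "C")])  # AAA -> ACA, Lys -> Thr
        out = nonsyn_density(m, ann, ["g1"]).iloc[0]
        assert (out.n_syn, out.n_nonsyn) == (0, 1)

    def test_minus_strand_codon_lookup(self):
        # genome + strand 'TTT'; mRNA is AAA (Lys); genomic T>G at the
        # gene end hits the first codon base: AAA -> CAA, Lys -> Gln
        ann = _gene_annotation("chr1", 1001, "TTT", strand="-")
        m = _snp_map("chr1", [(1003, "T", "G")])
        out = nonsyn_density(m, ann, ["g1"]).iloc[0]
        assert (out.n_syn, out.n_nonsyn) == (0, 1)

    def test_variable_regulator_fixture_five_syn_thirteen_nonsyn(self):
        # an 18-SNP coding gene where 13 SNPs change the protein:
        # five third-position wobble changes, thirteen first/second-
        # position changes, one SNP per codon over an 18-codon CDS
        syn = [("CTT", "CTC", 2), ("GGA", "GGG", 2), ("TCT", "TCC", 2),
               ("ACA", "ACG", 2), ("GTT", "GTA", 2)]
        nonsyn = [("AAA", "CAA", 0), ("GAA", "GTA", 1), ("TGT", "AGT", 0),
                  ("CAT", "CGT", 1), ("ATG", "CTG", 0), ("TTC", "TCC", 1),
                  ("AAC", "GAC", 0), ("CCA", "CAA", 1), ("GAT", "TAT", 0),
                  ("AGA", "ATA", 1), ("TAC", "GAC", 0), ("GCA", "GAA", 1),
                  ("TGG", "TAG", 1)]  # includes a premature stop
        codons = syn + nonsyn
        cds = "".join(ref for ref, _, _ in codons)
        start = 2001
        snps = []
        for i, (ref, alt, off) in enumerate(codons):
            pos = start + 3 * i + off
            snps.append((pos, ref[off], alt[off]))
        ann = _gene_annotation("chr1", start, cds)
        m = _snp_map("chr1", snps)
        out = nonsyn_density(m, ann, ["g1"]).iloc[0]
        assert (out.n_syn, out.n_nonsyn) == (5, 13)
        assert out.nonsyn_per_kb == pytest.approx(13 / (len(cds) / 1000))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_codon_oracle_on_random_cds(self, seed):
        rng = np.random.default_rng(seed)
        n_codons = 30
        cds = "".join(rng.choice(list("ACGT"), 3 * n_codons))
        start = 5001
        snps, expected_syn, expected_nonsyn = [], 0, 0
        for pos0 in sorted(rng.choice(range(3 * n_codons), 12, replace=False).tolist()):
            ref = cds[pos0]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            snps.append((start + pos0, ref, alt))
            c0 = 3 * (pos0 // 3)
            codon_ref = cds[c0 : c0 + 3]
            codon_alt = codon_ref[: pos0 % 3] + alt + codon_ref[pos0 % 3 + 1 :]
            if CODON_TABLE[codon_ref] == CODON_TABLE[codon_alt]:
                expected_syn += 1
            else:
                expected_nonsyn += 1
        ann = _gene_annotation("chr1", start, cds)
        m = _snp_map("chr1", snps)
        out = nonsyn_density(m, ann, ["g1"]).iloc[0]
        assert (out.n_syn, out.n_nonsyn) == (expected_syn, expected_nonsyn)


class TestBestFitDistances:
    def test_perfect_fit_gives_zero_distances(self):
        genes = [f"g{i}" for i in range(20)]
        x = pd.Series(np.linspace(10, 1000, 20), index=genes)
        result = bestfit_distance_cdf(x, x, genes[:5])
        assert np.allclose(result.distances, 0.0)
        assert result.ecdf(0.0) == 1.0

    def test_residuals_match_normal_equations(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(10)]
        x = pd.Series(rng.uniform(5, 2000, 10), index=genes)
        y = pd.Series(rng.uniform(5, 2000, 10), index=genes)
        result = bestfit_distance_cdf(x, y, genes)
        lx, ly = np.log2(x.to_numpy() + 1), np.log2(y.to_numpy() + 1)
        slope = ((lx - lx.mean()) * (ly - ly.mean())).sum() / ((lx - lx.mean()) ** 2).sum()
        intercept = ly.mean() - slope * lx.mean()
        want = np.abs(ly - (slope * lx + intercept))
        np.testing.assert_allclose(result.distances.to_numpy(), want, rtol=1e-9)

    def test_ecdf_is_monotone_to_one(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(50)]
        x = pd.Series(rng.uniform(1, 500, 50), index=genes)
        y = pd.Series(rng.uniform(1, 500, 50), index=genes)
        result = bestfit_distance_cdf(x, y, genes)
        grid = np.linspace(0, result.distances.max(), 100)
        vals = result.ecdf(grid)
        assert (np.diff(vals) >= 0).all()
        assert result.ecdf(result.distances.max()) == 1.0

    def test_orthogonal_distances_not_larger_than_vertical(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(40)]
        x = pd.Series(rng.uniform(1, 500, 40), index=genes)
        y = pd.Series(2 * x.to_numpy() + rng.normal(0, 20, 40).clip(-0.5), index=genes)
        ols = bestfit_distance_cdf(x, y, genes, method="ols")
        orth = bestfit_distance_cdf(x, y, genes, method="orthogonal")
        assert orth.distances.mean() <= ols.distances.mean() * 1.05

    def test_constant_x_rejected(self):
        genes = ["a", "b", "c"]
        x = pd.Series([7.0, 7.0, 7.0], index=genes)
        y = pd.Series([1.0, 2.0, 3.0], index=genes)
        with pytest.raises(ValueError, match="constant"):
            bestfit_distance_cdf(x, y, genes)


class TestCumulativeDE:
    def _table(self, lfcs_by_comp):
        rows = []
        for comp, lfcs in lfcs_by_comp.items():
            for i, l in enumerate(lfcs):
                rows.append([f"g{i}", comp, 100, 100, l, 0.01])
        return de_frame(rows)

    def test_identical_comparisons_have_zero_area(self):
        lfcs = [0.5, -1.0, 2.0, 0.1]
        table = self._table({"wtA_vs_wtB": lfcs, "delA_vs_delB": lfcs})
        ecdfs, summary = cumulative_de(
            table, ["wtA_vs_wtB", "delA_vs_delB"], [f"g{i}" for i in range(4)]
        )
        assert summary["signed_area"].iloc[0] == pytest.approx(0.0)

    def test_shifted_comparison_moves_cdf_right(self):
        lfcs = [0.5, 1.0, 2.0, 0.1]
        shifted = [l + 1 for l in lfcs]
        table = self._table({"wtA_vs_wtB": lfcs, "delA_vs_delB": shifted})
        ecdfs, summary = cumulative_de(
            table, ["wtA_vs_wtB", "delA_vs_delB"], [f"g{i}" for i in range(4)]
        )
        assert summary["signed_area"].iloc[0] == pytest.approx(1.0)
        grid = np.linspace(0, 4, 50)
        assert (ecdfs["delA_vs_delB"](grid) <= ecdfs["wtA_vs_wtB"](grid) + 1e-12).all()

    def test_ecdf_matches_sort_and_count(self):
        rng = np.random.default_rng(6)
        lfcs = rng.normal(0, 2, 30).tolist()
        table = self._table({"wtA_vs_wtB": lfcs})
        genes = [f"g{i}" for i in range(30)]
        ecdfs, _ = cumulative_de(table, ["wtA_vs_wtB"], genes)
        mags = np.abs(lfcs)
        for q in [0.0, 0.5, 1.0, 2.5, 10.0]:
            want = np.sum(np.sort(mags) <= q) / len(mags)
            assert ecdfs["wtA_vs_wtB"](q) == pytest.approx(want)

    def test_missing_gene_excluded_with_warning(self, caplog):
        table = self._table({"wtA_vs_wtB": [1.0, 2.0]})
        with caplog.at_level("WARNING", logger="ebsa"):
            ecdfs, _ = cumulative_de(table, ["wtA_vs_wtB"], ["g0", "g1", "missing"])
        assert "excluded" in caplog.text


def test_benjamini_hochberg_helper_matches_definition():
    p = np.array([0.001, 0.01, 0.02, 0.5])
    adj = adjust_pvalues(p)
    # BH: p_(i) * n / i, cumulative-min from the largest
    n = len(p)
    want = np.minimum.accumulate((p * n / np.arange(1, n + 1))[::-1])[::-1]
    np.testing.assert_allclose(adj, np.minimum(want, 1.0))
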