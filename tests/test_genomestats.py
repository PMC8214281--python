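"""Arm binning, permutation enrichment, regression, group comparisons,
chi-square, and donor consistency."""

import numpy as np
import pytest
from scipy import stats

import quartetconv as qc
from quartetconv.genomestats import ArmBin, bin_genes, fold_increase_and_permute
from quartetconv.records import ConversionCall, GeneRecord, PairDistances


def _gene(gid, start, end=None, chrom="chr1", genome="G"):
    end = end or start + 999
    return GeneRecord(gene_id=gid, genome=genome, chrom=chrom, start=start, end=end)


CHROM_LEN = {"chr1": 30_000_000}


class TestBinGenes:
    def test_left_arm_bin0(self):
        bins = bin_genes([_gene("g", 100_000)], set(), CHROM_LEN)
        assert (bins[0].arm, bins[0].bin_index) == ("left", 0)

    def test_right_arm_bin0(self):
        bins = bin_genes([_gene("g", 29_800_000, 29_801_000)], set(), CHROM_LEN)
        assert (bins[0].arm, bins[0].bin_index) == ("right", 0)

    def test_bin_index_arithmetic(self):
        bins = bin_genes([_gene("g", 1_750_000, 1_750_100)], set(), CHROM_LEN)
        assert bins[0].bin_index == 3

    def test_conservation_and_conversion_split(self):
        genes = [_gene(f"g{i}", 1 + i * 100_000, 500 + i * 100_000) for i in range(50)]
        conv = {"g0", "g5", "g40"}
        bins = bin_genes(genes, conv, CHROM_LEN)
        assert sum(b.total for b in bins) == 50
        assert sum(b.converted for b in bins) == 3

    def test_gene_beyond_length_raises_with_name(self):
        with pytest.raises(ValueError, match="gX"):
            bin_genes([_gene("gX", 29_999_900, 30_100_000)], set(), CHROM_LEN)


def _bins(rates, width=500_000):
    """Build one-arm bins with the given converted/total structure."""
    out = []
    for i, r in enumerate(rates):
        conv = int(round(r * 100))
        out.append(ArmBin(genome="G", chrom="chr1", arm="left", bin_index=i,
                          bin_width=width, converted=conv, nonconverted=100 - conv))
    return out


class TestFoldIncrease:
    def test_flat_rates_fold_one_p_near_one(self):
        res = fold_increase_and_permute(_bins([0.2] * 8), outer_span=1_000_000,
                                        rounds=999, seed=1)
        assert res.observed_fold == pytest.approx(1.0)
        assert res.p_value > 0.5

    def test_extreme_enrichment_minimal_p(self):
        res = fold_increase_and_permute(
            _bins([0.5, 0.5, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]),
            outer_span=1_000_000, rounds=1000, seed=2,
        )
        assert np.isinf(res.observed_fold)
        # permutation can tie the observed assignment itself
        assert res.p_value <= (1 + 1000 * (2 * 1 / 28)) / 1001 + 0.02

    def test_exact_enumeration_matches_sampling(self):
        bins = _bins([0.5, 0.4, 0.2, 0.1, 0.15, 0.1, 0.2, 0.1])
        exact = fold_increase_and_permute(bins, outer_span=1_000_000, exact=True)
        sampled = fold_increase_and_permute(bins, outer_span=1_000_000,
                                            rounds=200_000, seed=3)
        assert abs(exact.p_value - sampled.p_value) < 0.01

    def test_empty_groups_error(self):
        with pytest.raises(ValueError):
            fold_increase_and_permute(_bins([0.1, 0.2]), outer_span=5_000_000)

    def test_p_value_bounds(self):
        res = fold_increase_and_permute(
            _bins([0.9, 0.8, 0.1, 0.1, 0.1, 0.1]), outer_span=1_000_000,
            rounds=499, seed=4,
        )
        assert 1 / 500 <= res.p_value <= 1.0


class TestRegression:
    def test_perfectly_collinear(self):
        counts = {f"c{i}": float(i) for i in range(6)}
        rates = {f"c{i}": 2.0 * i + 1.0 for i in range(6)}
        res = qc.block_rate_regression(counts, rates)
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)

    def test_constant_response(self):
        counts = {f"c{i}": float(i) for i in range(5)}
        rates = {f"c{i}": 0.3 for i in range(5)}
        res = qc.block_rate_regression(counts, rates)
        assert res["r_squared"] == 0.0 and res["slope"] == 0.0

    def test_known_ols_solution_and_exclusions(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        y = [2.1, 2.9, 4.2, 4.8, 6.1, 7.2, 7.8, 9.1]
        counts = {f"c{i}": xi for i, xi in enumerate(x)}
        rates = {f"c{i}": yi for i, yi in enumerate(y)}
        res = qc.block_rate_regression(counts, rates)
        lr = stats.linregress(x, y)
        assert res["r_squared"] == pytest.approx(lr.rvalue**2)
        assert res["p_value"] == pytest.approx(lr.pvalue)
        with pytest.raises(ValueError):
            qc.block_rate_regression(counts, rates, exclude={f"c{i}" for i in range(6)})

    def test_r2_invariant_under_affine_predictor_rescale(self):
        rng = np.random.default_rng(0)
        x = rng.random(10)
        y = 3 * x + rng.normal(0, 0.1, 10)
        counts = {f"c{i}": xi for i, xi in enumerate(x)}
        rates = {f"c{i}": yi for i, yi in enumerate(y)}
        r2 = qc.block_rate_regression(counts, rates)["r_squared"]
        counts2 = {k: 7.0 * v - 3.0 for k, v in counts.items()}
        r2b = qc.block_rate_regression(counts2, rates)["r_squared"]
        assert r2 == pytest.approx(r2b)


def _dist(pn, ps):
    return PairDistances(id1="a", id2="b", pn=pn, ps=ps, Pn=pn, Ps=ps,
                         aa_identity=1 - pn, n_sites=100)


class TestConvertedVsNonconverted:
    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(1)
        dists = {}
        conv = set()
        vals = rng.normal(0.25, 0.02, 40)
        for i, v in enumerate(vals):
            key = frozenset((f"a{i}", f"b{i}"))
            dists[key] = _dist(v, v + 0.2)
            if i % 2:
                conv.add(key)
        table = qc.compare_converted_vs_nonconverted(dists, conv)
        assert table.loc["Pn", "p_value"] > 0.05

    def test_welch_matches_scipy(self):
        a = [0.1, 0.12, 0.15, 0.2, 0.18]
        b = [0.25, 0.3, 0.22, 0.28, 0.31, 0.27]
        dists = {}
        conv = set()
        for i, v in enumerate(a):
            key = frozenset((f"ca{i}", f"cb{i}"))
            dists[key] = _dist(v, 0.4)
            conv.add(key)
        for i, v in enumerate(b):
            dists[frozenset((f"na{i}", f"nb{i}"))] = _dist(v, 0.5)
        table = qc.compare_converted_vs_nonconverted(dists, conv)
        expect = stats.ttest_ind(a, b, equal_var=False).pvalue
        assert table.loc["Pn", "p_value"] == pytest.approx(expect)
        assert table.loc["Pn", "converted_mean"] == pytest.approx(np.mean(a))

    def test_converted_group_lower_ps_on_simulation_style_data(self):
        rng = np.random.default_rng(2)
        dists = {}
        conv = set()
        for i in range(60):
            key = frozenset((f"a{i}", f"b{i}"))
            if i < 20:  # homogenized by conversion: small Ps
                dists[key] = _dist(0.1, float(rng.uniform(0.0, 0.2)))
                conv.add(key)
            else:
                dists[key] = _dist(0.25, float(rng.uniform(0.4, 0.7)))
        table = qc.compare_converted_vs_nonconverted(dists, conv)
        assert table.loc["Ps", "converted_mean"] < table.loc["Ps", "nonconverted_mean"]
        assert table.loc["Ps", "p_value"] < 1e-6


class TestExpressionCompare:
    @pytest.fixture
    def matrix(self):
        import pandas as pd

        genes = [f"g{i}" for i in range(10)]
        return pd.DataFrame({"leaf": [10, 30, 10, 15, 0, 50, 5, 20, 8, 9]}, index=genes)

    def test_twofold_and_zero_rules(self, matrix):
        pairs = [("g0", "g1"), ("g2", "g3"), ("g4", "g5"), ("g6", "g7"), ("g8", "g9")]
        conv = {frozenset(("g0", "g1")), frozenset(("g6", "g7"))}
        table = qc.expression_compare(matrix, pairs, conv, "leaf")
        # (10,30) ratio 3 -> twofold; (g4,g5) dropped for zero expression
        assert table.loc["converted", "n_pairs"] == 2
        assert table.loc["converted", "twofold_fraction"] == pytest.approx(1.0)
        assert table.loc["nonconverted", "n_pairs"] == 2
        assert table.loc["nonconverted", "twofold_fraction"] == pytest.approx(0.0)

    def test_missing_sample_errors(self, matrix):
        with pytest.raises(ValueError):
            qc.expression_compare(matrix, [], set(), "root")


class TestCategoryChisq:
    def test_matches_hand_computation(self):
        # 2x2 built from printed-style percentages: 157/500 vs 255/1000
        conv = {f"c{i}" for i in range(500)}
        nonconv = {f"n{i}" for i in range(1000)}
        members = {f"c{i}" for i in range(157)} | {f"n{i}" for i in range(255)}
        table = qc.category_chisq({"catalytic": members}, conv, conv | nonconv)
        obs = np.array([[157, 343], [255, 745]])
        chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
        assert table.loc["catalytic", "chi2"] == pytest.approx(chi2)
        assert table.loc["catalytic", "p_value"] == pytest.approx(p)
        assert table.loc["catalytic", "converted_pct"] == pytest.approx(31.4)
        assert table.loc["catalytic", "nonconverted_pct"] == pytest.approx(25.5)

    def test_category_with_all_genes_p_one(self):
        conv = {"a", "b"}
        nonconv = {"c", "d"}
        table = qc.category_chisq({"everything": conv | nonconv}, conv, conv | nonconv)
        assert table.loc["everything", "p_value"] == pytest.approx(1.0)

    def test_empty_category_skipped(self):
        table = qc.category_chisq({"empty": set()}, {"a"}, {"a", "b"})
        assert "empty" not in table.index


class TestDonorConsistency:
    def _call(self, genome, g1, g2, donor):
        return ConversionCall(genome=genome, gene1=g1, gene2=g2,
                              methods={"pcv"}, donor=donor)

    def test_counts(self):
        # locus L1/L2 pair converted in three genomes, same donor locus L1
        groups = {}
        merged = {}
        for g in ("A", "B", "C"):
            groups[f"{g}_1"] = "L1"
            groups[f"{g}_2"] = "L2"
            merged[g] = [self._call(g, f"{g}_1", f"{g}_2", f"{g}_1")]
        out = qc.donor_consistency(merged, groups)
        assert out["converted_in_ge2_genomes"] == 2  # both loci seen everywhere
        assert out["donor_in_ge2_pct"] == pytest.approx(100.0)
        assert out["same_donor_all_genomes"] == 1

    def test_single_genome_donor_excluded(self):
        groups = {"A_1": "L1", "A_2": "L2"}
        merged = {"A": [self._call("A", "A_1", "A_2", "A_1")],
                  "B": [], "C": []}
        out = qc.donor_consistency(merged, groups)
        assert out["donor_in_ge2_genomes"] == 0
        assert out["same_donor_all_genomes"] == 0
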