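"""Gene-body-methylation classifier: binomial tails, BH, planted recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from methagene.gbm import (
    BackgroundRates,
    bh_adjust,
    binom_tail,
    classify_genes,
    estimate_background,
    site_is_methylated,
)
from methagene.io import read_coverage_or_bedgraph
from methagene.simulate import FixtureSpec, generate
from methagene.types import SampleTable


def _sample(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "count_m", "count_u"])
    df["trinucleotide"] = "NNN"
    return SampleTable.from_frame("s", df)


def enumeration_tail(m, n, p):
    """Exhaustive upper-tail sum using exact binomial coefficients."""
    return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(m, n + 1))


class TestBackground:
    def test_saturated_cg(self):
        s = _sample([("chr1", 1, "+", "CG", 5, 0), ("chr1", 2, "+", "CG", 3, 0)])
        assert estimate_background(s).p_cg == 1.0

    def test_pooled_ratio(self):
        s = _sample([("chr1", 1, "+", "CG", 2, 2), ("chr1", 2, "+", "CG", 2, 2)])
        bg = estimate_background(s)
        assert bg.p_cg == 0.5
        assert np.isnan(bg.p_chg)  # no CHG sites

    def test_estimate_concentrates_on_truth(self, tmp_path):
        spec = FixtureSpec(seed=13, n_chromosomes=1, chromosome_length=1_000_000,
                           n_genes=0, sites_per_kb={"CG": 50.0},
                           background_rates={"CG": 0.05})
        res = generate(spec, tmp_path)
        bg = estimate_background(res.sample_table())
        assert len(res.sites) >= 50_000
        assert abs(bg.p_cg - 0.05) < 0.005

    def test_bedgraph_only_input_refused(self, tmp_path):
        p = tmp_path / "a.bedGraph"
        p.write_text("chr1\t0\t1\t50\n")
        s = read_coverage_or_bedgraph(p, "bedgraph")
        with pytest.raises(ValueError, match="count data required"):
            estimate_background(s)


class TestSiteTest:
    def test_fully_methylated_closed_form(self):
        # tail = p^n = 0.05^5, well under alpha
        assert binom_tail(5, 5, 0.05) == pytest.approx(0.05**5, rel=1e-12)
        assert site_is_methylated(5, 5, 0.05)

    def test_zero_methylated_never_called(self):
        assert binom_tail(0, 10, 0.3) == 1.0
        assert not site_is_methylated(0, 10, 0.99, alpha_site=0.5)

    def test_zero_coverage_is_error(self):
        with pytest.raises(ValueError):
            site_is_methylated(0, 0, 0.05)

    @pytest.mark.parametrize("p", [0.05, 0.3, 0.5])
    def test_tail_matches_enumeration(self, p):
        for n in range(1, 51):
            ms = np.arange(0, n + 1)
            got = binom_tail(ms, n, p)
            exact = np.array([enumeration_tail(int(m), n, p) for m in ms])
            assert np.max(np.abs(got - exact)) < 1e-12

    def test_monotone_in_count(self):
        n = 30
        tails = binom_tail(np.arange(n + 1), n, 0.2)
        assert (np.diff(tails) <= 1e-15).all()


class TestBH:
    def test_hand_computed_example(self):
        q = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_adjust([0.2]).tolist() == [0.2]

    def test_nan_passthrough(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1]) and not np.isnan(q[0])

    def test_matches_statsmodels_reference(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=100)
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), expected)


class TestClassifier:
    def test_extreme_gbm_gene(self):
        rows = [("chr1", 10 + 2 * i, "+", "CG", 10, 0) for i in range(20)]
        rows += [("chr1", 200 + i, "+", "CG", 0, 10) for i in range(380)]
        rows += [("chr1", 11 + 4 * i, "-", "CHG", 0, 10) for i in range(20)]
        rows += [("chr1", 12 + 4 * i, "-", "CHH", 0, 10) for i in range(20)]
        s = _sample(rows)
        feats = pd.DataFrame(
            [("chr1", 0, 100, "+", "g1", "gene")],
            columns=["chrom", "start", "end", "strand", "feature_id", "feature_type"],
        )
        calls = classify_genes(s, feats, min_sites_per_context=10)
        assert calls.iloc[0].label == "gbM"
        assert calls.iloc[0].n_methylated_CG == 20

    def test_silent_gene_unmethylated(self):
        rows = [("chr1", 10 + 3 * i + j, "+", ctx, 0, 10)
                for j, ctx in enumerate(("CG", "CHG", "CHH")) for i in range(15)]
        s = _sample(rows)
        feats = pd.DataFrame(
            [("chr1", 0, 100, "+", "g1", "gene")],
            columns=["chrom", "start", "end", "strand", "feature_id", "feature_type"],
        )
        calls = classify_genes(s, feats, min_sites_per_context=10)
        assert calls.iloc[0].label == "unmethylated"

    def test_sparse_gene_undetermined(self):
        rows = [("chr1", 10 + i, "+", "CG", 1, 1) for i in range(15)]
        s = _sample(rows)
        feats = pd.DataFrame(
            [("chr1", 0, 100, "+", "g1", "gene")],
            columns=["chrom", "start", "end", "strand", "feature_id", "feature_type"],
        )
        calls = classify_genes(s, feats, min_sites_per_context=10)
        assert calls.iloc[0].label == "undetermined"  # no CHG/CHH coverage

    def test_planted_recovery(self, gbm_fixture):
        res, spec = gbm_fixture
        calls = classify_genes(res.sample_table(), res.genes)
        merged = calls.merge(res.genes[["feature_id", "is_gbm"]], on="feature_id")
        pred = merged.label == "gbM"
        truth = merged.is_gbm
        sensitivity = (pred & truth).sum() / truth.sum()
        fdr = (pred & ~truth).sum() / max(pred.sum(), 1)
        assert sensitivity >= 0.95
        assert fdr <= 0.05

    def test_every_gene_gets_exactly_one_label(self, gbm_fixture):
        res, _ = gbm_fixture
        calls = classify_genes(res.sample_table(), res.genes)
        assert len(calls) == len(res.genes)
        assert set(calls.label) <= {"gbM", "CHG/CHH-methylated", "unmethylated", "undetermined"}

    def test_null_call_rate_controlled(self, tmp_path):
        """With no planted signal the gbM call rate stays near the FDR level."""
        rates, n_total = [], 0
        for rep in range(3):
            spec = FixtureSpec(seed=100 + rep, n_chromosomes=1,
                               chromosome_length=500_000, n_genes=150,
                               gene_length=(1500, 2500), intergenic_spacing=700,
                               sites_per_kb={"CG": 15.0, "CHG": 10.0, "CHH": 12.0},
                               gbm_fraction=0.0)
            res = generate(spec, tmp_path / f"rep{rep}")
            calls = classify_genes(res.sample_table(), res.genes)
            rates.append((calls.label == "gbM").mean())
            n_total += len(calls)
        se = math.sqrt(0.05 * 0.95 / n_total)
        assert np.mean(rates) <= 0.05 + 3 * se
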