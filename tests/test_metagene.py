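"""Metagene binning, profile aggregation, smoothing, and heatmap ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methagene.io import read_annotation, read_cytosine_report
from methagene.metagene import (
    MetageneConfig,
    bin_regions,
    heatmap_matrix,
    profile,
    region_scores,
    smooth_profile,
)
from methagene.types import SampleTable

from conftest import matrix_from_density


def _sample(rows, sample_id="s"):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "count_m", "count_u"])
    df["trinucleotide"] = "NNN"
    return SampleTable.from_frame(sample_id, df)


def _features(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "feature_id", "feature_type"])


def brute_force_bins(sample, features, config):
    """Independent per-site accumulation: for every (gene, site) pair test
    window membership directly and add counts to the floor-formula bin."""
    fb, bb = config.flank_bins, config.body_bins
    flank = config.flank_length if fb else 0
    n_bins = 2 * fb + bb
    feats = features[(features.end - features.start) >= config.min_gene_length].reset_index(drop=True)
    m = np.zeros((len(feats), n_bins))
    t = np.zeros((len(feats), n_bins))
    sites = sample.sites[sample.sites.context == config.context]
    for gi, g in feats.iterrows():
        for s in sites.itertuples(index=False):
            if s.chrom != g.chrom:
                continue
            p0 = s.pos - 1
            if flank and g.start - flank <= p0 < g.start:
                b = min((p0 - (g.start - flank)) * fb // flank, fb - 1)
            elif g.start <= p0 < g.end:
                b = fb + min((p0 - g.start) * bb // (g.end - g.start), bb - 1)
            elif flank and g.end <= p0 < g.end + flank:
                b = fb + bb + min((p0 - g.end) * fb // flank, fb - 1)
            else:
                continue
            if g.strand == "-":
                b = n_bins - 1 - b
            m[gi, b] += s.count_m
            t[gi, b] += s.count_m + s.count_u
    return m, t


class TestBinRegions:
    CFG = MetageneConfig(flank_length=0, body_bins=2, flank_bins=0,
                         smoothing_window=3, smoothing_polyorder=1)

    def test_two_sites_two_bins(self):
        sample = _sample([("chr1", 11, "+", "CG", 4, 0), ("chr1", 61, "+", "CG", 0, 4)])
        feats = _features([("chr1", 0, 100, "+", "g1", "gene")])
        mat = bin_regions(sample, feats, self.CFG)
        assert np.allclose(mat.density[0], [1.0, 0.0])

    def test_minus_strand_reverses_bins(self):
        sample = _sample([("chr1", 11, "+", "CG", 4, 0), ("chr1", 61, "+", "CG", 0, 4)])
        feats = _features([("chr1", 0, 100, "-", "g1", "gene")])
        mat = bin_regions(sample, feats, self.CFG)
        assert np.allclose(mat.density[0], [0.0, 1.0])

    def test_strand_law_on_fixture(self, binning_fixture):
        res, _ = binning_fixture
        sample = res.sample_table()
        feats = res.genes.copy()
        cfg = MetageneConfig(flank_length=300, body_bins=10, flank_bins=4)
        plus = feats.assign(strand="+")
        minus = feats.assign(strand="-")
        mp = bin_regions(sample, plus, cfg)
        mm = bin_regions(sample, minus, cfg)
        assert np.array_equal(mp.support_m, mm.support_m[:, ::-1])
        assert np.array_equal(mp.support_total, mm.support_total[:, ::-1])

    def test_matches_brute_force_oracle(self, binning_fixture):
        res, _ = binning_fixture
        sample = res.sample_table()
        feats = res.genes
        cfg = MetageneConfig(flank_length=200, body_bins=8, flank_bins=3)
        mat = bin_regions(sample, feats, cfg)
        m, t = brute_force_bins(sample, feats, cfg)
        assert np.array_equal(mat.support_m, m)
        assert np.array_equal(mat.support_total, t)

    def test_conservation_per_region(self, binning_fixture):
        """No in-window site is lost or double counted within one region."""
        res, _ = binning_fixture
        sample = res.sample_table()
        cfg = MetageneConfig(flank_length=0, body_bins=5, flank_bins=0)
        mat = bin_regions(sample, res.genes, cfg)
        sites = sample.sites[sample.sites.context == "CG"]
        for i in range(0, mat.n_regions, 17):
            g = res.genes.iloc[i]
            sel = (sites.chrom == g.chrom) & (sites.pos - 1 >= g.start) & (sites.pos - 1 < g.end)
            assert mat.support_m[i].sum() == sites.loc[sel, "count_m"].sum()

    def test_length_filter_error(self):
        sample = _sample([("chr1", 11, "+", "CG", 1, 1)])
        feats = _features([("chr1", 0, 100, "+", "g1", "gene")])
        cfg = MetageneConfig(min_gene_length=1000, body_bins=2, flank_bins=0,
                             flank_length=0, smoothing_window=3, smoothing_polyorder=1)
        with pytest.raises(ValueError, match="min_gene_length"):
            bin_regions(sample, feats, cfg)

    def test_chromosome_mismatch_error(self):
        sample = _sample([("1", 11, "+", "CG", 1, 1)])
        feats = _features([("chr1", 0, 100, "+", "g1", "gene")])
        with pytest.raises(ValueError, match="naming"):
            bin_regions(sample, feats, self.CFG)

    @given(
        positions=st.lists(st.integers(min_value=1, max_value=200), min_size=1,
                           max_size=30, unique=True),
        counts=st.data(),
    )
    @settings(max_examples=40, deadline=None)
    def test_strand_law_and_bounds_property(self, positions, counts):
        rows = [
            ("chr1", p, "+", "CG",
             counts.draw(st.integers(0, 5)), counts.draw(st.integers(0, 5)))
            for p in positions
        ]
        sample = _sample(rows)
        cfg = MetageneConfig(flank_length=50, body_bins=4, flank_bins=2,
                             smoothing_window=3, smoothing_polyorder=1)
        plus = _features([("chr1", 40, 160, "+", "g1", "gene")])
        minus = _features([("chr1", 40, 160, "-", "g1", "gene")])
        mp = bin_regions(sample, plus, cfg)
        mm = bin_regions(sample, minus, cfg)
        assert np.array_equal(mp.support_m[0], mm.support_m[0][::-1])
        d = mp.density
        defined = ~np.isnan(d)
        assert ((d[defined] >= 0) & (d[defined] <= 1)).all()


class TestProfile:
    def test_identical_rows_degenerate_variance(self):
        row = np.linspace(0.1, 0.9, 21)
        mat = matrix_from_density(np.tile(row, (5, 1)))
        cfg = MetageneConfig(body_bins=21, flank_bins=0, flank_length=0,
                             smoothing_window=5, smoothing_polyorder=2)
        prof = profile(mat, cfg)
        assert np.allclose(prof.sd, 0)
        assert np.allclose(prof.ci_upper - prof.ci_lower, 0)

    def test_savitzky_golay_reproduces_cubic(self):
        x = np.linspace(-1, 1, 60)
        cubic = 0.2 + 0.1 * x - 0.3 * x**2 + 0.25 * x**3
        smoothed = smooth_profile(cubic, window=11, polyorder=3)
        assert np.max(np.abs(smoothed - cubic)) < 1e-9

    def test_t_band_matches_direct_formula(self):
        from scipy.stats import t as t_dist
        rng = np.random.default_rng(2)
        dens = rng.uniform(0.2, 0.8, size=(12, 6))
        mat = matrix_from_density(dens)
        cfg = MetageneConfig(body_bins=6, flank_bins=0, flank_length=0,
                             smoothing_window=3, smoothing_polyorder=1)
        prof = profile(mat, cfg)
        n = dens.shape[0]
        half = t_dist.ppf(0.975, n - 1) * dens.std(axis=0, ddof=1) / np.sqrt(n)
        assert np.allclose(prof.ci_upper - prof.mean_density, half)
        assert (prof.ci_lower <= prof.mean_density + 1e-12).all()
        assert (prof.ci_upper >= prof.mean_density - 1e-12).all()

    def test_all_missing_bin_stays_missing(self):
        dens = np.full((4, 5), 0.5)
        dens[:, 2] = np.nan
        mat = matrix_from_density(dens)
        cfg = MetageneConfig(body_bins=5, flank_bins=0, flank_length=0,
                             smoothing_window=3, smoothing_polyorder=1)
        prof = profile(mat, cfg)
        assert np.isnan(prof.mean_density[2]) and np.isnan(prof.smoothed_mean[2])
        assert prof.n_regions_per_bin[2] == 0

    def test_equal_support_profile_conservation(self):
        """With equal support everywhere, the coverage-weighted whole-body
        density equals the mean of per-bin densities."""
        rng = np.random.default_rng(3)
        dens = rng.uniform(0, 1, size=(7, 9))
        mat = matrix_from_density(dens, weight=40.0)
        whole = mat.support_m.sum() / mat.support_total.sum()
        assert whole == pytest.approx(float(np.mean(dens)))


class TestHeatmap:
    def test_sort_and_tie_rule(self):
        dens = np.array([[0.9] * 3, [0.1] * 3, [0.5] * 3, [0.5] * 3])
        mat = matrix_from_density(dens, ids=["d", "a", "c", "b"])
        heat = heatmap_matrix(mat)
        assert heat.ranking.region_id.tolist() == ["d", "b", "c", "a"]

    def test_all_missing_region_last_with_missing_score(self):
        dens = np.array([[0.2] * 3, [np.nan] * 3, [0.8] * 3])
        mat = matrix_from_density(dens, ids=["a", "b", "c"])
        heat = heatmap_matrix(mat)
        assert heat.ranking.region_id.tolist() == ["c", "a", "b"]
        assert np.isnan(heat.ranking.score.iloc[-1])

    def test_superrow_means_match_block_oracle(self):
        rng = np.random.default_rng(9)
        dens = rng.uniform(0, 1, size=(1000, 12))
        mat = matrix_from_density(dens)
        heat = heatmap_matrix(mat, n_display_rows=100)
        scores = region_scores(mat)
        order = np.lexsort((mat.region_ids.astype(str), -scores))
        blocks = np.array_split(np.arange(1000), 100)
        expected = np.vstack([dens[order[b]].mean(axis=0) for b in blocks])
        assert np.allclose(heat.values, expected)
        assert heat.values.shape == (100, 12)
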