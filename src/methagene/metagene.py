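"""Metagene coordinate mapping, profile aggregation, and ranked heatmaps.

A metagene places variable-length regions on a common axis: an upstream
flank of ``flank_length`` bp split into ``flank_bins`` bins, the region body
split into ``body_bins`` bins, and a downstream flank mirroring the upstream
one. Bin 0 is always the 5' end: minus-strand regions have their bin vector
reversed after genomic binning, so profiles from the two strands are
directly comparable.

Within a cell (region x bin) the methylation density is coverage-weighted:
sum of methylated counts over sum of total counts across the sites in the
cell. Across regions the profile mean is the unweighted mean of per-region
bin densities, so every region contributes equally to the metagene.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import t as t_dist

from methagene.types import CONTEXTS, BinnedDensityMatrix, MetageneProfile, RankedHeatmap, SampleTable

__all__ = ["MetageneConfig", "bin_regions", "profile", "heatmap_matrix"]


@dataclass(frozen=True)
class MetageneConfig:
    """Parameters of the metagene coordinate system and profile smoothing.

    Attributes
    ----------
    min_gene_length : int
        Regions shorter than this many bp are excluded before binning.
    flank_length : int
        Length in bp of each flank window adjacent to the region.
    body_bins, flank_bins : int
        Number of bins for the body and for each flank (flank_bins may be 0).
    context : str
        Cytosine context analysed (CG, CHG or CHH).
    smoothing_window, smoothing_polyorder : int
        Savitzky-Golay filter parameters; the window is reduced to the
        largest valid odd number when it exceeds the bin count.
    ci_level : float
        Coverage level of the t-based confidence band around the mean.
    """

    min_gene_length: int = 0
    flank_length: int = 2000
    body_bins: int = 100
    flank_bins: int = 50
    context: str = "CG"
    smoothing_window: int = 21
    smoothing_polyorder: int = 3
    ci_level: float = 0.95

    def __post_init__(self):
        if self.body_bins < 1:
            raise ValueError("body_bins must be >= 1")
        if self.flank_bins < 0:
            raise ValueError("flank_bins must be >= 0")
        if self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}")
        if self.smoothing_window < 3 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be an odd integer >= 3")
        if self.smoothing_polyorder >= self.smoothing_window:
            raise ValueError("smoothing_polyorder must be < smoothing_window")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")

    @property
    def n_total_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins

    def with_context(self, context: str) -> "MetageneConfig":
        return replace(self, context=context)


def bin_regions(
    sample: SampleTable,
    features: pd.DataFrame,
    config: MetageneConfig,
) -> BinnedDensityMatrix:
    """Accumulate per-site counts of one context into region x bin cells.

    Body sites map to bin ``floor((pos - start) / body_length * body_bins)``
    (clamped to the last body bin so the final base belongs to it); flank
    sites map likewise over ``[start - flank_length, start)`` and
    ``[end, end + flank_length)``. The whole bin vector is reversed for
    minus-strand features so bin 0 is the 5' upstream end. A site may
    contribute to every feature whose window covers it; flanks are not
    masked against neighbouring features.

    Raises
    ------
    ValueError
        If no feature passes the ``min_gene_length`` filter, or if no
        feature chromosome matches any site chromosome (likely a naming
        mismatch such as "1" vs "chr1").
    """
    feats = features[(features["end"] - features["start"]) >= config.min_gene_length]
    if len(feats) == 0:
        raise ValueError(
            f"no features left after min_gene_length={config.min_gene_length} filter"
        )
    sites = sample.subset_context(config.context)
    feat_chroms = set(feats["chrom"].unique())
    site_chroms = set(sites["chrom"].unique())
    if len(sites) and not (feat_chroms & site_chroms):
        raise ValueError(
            "no feature chromosome matches any site chromosome "
            f"(features: {sorted(feat_chroms)[:5]}, sites: {sorted(site_chroms)[:5]}); "
            "check chromosome naming conventions"
        )

    fb, bb = config.flank_bins, config.body_bins
    n_bins = config.n_total_bins
    flank_len = config.flank_length if fb > 0 else 0
    n_regions = len(feats)
    support_m = np.zeros((n_regions, n_bins))
    support_t = np.zeros((n_regions, n_bins))

    # per-chromosome sorted site arrays
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in sites.groupby("chrom", observed=True, sort=False):
        pos0 = grp["pos"].to_numpy(np.int64) - 1  # 0-based
        order = np.argsort(pos0, kind="stable")
        by_chrom[chrom] = (
            pos0[order],
            grp["count_m"].to_numpy(float)[order],
            (grp["count_m"] + grp["count_u"]).to_numpy(float)[order],
        )

    f_chrom = feats["chrom"].to_numpy()
    f_start = feats["start"].to_numpy(np.int64)
    f_end = feats["end"].to_numpy(np.int64)
    f_strand = feats["strand"].to_numpy()

    for i in range(n_regions):
        entry = by_chrom.get(f_chrom[i])
        if entry is None:
            continue
        pos0, m, tot = entry
        start, end = f_start[i], f_end[i]
        body_len = end - start

        # genomic windows: (window_start, window_len, n_window_bins, bin_offset)
        windows = []
        if flank_len > 0:
            windows.append((start - flank_len, flank_len, fb, 0))
        windows.append((start, body_len, bb, fb))
        if flank_len > 0:
            windows.append((end, flank_len, fb, fb + bb))

        for wstart, wlen, wbins, offset in windows:
            lo = np.searchsorted(pos0, wstart, side="left")
            hi = np.searchsorted(pos0, wstart + wlen, side="left")
            if hi <= lo:
                continue
            rel = pos0[lo:hi] - wstart
            idx = (rel * wbins) // wlen  # exact integer floor
            np.minimum(idx, wbins - 1, out=idx)
            np.add.at(support_m[i], idx + offset, m[lo:hi])
            np.add.at(support_t[i], idx + offset, tot[lo:hi])

        if f_strand[i] == "-":  # 5' end of a minus-strand gene is at `end`
            support_m[i] = support_m[i][::-1]
            support_t[i] = support_t[i][::-1]

    return BinnedDensityMatrix(
        region_ids=feats["feature_id"].to_numpy(),
        support_m=support_m,
        support_total=support_t,
        flank_bins=fb,
        body_bins=bb,
        context=config.context,
        sample_id=sample.sample_id,
    )


def _interpolate_nan(y: np.ndarray) -> np.ndarray:
    """Linearly interpolate NaN runs; edge NaNs take the nearest value."""
    out = y.copy()
    good = ~np.isnan(out)
    if good.sum() == 0:
        return out
    x = np.arange(len(out))
    out[~good] = np.interp(x[~good], x[good], out[good])
    return out


def smooth_profile(mean_density: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    """Savitzky-Golay smoothing robust to missing bins.

    Missing bins are linearly interpolated before filtering and set back to
    NaN afterwards; the window shrinks to the largest valid odd number when
    it exceeds the profile length, and the polynomial order is capped below
    the effective window.
    """
    n = len(mean_density)
    missing = np.isnan(mean_density)
    if missing.all() or n == 0:
        return mean_density.copy()
    w = min(window, n if n % 2 == 1 else n - 1)
    if w < 3:
        return mean_density.copy()
    p = min(polyorder, w - 1)
    smoothed = savgol_filter(_interpolate_nan(mean_density), w, p, mode="interp")
    smoothed[missing] = np.nan
    return smoothed


def profile(matrix: BinnedDensityMatrix, config: MetageneConfig) -> MetageneProfile:
    """Aggregate a binned matrix into a metagene profile.

    Per bin: unweighted mean and sample standard deviation of the defined
    per-region densities, a t-based confidence band
    ``mean +/- t_{1-(1-ci)/2, n-1} * sd / sqrt(n)`` (n = regions with a
    defined value in that bin), and the Savitzky-Golay smoothed mean. Bins
    where every region is missing stay missing — values are never
    fabricated.
    """
    if matrix.n_regions < 1:
        raise ValueError("matrix has no regions")
    dens = matrix.density
    n = (~np.isnan(dens)).sum(axis=0).astype(float)
    sums = np.nansum(dens, axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
        sd = np.full(matrix.n_total_bins, np.nan)
        multi = n >= 2
        if multi.any():
            sd[multi] = np.nanstd(dens[:, multi], axis=0, ddof=1)
    half = np.full(matrix.n_total_bins, np.nan)
    if multi.any():
        crit = t_dist.ppf(1.0 - (1.0 - config.ci_level) / 2.0, n[multi] - 1)
        half[multi] = crit * sd[multi] / np.sqrt(n[multi])
    ci_lower = mean - half
    ci_upper = mean + half
    single = n == 1  # degenerate band: the point itself
    ci_lower[single] = mean[single]
    ci_upper[single] = mean[single]

    smoothed = smooth_profile(mean, config.smoothing_window, config.smoothing_polyorder)
    return MetageneProfile(
        mean_density=mean,
        sd=sd,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        smoothed_mean=smoothed,
        n_regions_per_bin=n.astype(int),
        flank_bins=matrix.flank_bins,
        body_bins=matrix.body_bins,
        context=matrix.context,
        sample_id=matrix.sample_id,
        ci_level=config.ci_level,
    )


def region_scores(matrix: BinnedDensityMatrix) -> np.ndarray:
    """Overall methylation density per region: the mean over its defined
    bins (NaN when every bin is missing). This is the heatmap ranking score
    and the per-region value behind violin/box distributions."""
    dens = matrix.density
    with np.errstate(invalid="ignore"):
        counts = (~np.isnan(dens)).sum(axis=1)
        sums = np.nansum(dens, axis=1)
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def heatmap_matrix(matrix: BinnedDensityMatrix, n_display_rows: int | None = None) -> RankedHeatmap:
    """Order regions by overall methylation density for heatmap display.

    Regions are sorted descending by score (mean of defined bin densities);
    ties break by region_id lexical order and all-missing regions go last.
    When ``n_display_rows`` is fewer than the region count, consecutive rank
    blocks are averaged (unweighted nanmean per bin) into super-rows so the
    heatmap stays readable.
    """
    if matrix.n_regions == 0:
        raise ValueError("matrix has no regions")
    scores = region_scores(matrix)
    order_df = pd.DataFrame({"region_id": matrix.region_ids.astype(str), "score": scores})
    order_df = order_df.sort_values(
        ["score", "region_id"], ascending=[False, True], na_position="last",
        kind="mergesort",
    )
    order = order_df.index.to_numpy()
    ranking = order_df.reset_index(drop=True)
    ranking.insert(0, "rank", np.arange(1, len(ranking) + 1))

    dens = matrix.density[order]
    ids = matrix.region_ids[order].astype(str)
    if n_display_rows is None or n_display_rows >= len(ids):
        values = dens
        labels = list(ids)
    else:
        if n_display_rows < 1:
            raise ValueError("n_display_rows must be >= 1")
        blocks = np.array_split(np.arange(len(ids)), n_display_rows)
        values = np.full((n_display_rows, matrix.n_total_bins), np.nan)
        labels = []
        for b, block in enumerate(blocks):
            with np.errstate(invalid="ignore"):
                block_dens = dens[block]
                cnt = (~np.isnan(block_dens)).sum(axis=0)
                values[b] = np.where(
                    cnt > 0, np.nansum(block_dens, axis=0) / np.maximum(cnt, 1), np.nan
                )
            labels.append(f"rank_{block[0] + 1}-{block[-1] + 1}")
    return RankedHeatmap(
        values=values,
        row_labels=labels,
        ranking=ranking,
        flank_bins=matrix.flank_bins,
        body_bins=matrix.body_bins,
        context=matrix.context,
        sample_id=matrix.sample_id,
    )
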