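"""Chromosome-scale methylation tracks and per-sample distributions.

Each chromosome is tiled into non-overlapping windows of a fixed length and
the pooled methylation density (sum methylated / sum total reads) is
computed per window and context. Chromosome extents are inferred from the
data (maximum observed site position), so no sequence dictionary is needed
— convenient for non-model genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from methagene.types import BinnedDensityMatrix, SampleTable
from methagene.metagene import region_scores

__all__ = [
    "chromosome_levels",
    "SampleDistribution",
    "sample_distribution",
    "site_densities",
]

DEFAULT_WINDOW_LENGTH = 100_000


def chromosome_levels(sample: SampleTable, window_length: int = DEFAULT_WINDOW_LENGTH) -> pd.DataFrame:
    """Windowed methylation densities along every chromosome.

    A site at 1-based position ``p`` falls in window ``(p - 1) //
    window_length``. Returns one row per (chrom, window, context) that holds
    at least one site, with columns chrom, window_start, window_length,
    context, n_sites, sum_m, sum_total, density. Windows without sites are
    simply absent — no rows are fabricated.
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    sites = sample.sites
    if sites.empty:
        return pd.DataFrame(
            columns=["chrom", "window_start", "window_length", "context",
                     "n_sites", "sum_m", "sum_total", "density"]
        )
    window = (sites["pos"].to_numpy(np.int64) - 1) // window_length
    df = sites.assign(window=window, total=sites["count_m"] + sites["count_u"])
    grouped = (
        df.groupby(["chrom", "window", "context"], observed=True)
        .agg(n_sites=("pos", "size"), sum_m=("count_m", "sum"), sum_total=("total", "sum"))
        .reset_index()
    )
    grouped["window_start"] = grouped["window"] * window_length
    grouped["window_length"] = window_length
    with np.errstate(invalid="ignore", divide="ignore"):
        grouped["density"] = np.where(
            grouped["sum_total"] > 0, grouped["sum_m"] / grouped["sum_total"], np.nan
        )
    grouped = grouped.sort_values(["chrom", "window", "context"], kind="mergesort")
    return grouped[
        ["chrom", "window_start", "window_length", "context",
         "n_sites", "sum_m", "sum_total", "density"]
    ].reset_index(drop=True)


@dataclass
class SampleDistribution:
    """Distribution of per-region overall methylation densities for one
    sample x context — the input of violin/box comparisons.

    Quantiles use linear interpolation between order statistics; whiskers
    follow the 1.5 x IQR rule (most extreme values within the fences).
    """

    sample_id: str
    context: str
    values: np.ndarray
    mean: float
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [self.sample_id],
                "context": [self.context],
                "n": [len(self.values)],
                "mean": [self.mean],
                "q1": [self.q1],
                "median": [self.median],
                "q3": [self.q3],
                "whisker_low": [self.whisker_low],
                "whisker_high": [self.whisker_high],
            }
        )


def _summarise(values: np.ndarray, sample_id: str, context: str) -> SampleDistribution:
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q3 - q1
    inside = values[(values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)]
    return SampleDistribution(
        sample_id=sample_id,
        context=context,
        values=values,
        mean=float(values.mean()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
    )


def sample_distribution(matrix: BinnedDensityMatrix) -> SampleDistribution:
    """Per-region overall densities of a binned matrix as a distribution.

    The per-region value is the same score the heatmap ranking uses: the
    mean over the region's defined bins. Regions with no defined bin are
    excluded; if none remain an error is raised.
    """
    scores = region_scores(matrix)
    values = scores[~np.isnan(scores)]
    if len(values) == 0:
        raise ValueError("no region has a defined methylation density")
    return _summarise(values, matrix.sample_id, matrix.context)


def site_densities(sample: SampleTable, context: str) -> SampleDistribution:
    """Per-site methylation fractions as a distribution (the per-site
    alternative to the region-level :func:`sample_distribution`)."""
    sites = sample.subset_context(context)
    total = (sites["count_m"] + sites["count_u"]).to_numpy(float)
    m = sites["count_m"].to_numpy(float)
    covered = total > 0
    if not covered.any():
        raise ValueError(f"no covered {context} sites")
    return _summarise(m[covered] / total[covered], sample.sample_id, context)
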