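"""Core in-memory containers shared across modules.

Conventions
-----------
* Methylation sites use 1-based positions (``pos``), as emitted by Bismark
  and CGmap callers.
* Genomic features use 0-based half-open ``[start, end)`` coordinates
  internally; all conversions happen at the parser boundary.
* Methylation density is always the pooled ratio sum(methylated reads) /
  sum(total reads), never a mean of per-site fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognised cytosine sequence contexts (H = A, T or C).
CONTEXTS = ("CG", "CHG", "CHH")

#: Column order of the per-site table inside a :class:`SampleTable`.
SITE_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "context",
    "trinucleotide",
    "count_m",
    "count_u",
]

#: Column order of an annotation table (one row per genomic feature).
FEATURE_COLUMNS = ["chrom", "start", "end", "strand", "feature_id", "feature_type"]


@dataclass
class SampleTable:
    """Per-cytosine methylation calls for one sample.

    Attributes
    ----------
    sample_id
        Free-text label for the sample.
    sites
        DataFrame with :data:`SITE_COLUMNS`; sorted by (chrom, pos), unique
        on (chrom, pos, strand). ``count_m``/``count_u`` are floats so that
        density-only inputs (bedGraph) can carry fractional unit counts.
    dropped_records
        Input records discarded for invalid context/strand/duplication.
    filtered_records
        Input records excluded by the coverage filter.
    low_confidence
        True when counts are synthetic unit counts reconstructed from a
        density-only format (bedGraph); count-based statistics must refuse
        such samples.
    """

    sample_id: str
    sites: pd.DataFrame
    dropped_records: int = 0
    filtered_records: int = 0
    low_confidence: bool = False
    warnings: list[str] = field(default_factory=list)

    @classmethod
    def from_frame(
        cls,
        sample_id: str,
        sites: pd.DataFrame,
        dropped_records: int = 0,
        filtered_records: int = 0,
        low_confidence: bool = False,
        warnings: list[str] | None = None,
    ) -> "SampleTable":
        """Sort by (chrom, pos), keep the first of duplicate
        (chrom, pos, strand) records (extras are tallied as dropped)."""
        sites = sites.loc[:, SITE_COLUMNS].copy()
        sites = sites.sort_values(["chrom", "pos"], kind="mergesort")
        dup = sites.duplicated(subset=["chrom", "pos", "strand"], keep="first")
        n_dup = int(dup.sum())
        if n_dup:
            sites = sites.loc[~dup]
        sites = sites.reset_index(drop=True)
        return cls(
            sample_id=sample_id,
            sites=sites,
            dropped_records=dropped_records + n_dup,
            filtered_records=filtered_records,
            low_confidence=low_confidence,
            warnings=list(warnings or []),
        )

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def context_totals(self) -> pd.DataFrame:
        """Per-context sums of methylated/unmethylated read counts."""
        return (
            self.sites.groupby("context", observed=True)[["count_m", "count_u"]]
            .sum()
            .reindex(list(CONTEXTS))
            .fillna(0.0)
        )

    def subset_context(self, context: str) -> pd.DataFrame:
        if context not in CONTEXTS:
            raise ValueError(f"unknown context {context!r}; expected one of {CONTEXTS}")
        return self.sites[self.sites["context"] == context]


@dataclass
class BinnedDensityMatrix:
    """Regions x bins matrix of methylation support counts.

    Bin 0 is always the 5' end of the upstream flank; minus-strand regions
    are reversed at binning time. Density is defined per cell as
    ``support_m / support_total`` where the total is positive, NaN elsewhere.
    """

    region_ids: np.ndarray
    support_m: np.ndarray
    support_total: np.ndarray
    flank_bins: int
    body_bins: int
    context: str
    sample_id: str = ""

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_total_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins

    @property
    def density(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = self.support_m / self.support_total
        d[self.support_total <= 0] = np.nan
        return d

    def bin_labels(self) -> list[str]:
        return [f"bin_{j}" for j in range(self.n_total_bins)]

    def to_frame(self) -> pd.DataFrame:
        """Density matrix as a DataFrame: region_id + one column per bin."""
        df = pd.DataFrame(self.density, columns=self.bin_labels())
        df.insert(0, "region_id", self.region_ids)
        return df


@dataclass
class MetageneProfile:
    """Aggregated per-bin profile for one sample x context.

    ``mean_density`` is the unweighted mean over regions of per-region bin
    densities, so each region contributes equally to the metagene. The band
    is a t-based confidence interval on that mean; ``smoothed_mean`` is the
    Savitzky-Golay filtered mean with missing bins interpolated before
    filtering and re-flagged after.
    """

    mean_density: np.ndarray
    sd: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    smoothed_mean: np.ndarray
    n_regions_per_bin: np.ndarray
    flank_bins: int
    body_bins: int
    context: str
    sample_id: str = ""
    ci_level: float = 0.95

    @property
    def n_total_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_index": np.arange(self.n_total_bins),
                "mean_density": self.mean_density,
                "sd": self.sd,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "smoothed_mean": self.smoothed_mean,
                "n_regions": self.n_regions_per_bin,
            }
        )


@dataclass
class RankedHeatmap:
    """Heatmap-ready matrix: rows ordered by overall methylation density.

    ``values`` holds the display rows (possibly rank-block averages when the
    number of regions exceeds the requested display rows); ``ranking`` keeps
    the full per-region score table.
    """

    values: np.ndarray
    row_labels: list[str]
    ranking: pd.DataFrame
    flank_bins: int
    body_bins: int
    context: str
    sample_id: str = ""

    @property
    def n_total_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"bin_{j}" for j in range(self.values.shape[1])]
        )
        df.insert(0, "region_id", self.row_labels)
        return df
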