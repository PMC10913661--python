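"""Cross-sample / cross-context / cross-species comparison.

Each labelled entry (a sample plus its own annotation — annotations may
come from different species) is binned and profiled independently on a
shared metagene grid, so overlay line plots, side-by-side heatmaps and
distribution comparisons are directly comparable. The comparison layer
adds no computation to individual entries: each entry's results are
exactly what metagene_core produces for it alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from methagene.genome import sample_distribution
from methagene.metagene import MetageneConfig, bin_regions, profile
from methagene.types import BinnedDensityMatrix, MetageneProfile, SampleTable

__all__ = ["ComparisonEntry", "ComparisonSet", "build_comparison", "compare_distributions"]


@dataclass
class ComparisonEntry:
    label: str
    context: str
    matrix: BinnedDensityMatrix
    profile: MetageneProfile


@dataclass
class ComparisonSet:
    """Labelled metagene results on one shared bin grid."""

    entries: list[ComparisonEntry]
    body_bins: int
    flank_bins: int

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    def get(self, label: str) -> ComparisonEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)


def build_comparison(
    samples: list[tuple],
    config: MetageneConfig | list[MetageneConfig],
) -> ComparisonSet:
    """Profile several labelled (sample, features) pairs on a common grid.

    Parameters
    ----------
    samples
        List of ``(SampleTable, features, label)`` or
        ``(SampleTable, features, label, context)`` tuples; a per-entry
        context overrides ``config.context`` (used to overlay CG/CHG/CHH of
        one sample).
    config
        One shared :class:`MetageneConfig`, or one per entry — in which
        case every config must share the same (body_bins, flank_bins) grid.
    """
    if len(samples) < 2:
        raise ValueError("a comparison needs at least 2 entries")
    if isinstance(config, MetageneConfig):
        configs = [config] * len(samples)
    else:
        configs = list(config)
        if len(configs) != len(samples):
            raise ValueError("one config per entry required")
        grids = {(c.body_bins, c.flank_bins) for c in configs}
        if len(grids) > 1:
            raise ValueError(f"mismatched bin grids across entries: {sorted(grids)}")

    entries = []
    seen = set()
    for item, cfg in zip(samples, configs):
        if len(item) == 4:
            sample, features, label, context = item
            cfg = cfg.with_context(context)
        else:
            sample, features, label = item
        if label in seen:
            raise ValueError(f"duplicate entry label {label!r}")
        seen.add(label)
        if not isinstance(sample, SampleTable):
            raise TypeError("first element of each entry must be a SampleTable")
        matrix = bin_regions(sample, features, cfg)
        entries.append(
            ComparisonEntry(
                label=label, context=cfg.context, matrix=matrix,
                profile=profile(matrix, cfg),
            )
        )
    c0 = configs[0]
    return ComparisonSet(entries=entries, body_bins=c0.body_bins, flank_bins=c0.flank_bins)


def compare_distributions(comparison: ComparisonSet) -> pd.DataFrame:
    """Summary of per-region overall densities for every entry.

    One row per entry: label, context, n regions with a defined density,
    mean, quartiles and whiskers — the table behind violin/box overlays.
    Raises if any entry has no region with a defined density.
    """
    rows = []
    for entry in comparison:
        dist = sample_distribution(entry.matrix)  # raises on empty entries
        frame = dist.to_frame()
        frame.insert(0, "label", entry.label)
        frame["context"] = entry.context
        rows.append(frame.drop(columns=["sample_id"]))
    return pd.concat(rows, ignore_index=True)
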