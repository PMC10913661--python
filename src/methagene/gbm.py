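"""Probabilistic gene-body-methylation (gbM) classification.

Gene-body methylated genes are methylated in the CG context within their
bodies while staying at background levels in CHG and CHH. The classifier
follows the two-tier binomial construction of Takuno & Gaut:

1. *Site tier* — every covered cytosine is tested against the genome-wide
   methylation proportion of its context: a site with ``m`` methylated
   reads out of ``n`` is called methylated when the one-sided binomial
   upper tail ``P(X >= m | n, p_context)`` is at most ``alpha_site``.
2. *Gene tier* — for each gene and context, the number of methylated sites
   among its body sites is tested against the genome-wide fraction of
   sites called methylated at that context (the null that a gene is a
   random draw of sites). P-values are Benjamini-Hochberg adjusted across
   genes within each context.

Labels: ``gbM`` (CG significant, CHG and CHH not), ``CHG/CHH-methylated``
(TE-like; CHG or CHH significant), ``unmethylated`` (nothing significant),
``undetermined`` (too few covered sites in some context to decide).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from methagene.types import CONTEXTS, SampleTable

__all__ = [
    "BackgroundRates",
    "estimate_background",
    "binom_tail",
    "site_is_methylated",
    "bh_adjust",
    "classify_genes",
]

LABEL_GBM = "gbM"
LABEL_TE = "CHG/CHH-methylated"
LABEL_UNMETH = "unmethylated"
LABEL_UNDET = "undetermined"


@dataclass(frozen=True)
class BackgroundRates:
    """Genome-wide pooled methylation proportions per context:
    sum(count_m) / sum(count_m + count_u) over all retained sites."""

    p_cg: float
    p_chg: float
    p_chh: float

    def rate(self, context: str) -> float:
        return {"CG": self.p_cg, "CHG": self.p_chg, "CHH": self.p_chh}[context]


def _require_counts(sample: SampleTable) -> None:
    if sample.low_confidence:
        raise ValueError(
            "count data required for classification: sample "
            f"{sample.sample_id!r} was read from a density-only format "
            "(bedGraph); use a cytosine report, CGmap or coverage file"
        )


def estimate_background(sample: SampleTable) -> BackgroundRates:
    """Coverage-weighted genome-wide methylation proportion per context."""
    _require_counts(sample)
    totals = sample.context_totals
    rates = {}
    for ctx in CONTEXTS:
        m = float(totals.loc[ctx, "count_m"])
        u = float(totals.loc[ctx, "count_u"])
        rates[ctx] = m / (m + u) if (m + u) > 0 else np.nan
    return BackgroundRates(p_cg=rates["CG"], p_chg=rates["CHG"], p_chh=rates["CHH"])


def binom_tail(count_m, n_total, p) -> np.ndarray | float:
    """One-sided binomial upper tail ``P(X >= count_m | n_total, p)``.

    Computed through the regularised incomplete beta function (scipy's
    survival function), which stays accurate where naive summation of
    ``p^k`` terms underflows.
    """
    return binom.sf(np.asarray(count_m) - 1, n_total, p)


def site_is_methylated(count_m, count_total, background_rate: float, alpha_site: float = 0.05):
    """Per-site methylation call: upper-tail probability <= alpha_site.

    Accepts scalars or aligned arrays; zero-coverage sites are an error
    (they must be filtered upstream).
    """
    count_total = np.asarray(count_total)
    if (count_total <= 0).any():
        raise ValueError("zero-coverage site passed to site_is_methylated")
    result = binom_tail(count_m, count_total, background_rate) <= alpha_site
    return bool(result) if np.isscalar(count_m) else result


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are ignored (not counted in the number of tests) and stay
    NaN. Output is clipped to [0, 1] and monotone in the input ranks.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p down
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    q[ok] = out
    return q


def called_fractions(
    sample: SampleTable,
    background: BackgroundRates,
    alpha_site: float = 0.05,
    min_site_coverage: int = 0,
) -> dict[str, float]:
    """Genome-wide fraction of sites called methylated per context — the
    gene-tier null rate."""
    _require_counts(sample)
    fractions = {}
    for ctx in CONTEXTS:
        sites = sample.subset_context(ctx)
        total = (sites["count_m"] + sites["count_u"]).to_numpy(float)
        keep = total >= max(min_site_coverage, 1)
        total = total[keep]
        if total.size == 0:
            fractions[ctx] = np.nan
            continue
        m = sites["count_m"].to_numpy(float)[keep]
        called = site_is_methylated(m, total, background.rate(ctx), alpha_site)
        fractions[ctx] = float(np.mean(called))
    return fractions


def classify_genes(
    sample: SampleTable,
    features: pd.DataFrame,
    background: BackgroundRates | None = None,
    alpha_site: float = 0.05,
    fdr_level: float = 0.05,
    min_sites_per_context: int = 10,
    min_site_coverage: int = 0,
) -> pd.DataFrame:
    """Classify each gene's methylation pattern across the three contexts.

    Returns one row per feature with, per context, the number of covered
    body sites (``n_sites_<ctx>``), the number called methylated
    (``n_methylated_<ctx>``), the gene-level binomial p-value and BH
    q-value, plus the final ``label``. Genes with fewer than
    ``min_sites_per_context`` covered sites in any context are
    ``undetermined`` (their p-values are still reported where defined).
    """
    _require_counts(sample)
    if len(features) == 0:
        raise ValueError("no features to classify")
    if background is None:
        background = estimate_background(sample)
    fractions = called_fractions(sample, background, alpha_site, min_site_coverage)

    result = pd.DataFrame({"feature_id": features["feature_id"].to_numpy()})
    n_genes = len(features)
    f_chrom = features["chrom"].to_numpy()
    f_start = features["start"].to_numpy(np.int64)
    f_end = features["end"].to_numpy(np.int64)

    undetermined = np.zeros(n_genes, dtype=bool)
    significant = {}
    for ctx in CONTEXTS:
        sites = sample.subset_context(ctx)
        total_all = (sites["count_m"] + sites["count_u"]).to_numpy(float)
        keep = total_all >= max(min_site_coverage, 1)
        pos0 = sites["pos"].to_numpy(np.int64)[keep] - 1
        m_all = sites["count_m"].to_numpy(float)[keep]
        total_all = total_all[keep]
        chrom_all = sites["chrom"].to_numpy()[keep]

        p_ctx = background.rate(ctx)
        if np.isnan(p_ctx):
            called_all = np.zeros(len(pos0), dtype=bool)
        else:
            called_all = (
                site_is_methylated(m_all, total_all, p_ctx, alpha_site)
                if len(pos0)
                else np.zeros(0, dtype=bool)
            )

        by_chrom = {}
        for chrom in np.unique(chrom_all):
            sel = chrom_all == chrom
            p = pos0[sel]
            order = np.argsort(p, kind="stable")
            by_chrom[chrom] = (p[order], called_all[sel][order])

        n_sites = np.zeros(n_genes, dtype=int)
        n_meth = np.zeros(n_genes, dtype=int)
        for i in range(n_genes):
            entry = by_chrom.get(f_chrom[i])
            if entry is None:
                continue
            p, called = entry
            lo = np.searchsorted(p, f_start[i], side="left")
            hi = np.searchsorted(p, f_end[i], side="left")
            n_sites[i] = hi - lo
            n_meth[i] = int(called[lo:hi].sum())

        frac = fractions[ctx]
        pvals = np.full(n_genes, np.nan)
        testable = n_sites > 0
        if not np.isnan(frac):
            pvals[testable] = binom_tail(n_meth[testable], n_sites[testable], frac)
        qvals = bh_adjust(pvals)

        result[f"n_sites_{ctx}"] = n_sites
        result[f"n_methylated_{ctx}"] = n_meth
        result[f"p_{ctx}"] = pvals
        result[f"q_{ctx}"] = qvals
        undetermined |= n_sites < min_sites_per_context
        significant[ctx] = np.where(np.isnan(qvals), False, qvals <= fdr_level)

    labels = np.full(n_genes, LABEL_UNMETH, dtype=object)
    labels[significant["CG"]] = LABEL_GBM
    te_like = significant["CHG"] | significant["CHH"]
    labels[te_like] = LABEL_TE
    labels[undetermined] = LABEL_UNDET
    result["label"] = labels
    return result
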