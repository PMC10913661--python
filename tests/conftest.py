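import numpy as np
import pytest

from methagene.simulate import Archetype, FixtureSpec, generate
from methagene.types import BinnedDensityMatrix


def matrix_from_density(dens, flank_bins=0, context="CG", ids=None, weight=100.0):
    """Build a BinnedDensityMatrix whose density equals ``dens`` exactly
    (NaN cells get zero support)."""
    dens = np.asarray(dens, dtype=float)
    total = np.where(np.isnan(dens), 0.0, weight)
    m = np.where(np.isnan(dens), 0.0, dens * weight)
    n, b = dens.shape
    body_bins = b - 2 * flank_bins
    return BinnedDensityMatrix(
        region_ids=np.array(ids if ids is not None else [f"g{i}" for i in range(n)]),
        support_m=m,
        support_total=total,
        flank_bins=flank_bins,
        body_bins=body_bins,
        context=context,
    )


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """40-gene two-chromosome synthetic methylome with planted gbM genes."""
    spec = FixtureSpec(
        seed=11,
        n_chromosomes=2,
        chromosome_length=150_000,
        n_genes=40,
        gene_length=(800, 2000),
        intergenic_spacing=1000,
        sites_per_kb={"CG": 15.0, "CHG": 10.0, "CHH": 20.0},
        gbm_fraction=0.2,
    )
    return generate(spec, tmp_path_factory.mktemp("fx_small")), spec


@pytest.fixture(scope="session")
def binning_fixture(tmp_path_factory):
    """200 genes with a planted body-peak archetype, sized so a pure-Python
    per-site oracle stays fast."""
    spec = FixtureSpec(
        seed=23,
        n_chromosomes=2,
        chromosome_length=200_000,
        n_genes=200,
        gene_length=(800, 1600),
        intergenic_spacing=300,
        sites_per_kb={"CG": 10.0, "CHG": 5.0, "CHH": 5.0},
        archetypes=(Archetype("body_peak", base=0.1, peak_pos=0.5, peak_height=0.7),),
        archetype_fractions=(0.5,),
    )
    return generate(spec, tmp_path_factory.mktemp("fx_bin")), spec


@pytest.fixture(scope="session")
def gbm_fixture(tmp_path_factory):
    """Planted-gbM methylome: 1000 genes, 100 gbM (per-site CG rate 0.8 vs
    background 0.05), every gene with at least ~20 covered CG sites."""
    spec = FixtureSpec(
        seed=7,
        n_chromosomes=4,
        chromosome_length=1_400_000,
        n_genes=1000,
        gene_length=(2000, 3200),
        intergenic_spacing=1000,
        sites_per_kb={"CG": 20.0, "CHG": 10.0, "CHH": 12.0},
        background_rates={"CG": 0.05, "CHG": 0.03, "CHH": 0.02},
        gbm_fraction=0.1,
        gbm_within_rate=0.8,
    )
    return generate(spec, tmp_path_factory.mktemp("fx_gbm")), spec
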