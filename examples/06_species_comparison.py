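"""Compare methylation profiles of two 'species' on a common metagene grid.

Species A carries a CG body peak at 40% of the gene body, species B at
60%; each is profiled on its own annotation. The overlay shows both peaks
at their planted positions, and the distribution summary separates the
overall methylation levels.
"""

from pathlib import Path

import numpy as np

from methagene import FixtureSpec, MetageneConfig, build_comparison, compare_distributions, generate
from methagene.simulate import Archetype
from methagene.plotting import plot_profile, save_figure

out = Path("example_output/06")
entries = []
for label, peak, seed in (("species_A", 0.4, 31), ("species_B", 0.6, 32)):
    spec = FixtureSpec(
        seed=seed, n_chromosomes=1, chromosome_length=400_000, n_genes=150,
        gene_length=(1500, 2500), intergenic_spacing=400,
        sites_per_kb={"CG": 25.0, "CHG": 10.0, "CHH": 10.0},
        archetypes=(Archetype("peak", base=0.05, peak_pos=peak,
                              peak_height=0.8, peak_width=0.08),),
        archetype_fractions=(1.0,),
    )
    res = generate(spec, out / label)
    entries.append((res.sample_table(label), res.genes, label))

cfg = MetageneConfig(flank_length=0, body_bins=100, flank_bins=0, context="CG")
comparison = build_comparison(entries, cfg)

for entry in comparison:
    peak_bin = int(np.nanargmax(entry.profile.smoothed_mean))
    print(f"{entry.label}: body peak at bin {peak_bin} of 100")

print("\nper-region density summaries:")
print(compare_distributions(comparison).to_string(index=False))

save_figure(
    plot_profile([e.profile for e in comparison], labels=comparison.labels()),
    out / "overlay.png",
)
print(f"figure written to {out}/")
# Peaks land at bins ~40 and ~60 — each species' signal is computed on its
# own annotation, yet the shared grid makes them directly comparable.
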