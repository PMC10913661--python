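"""Assemble a self-contained HTML report from analysis artifacts.

Runs a metagene analysis, renders its figures, and embeds everything
(base64 images + tables) in a single HTML file that opens offline.
Regenerating from identical artifacts yields identical bytes.
"""

from pathlib import Path

from methagene import FixtureSpec, MetageneConfig, bin_regions, generate, heatmap_matrix, profile
from methagene.plotting import plot_heatmap, plot_profile, save_figure
from methagene.report import render_report

out = Path("example_output/07")
spec = FixtureSpec(seed=3, n_chromosomes=1, chromosome_length=400_000, n_genes=60,
                   gbm_fraction=0.2)
res = generate(spec, out)
sample = res.sample_table()

cfg = MetageneConfig(flank_length=500, body_bins=50, flank_bins=10, context="CG")
matrix = bin_regions(sample, res.genes, cfg)
prof = profile(matrix, cfg)
heat = heatmap_matrix(matrix, n_display_rows=40)

save_figure(plot_profile(prof), out / "profile.png")
save_figure(plot_heatmap(heat), out / "heatmap.png")

render_report(
    {
        "CG metagene profile": [str(out / "profile.png"), prof.to_frame().head(10)],
        "Ranked heatmap": [str(out / "heatmap.png"), heat.ranking.head(10)],
    },
    out / "report.html",
    title="Synthetic methylome — CG metagene report",
)
size = (out / "report.html").stat().st_size
print(f"wrote {out / 'report.html'} ({size} bytes, self-contained)")
# Open the file in any browser: both figures and the tables render without
# network access.
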