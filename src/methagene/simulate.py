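"""Deterministic synthetic-methylome generator.

Emulates the outputs of a bisulfite-sequencing pipeline with fully known
ground truth: a genome of one or more chromosomes carrying non-overlapping
genes, cytosine sites placed at context-specific densities, per-site read
depths drawn from a truncated negative binomial (overdispersed, as real
WGBS coverage is), and methylated read counts drawn binomially from each
site's true methylation rate. Two kinds of structure can be planted:

* **gbM genes** — a fraction of genes whose body CG sites methylate at a
  high within-gene rate against a low genomic background (ground truth for
  the gene-body-methylation classifier);
* **profile archetypes** — named along-the-body rate shapes (flat, body
  peak, TSS dip, ...) assigned to gene groups (ground truth for metagene
  profiles and module clustering).

The same ground truth is written in every supported format (CX report,
CGmap, coverage; GFF3, BED, TSV annotation) so parsers can be checked
against each other, plus a truth table with each gene's class, archetype
and true per-bin CG rate. Generation is a pure function of the spec:
identical specs produce byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from methagene.types import SampleTable

__all__ = ["Archetype", "FixtureSpec", "FixtureResult", "generate"]

_TRINUC = {"CG": "CGA", "CHG": "CAG", "CHH": "CAA"}
_DINUC = {"CG": "CG", "CHG": "CA", "CHH": "CA"}

#: number of body positions at which the truth table records the true CG rate
TRUTH_BINS = 20


@dataclass(frozen=True)
class Archetype:
    """A methylation-rate shape along the gene body (relative coordinate
    x in [0, 1], 5' -> 3').

    rate(x) = base + peak_height * exp(-(x - peak_pos)^2 / (2 * peak_width^2))

    A flat archetype is expressed with ``peak_height = 0``. Negative
    ``peak_height`` carves a dip (e.g. TSS depletion). Rates are clipped
    to [0.001, 0.999].
    """

    name: str
    base: float = 0.1
    peak_pos: float = 0.5
    peak_height: float = 0.0
    peak_width: float = 0.15
    context: str = "CG"

    def rate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        r = self.base + self.peak_height * np.exp(
            -((x - self.peak_pos) ** 2) / (2.0 * self.peak_width**2)
        )
        return np.clip(r, 0.001, 0.999)


@dataclass(frozen=True)
class FixtureSpec:
    """Full description of one synthetic methylome (a pure function of
    these fields, including ``seed``).

    Site densities are sites per kilobase per context; background rates are
    the per-context methylation probabilities outside planted structure.
    Read depth is negative binomial with the given mean and dispersion
    (shape) parameter, truncated at a minimum of one read.
    """

    seed: int = 42
    n_chromosomes: int = 2
    chromosome_length: int = 300_000
    n_genes: int = 100
    gene_length: tuple[int, int] = (1_000, 3_000)
    intergenic_spacing: int = 1_500
    sites_per_kb: dict = field(
        default_factory=lambda: {"CG": 20.0, "CHG": 15.0, "CHH": 30.0}
    )
    background_rates: dict = field(
        default_factory=lambda: {"CG": 0.05, "CHG": 0.03, "CHH": 0.02}
    )
    gbm_fraction: float = 0.0
    gbm_within_rate: float = 0.8
    archetypes: tuple[Archetype, ...] = ()
    archetype_fractions: tuple[float, ...] = ()
    read_depth_mean: float = 20.0
    read_depth_dispersion: float = 5.0

    def __post_init__(self):
        for ctx, r in self.background_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"background rate for {ctx} outside [0,1]")
        if not 0.0 <= self.gbm_fraction <= 1.0:
            raise ValueError("gbm_fraction outside [0,1]")
        if self.archetypes and len(self.archetypes) != len(self.archetype_fractions):
            raise ValueError("archetype_fractions must match archetypes")
        if self.archetype_fractions and sum(self.archetype_fractions) > 1.0 + 1e-9:
            raise ValueError("archetype fractions sum above 1")


@dataclass
class FixtureResult:
    """Generated files plus the in-memory ground truth.

    ``paths`` maps short names (cx_report, cgmap, coverage, gff3, bed, tsv,
    truth_genes) to file paths. ``genes`` includes each gene's class and
    archetype; ``sites`` includes each site's true methylation rate and the
    simulated counts.
    """

    paths: dict
    genes: pd.DataFrame
    sites: pd.DataFrame

    def sample_table(self, sample_id: str = "synthetic") -> SampleTable:
        """Ground-truth sites as a SampleTable, bypassing any parser."""
        df = self.sites.rename(columns={})[
            ["chrom", "pos", "strand", "context", "trinucleotide", "count_m", "count_u"]
        ].copy()
        return SampleTable.from_frame(sample_id, df)


def _place_genes(spec: FixtureSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Lay out non-overlapping genes chromosome by chromosome."""
    per_chrom = np.full(spec.n_chromosomes, spec.n_genes // spec.n_chromosomes)
    per_chrom[: spec.n_genes % spec.n_chromosomes] += 1
    lo, hi = spec.gene_length
    records = []
    gid = 0
    for c in range(spec.n_chromosomes):
        chrom = f"chr{c + 1}"
        cursor = spec.intergenic_spacing
        for _ in range(per_chrom[c]):
            length = int(rng.integers(lo, hi + 1))
            start = cursor
            end = start + length
            if end + spec.intergenic_spacing > spec.chromosome_length:
                raise ValueError(
                    f"genes do not fit: {chrom} needs more than "
                    f"{spec.chromosome_length} bp for {per_chrom[c]} genes — "
                    "increase chromosome_length or reduce n_genes/gene_length"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            records.append((f"gene{gid}", chrom, start, end, strand))
            cursor = end + spec.intergenic_spacing + int(rng.integers(0, spec.intergenic_spacing + 1))
    genes = pd.DataFrame(records, columns=["feature_id", "chrom", "start", "end", "strand"])
    genes["feature_type"] = "gene"
    return genes


def _assign_structure(genes: pd.DataFrame, spec: FixtureSpec, rng: np.random.Generator) -> pd.DataFrame:
    genes = genes.copy()
    n = len(genes)
    is_gbm = np.zeros(n, dtype=bool)
    if spec.gbm_fraction > 0 and n:
        n_gbm = int(round(spec.gbm_fraction * n))
        is_gbm[rng.choice(n, size=n_gbm, replace=False)] = True
    genes["is_gbm"] = is_gbm

    archetype = np.full(n, "background", dtype=object)
    if spec.archetypes and n:
        counts = [int(round(f * n)) for f in spec.archetype_fractions]
        pool = rng.permutation(n)
        offset = 0
        for arch, cnt in zip(spec.archetypes, counts):
            archetype[pool[offset : offset + cnt]] = arch.name
            offset += cnt
    genes["archetype"] = archetype
    return genes


def _site_positions(spec: FixtureSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Sample distinct site positions per chromosome and split them among
    contexts (each cytosine has exactly one context)."""
    contexts = list(spec.sites_per_kb)
    frames = []
    for c in range(spec.n_chromosomes):
        chrom = f"chr{c + 1}"
        n_per_ctx = {
            ctx: int(round(spec.chromosome_length / 1000.0 * dens))
            for ctx, dens in spec.sites_per_kb.items()
        }
        total = sum(n_per_ctx.values())
        pos = rng.choice(spec.chromosome_length, size=total, replace=False) + 1
        offset = 0
        for ctx in contexts:
            k = n_per_ctx[ctx]
            p = np.sort(pos[offset : offset + k])
            offset += k
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": p,
                        "strand": np.where(rng.random(k) < 0.5, "+", "-"),
                        "context": ctx,
                    }
                )
            )
    sites = pd.concat(frames, ignore_index=True)
    return sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def _true_rates(sites: pd.DataFrame, genes: pd.DataFrame, spec: FixtureSpec) -> np.ndarray:
    """Per-site true methylation rate: background, overridden inside gene
    bodies by the gbM rate (CG only) or by the gene's archetype shape."""
    rates = sites["context"].map(spec.background_rates).to_numpy(float)
    arch_by_name = {a.name: a for a in spec.archetypes}
    pos0 = sites["pos"].to_numpy(np.int64) - 1
    ctx = sites["context"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    for g in genes.itertuples(index=False):
        in_body = (chrom == g.chrom) & (pos0 >= g.start) & (pos0 < g.end)
        if not in_body.any():
            continue
        if g.is_gbm:
            rates[in_body & (ctx == "CG")] = spec.gbm_within_rate
        arch = arch_by_name.get(g.archetype)
        if arch is not None:
            sel = in_body & (ctx == arch.context)
            if sel.any():
                rel = (pos0[sel] - g.start) / (g.end - g.start)
                if g.strand == "-":
                    rel = 1.0 - rel
                rates[sel] = arch.rate(rel)
    return rates


def _simulate_counts(rates: np.ndarray, spec: FixtureSpec, rng: np.random.Generator):
    disp, mean = spec.read_depth_dispersion, spec.read_depth_mean
    p = disp / (disp + mean)
    depth = rng.negative_binomial(disp, p, size=len(rates))
    depth = np.maximum(depth, 1)
    count_m = rng.binomial(depth, rates)
    return count_m, depth - count_m


# ---------------------------------------------------------------------------
# writers (plain text, fixed formatting for byte determinism)
# ---------------------------------------------------------------------------


def _write_lines(path, lines) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.writelines(lines)


def _fmt_level(m: int, total: int) -> str:
    return format(m / total, ".6g")


def _write_methylation(sites: pd.DataFrame, outdir: Path, stem: str) -> dict:
    paths = {
        "cx_report": outdir / f"{stem}.CX_report.txt",
        "cgmap": outdir / f"{stem}.CGmap",
        "coverage": outdir / f"{stem}.cov",
        "bedgraph": outdir / f"{stem}.bedGraph",
    }
    cx, cg, cov, bg = [], [], [], []
    for s in sites.itertuples(index=False):
        m, u = int(s.count_m), int(s.count_u)
        total = m + u
        tri = _TRINUC[s.context]
        cx.append(f"{s.chrom}\t{s.pos}\t{s.strand}\t{m}\t{u}\t{s.context}\t{tri}\n")
        nuc = "C" if s.strand == "+" else "G"
        cg.append(
            f"{s.chrom}\t{nuc}\t{s.pos}\t{s.context}\t{_DINUC[s.context]}\t"
            f"{_fmt_level(m, total)}\t{m}\t{total}\n"
        )
        pct = format(100.0 * m / total, ".6g")
        cov.append(f"{s.chrom}\t{s.pos}\t{s.pos}\t{pct}\t{m}\t{u}\n")
        bg.append(f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{pct}\n")
    _write_lines(paths["cx_report"], cx)
    _write_lines(paths["cgmap"], cg)
    _write_lines(paths["coverage"], cov)
    _write_lines(paths["bedgraph"], bg)
    return {k: str(v) for k, v in paths.items()}


def _write_annotations(genes: pd.DataFrame, outdir: Path, stem: str) -> dict:
    paths = {
        "gff3": outdir / f"{stem}.gff3",
        "bed": outdir / f"{stem}.bed",
        "tsv": outdir / f"{stem}.genes.tsv",
    }
    gff = ["##gff-version 3\n"]
    bed, tsv = [], ["id\tchrom\tstart\tend\tstrand\n"]
    for g in genes.itertuples(index=False):
        gff.append(
            f"{g.chrom}\tmethagene\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={g.feature_id}\n"
        )
        bed.append(f"{g.chrom}\t{g.start}\t{g.end}\t{g.feature_id}\t0\t{g.strand}\n")
        tsv.append(f"{g.feature_id}\t{g.chrom}\t{g.start + 1}\t{g.end}\t{g.strand}\n")
    _write_lines(paths["gff3"], gff)
    _write_lines(paths["bed"], bed)
    _write_lines(paths["tsv"], tsv)
    return {k: str(v) for k, v in paths.items()}


def _truth_table(genes: pd.DataFrame, spec: FixtureSpec) -> pd.DataFrame:
    """True CG methylation rate at TRUTH_BINS body-bin midpoints per gene
    (5' -> 3'), alongside class and archetype."""
    arch_by_name = {a.name: a for a in spec.archetypes}
    x = (np.arange(TRUTH_BINS) + 0.5) / TRUTH_BINS
    rows = []
    for g in genes.itertuples(index=False):
        if g.is_gbm:
            rate = np.full(TRUTH_BINS, spec.gbm_within_rate)
        else:
            arch = arch_by_name.get(g.archetype)
            if arch is not None and arch.context == "CG":
                rate = arch.rate(x)
            else:
                rate = np.full(TRUTH_BINS, spec.background_rates.get("CG", np.nan))
        row = {
            "feature_id": g.feature_id,
            "chrom": g.chrom,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "true_class": "gbM" if g.is_gbm else "background",
            "archetype": g.archetype,
        }
        row.update({f"true_cg_rate_bin_{j}": rate[j] for j in range(TRUTH_BINS)})
        rows.append(row)
    return pd.DataFrame.from_records(rows)


def generate(spec: FixtureSpec, outdir) -> FixtureResult:
    """Generate the synthetic methylome described by ``spec`` into
    ``outdir`` and return paths plus ground truth.

    All methylation formats (CX report, CGmap, coverage, bedGraph) and all
    annotation formats (GFF3, BED, TSV) encode the identical ground truth.
    Raises if the requested genes cannot fit on the chromosomes.
    """
    outdir = Path(os.fspath(outdir))
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    genes = _place_genes(spec, rng)
    genes = _assign_structure(genes, spec, rng)
    sites = _site_positions(spec, rng)
    rates = _true_rates(sites, genes, spec)
    count_m, count_u = _simulate_counts(rates, spec, rng)
    sites = sites.assign(
        true_rate=rates,
        count_m=count_m.astype(float),
        count_u=count_u.astype(float),
        trinucleotide=sites["context"].map(_TRINUC),
    )

    stem = f"synthetic_seed{spec.seed}"
    paths = _write_methylation(sites, outdir, stem)
    paths.update(_write_annotations(genes, outdir, stem))

    truth = _truth_table(genes, spec)
    truth_path = outdir / f"{stem}.truth_genes.tsv"
    # fixed float formatting keeps generation byte-deterministic
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.6g",
                 lineterminator="\n")
    paths["truth_genes"] = str(truth_path)

    return FixtureResult(paths=paths, genes=genes, sites=sites)
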