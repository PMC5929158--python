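"""Truth-labelled synthetic data for every pipeline stage.

The generator emulates the regulatory architecture the analyses assume: a
gene-desert-like locus per gene with one TSS, CTCF sites spaced on average
every 10 kb, a docking CTCF site ~2 kb upstream of planted docking genes'
TSSs, cell-type-specific (super-)enhancer clusters, PETs mixing planted
docking loops with distance-decaying background, 4C profiles in wild-type
vs docking-site-deleted conditions, and motif-bearing sequences with an
elevated conservation track. Every generator derives an independent random
substream from the root seed keyed by its own name, so adding a generator
does not perturb the others, and all outputs are deterministic given the
seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, Peak, Tss
from .fourc import FragmentMap
from . import io as dio

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "GenomeData",
    "generate_genome",
    "generate_pets",
    "generate_fourc",
    "generate_sequence_with_motifs",
    "sequences_for_peaks",
    "synthetic_ctcf_pwm",
    "substream",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """An independent generator keyed by (root seed, stream name)."""
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), zlib.crc32(name.encode())))
    )


@dataclass
class SimulationConfig:
    """All knobs of the simulator, with the locus-scale defaults the
    analyses assume (TAD size 2.8 Mb, CTCF every ~10 kb, docking site 2 kb
    upstream of the TSS, super-enhancers up to 200 kb; depths and counts
    are desk-scale choices)."""

    seed: int = 0
    n_chroms: int = 3
    chrom_len: int = 5_000_000
    n_tss: int = 72
    tad_len: int = 2_800_000
    ctcf_spacing_mean: int = 10_000
    ctcf_peak_width: int = 400
    docking_offset: int = 2_000
    docking_fraction: float = 0.75
    n_cell_types: int = 3
    se_len_max: int = 200_000
    expr_threshold: float = 1.0
    pet_background_rate: float = 100.0   # background PETs per anchor peak
    pet_loop_lambda: float = 50.0
    decay_exponent: float = 1.0
    duplicate_fraction: float = 0.1
    min_pet_span: int = 4_000
    fourc_reads_per_rep: int = 100_000
    fourc_n_reps: int = 3
    fourc_frag_len_mean: int = 4_000
    fourc_enrichment: float = 6.0
    deletion_contact_scale: float = 0.4
    blind_fraction: float = 0.15

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_len", "n_tss", "tad_len", "ctcf_spacing_mean",
                     "ctcf_peak_width", "docking_offset", "n_cell_types", "se_len_max",
                     "fourc_reads_per_rep", "fourc_n_reps", "fourc_frag_len_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.deletion_contact_scale <= 1.0):
            raise ValueError("deletion_contact_scale must lie in [0, 1]")
        if not (0.0 <= self.blind_fraction < 1.0):
            raise ValueError("blind_fraction must lie in [0, 1)")
        if not (0.0 <= self.duplicate_fraction < 1.0):
            raise ValueError("duplicate_fraction must lie in [0, 1)")
        if not (0.0 < self.docking_fraction <= 1.0):
            raise ValueError("docking_fraction must lie in (0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return [f"cell{i + 1}" for i in range(self.n_cell_types)]

    def to_yaml(self, path: str | Path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class TruthTable:
    """Ground truth for parameter-recovery checks."""

    docking_tss: dict[str, set[str]] = field(default_factory=dict)
    # (cell_type, anchorA interval, anchorB interval, lambda)
    planted_loops: list[tuple[str, GenomicInterval, GenomicInterval, float]] = field(default_factory=list)
    # (region, contact scale applied in the deleted condition)
    fourc_true_regions: list[tuple[GenomicInterval, float]] = field(default_factory=list)
    fourc_viewpoint: GenomicInterval | None = None
    # (record name, offset, strand)
    planted_motifs: list[tuple[str, int, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cell, genes in sorted(self.docking_tss.items()):
            for gene in sorted(genes):
                rows.append(dict(kind="docking", cell_type=cell, gene=gene))
        for cell, a, b, lam in self.planted_loops:
            rows.append(dict(kind="loop", cell_type=cell, chrom=a.chrom,
                             start=a.start, end=a.end, start2=b.start,
                             end2=b.end, value=lam))
        for region, scale in self.fourc_true_regions:
            rows.append(dict(kind="fourc_region", chrom=region.chrom,
                             start=region.start, end=region.end, value=scale))
        if self.fourc_viewpoint is not None:
            v = self.fourc_viewpoint
            rows.append(dict(kind="viewpoint", chrom=v.chrom, start=v.start, end=v.end))
        for record, offset, strand in self.planted_motifs:
            rows.append(dict(kind="motif", gene=record, start=offset, strand=strand))
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t")
        truth = cls()
        for row in df.itertuples(index=False):
            kind = row.kind
            if kind == "docking":
                truth.docking_tss.setdefault(str(row.cell_type), set()).add(str(row.gene))
            elif kind == "loop":
                truth.planted_loops.append((
                    str(row.cell_type),
                    GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                    GenomicInterval(str(row.chrom), int(row.start2), int(row.end2)),
                    float(row.value),
                ))
            elif kind == "fourc_region":
                truth.fourc_true_regions.append((
                    GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                    float(row.value),
                ))
            elif kind == "viewpoint":
                truth.fourc_viewpoint = GenomicInterval(str(row.chrom), int(row.start), int(row.end))
            elif kind == "motif":
                truth.planted_motifs.append((str(row.gene), int(row.start), str(row.strand)))
        return truth


@dataclass
class GenomeData:
    """Everything :func:`generate_genome` produces."""

    config: SimulationConfig
    chrom_sizes: dict[str, int]
    tss_catalog: list[Tss]
    ctcf: dict[str, list[Peak]]
    h3k27ac: dict[str, list[Peak]]
    truth: TruthTable

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dio.write_chrom_sizes(self.chrom_sizes, outdir / "chrom.sizes")
        dio.write_tss_catalog(self.tss_catalog, outdir / "tss.tsv")
        for cell in self.config.cell_types:
            dio.write_bed(self.ctcf[cell], outdir / f"ctcf_{cell}.bed")
            dio.write_bed(self.h3k27ac[cell], outdir / f"h3k27ac_{cell}.bed")
        self.truth.to_tsv(outdir / "truth.tsv")
        self.config.to_yaml(outdir / "sim_config.yaml")


# Venn membership patterns over 3 cell types and their sampling weights:
# most planted docking genes are specific to one cell type, a minority are
# shared, a small core is common to all three.
_PATTERNS_3 = [(0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2)]
_PATTERN_W_3 = np.array([0.20, 0.20, 0.20, 0.08, 0.08, 0.08, 0.16])


def _membership_patterns(n_cells: int) -> tuple[list[tuple[int, ...]], np.ndarray]:
    if n_cells == 3:
        return _PATTERNS_3, _PATTERN_W_3
    from itertools import combinations
    pats = [p for r in range(1, n_cells + 1) for p in combinations(range(n_cells), r)]
    w = np.array([0.6 / n_cells if len(p) == 1 else 0.4 / (len(pats) - n_cells)
                  for p in pats]) if len(pats) > n_cells else np.ones(len(pats))
    return pats, w / w.sum()


def _peak(chrom: str, center: int, width: int, chrom_len: int,
          signal: float, name: str) -> Peak:
    start = int(np.clip(center - width // 2, 0, chrom_len - width))
    iv = GenomicInterval(chrom, start, start + width)
    return Peak(iv, summit=iv.midpoint, signal=signal, name=name)


def generate_genome(config: SimulationConfig) -> GenomeData:
    """Simulate chromosome sizes, the TSS catalog, CTCF and H3K27Ac peak
    sets per cell type, and the truth table.

    Each gene owns a disjoint territory (its miniature TAD); planted
    docking genes receive a constitutive CTCF peak ``docking_offset`` bp
    upstream of the TSS and, in each cell type where they dock, a
    super-enhancer-sized H3K27Ac cluster harbouring a CTCF site, connected
    by a planted loop. Backbone CTCF peaks follow exponential spacing with
    mean ``ctcf_spacing_mean``; roughly half are constitutive.
    """
    cfg = config
    genes_per_chrom = int(np.ceil(cfg.n_tss / cfg.n_chroms))
    territory = cfg.chrom_len // genes_per_chrom
    if territory < 80_000:
        raise ValueError(
            f"gene territories of {territory} bp overflow the chromosome; "
            "increase chrom_len or reduce n_tss"
        )
    rng = substream(cfg.seed, "genome")
    cells = cfg.cell_types
    chrom_sizes = {f"chr{i + 1}": cfg.chrom_len for i in range(cfg.n_chroms)}
    chroms = list(chrom_sizes)

    n_docking = int(round(cfg.docking_fraction * cfg.n_tss))
    docking_genes = set(rng.permutation(cfg.n_tss)[:n_docking].tolist())
    patterns, pattern_w = _membership_patterns(cfg.n_cell_types)

    tss_catalog: list[Tss] = []
    ctcf: dict[str, list[Peak]] = {c: [] for c in cells}
    h3k27ac: dict[str, list[Peak]] = {c: [] for c in cells}
    truth = TruthTable(docking_tss={c: set() for c in cells})
    se_clusters: dict[tuple[str, str], GenomicInterval] = {}  # (gene, cell) -> hull

    for g in range(cfg.n_tss):
        chrom = chroms[g // genes_per_chrom]
        t0 = (g % genes_per_chrom) * territory
        t1 = t0 + territory
        gene = f"gene{g + 1:03d}"
        tss_pos = t0 + territory // 2 + int(rng.integers(-2000, 2001))
        strand = "+" if rng.random() < 0.5 else "-"
        pattern = patterns[rng.choice(len(patterns), p=pattern_w)] if g in docking_genes else ()

        expression: dict[str, float] = {}
        for ci, cell in enumerate(cells):
            if ci in pattern:
                expression[cell] = float(rng.uniform(5, 20))
            else:
                expression[cell] = float(rng.uniform(2, 15)) if rng.random() < 0.5 else 0.0
        tss_catalog.append(Tss(gene, chrom, tss_pos, strand, expression))

        if pattern:
            upstream = tss_pos - cfg.docking_offset if strand == "+" else tss_pos + cfg.docking_offset
            dock_peak = _peak(chrom, upstream, cfg.ctcf_peak_width, cfg.chrom_len,
                              signal=float(rng.uniform(30, 80)), name=f"{gene}_dock")
            for cell in cells:  # docking sites are constitutively CTCF-bound
                ctcf[cell].append(dock_peak)

        for ci, cell in enumerate(cells):
            if ci in pattern:
                truth.docking_tss[cell].add(gene)
                # super-enhancer-sized H3K27Ac cluster, kept >= 10 kb clear
                # of the TSS so no constituent falls in the promoter window
                max_reach = min(cfg.se_len_max, territory // 2 - 15_000)
                dist = int(rng.uniform(30_000, max(max_reach, 31_000)))
                side = 1 if rng.random() < 0.5 else -1
                anchor_pos = tss_pos + side * dist
                k = int(rng.integers(3, 8))
                widths = rng.integers(800, 2500, size=k)
                gaps = rng.integers(3_000, 10_000, size=k - 1) if k > 1 else np.array([], int)
                span = int(widths.sum() + gaps.sum())
                if side > 0:
                    bound_lo, bound_hi = tss_pos + 10_000, t1 - 5_000
                else:
                    bound_lo, bound_hi = t0 + 5_000, tss_pos - 10_000
                lo = int(np.clip(anchor_pos - span // 2, bound_lo, bound_hi - span))
                pos = lo
                members: list[Peak] = []
                for m in range(k):
                    piv = GenomicInterval(chrom, pos, pos + int(widths[m]))
                    members.append(Peak(piv, summit=piv.midpoint,
                                        signal=float(rng.uniform(30, 80)),
                                        name=f"{gene}_{cell}_se{m}"))
                    pos = piv.end + (int(gaps[m]) if m < k - 1 else 0)
                h3k27ac[cell].extend(members)
                hull = GenomicInterval(chrom, members[0].start, members[-1].end)
                se_clusters[(gene, cell)] = hull
                mid_member = members[len(members) // 2]
                enh_ctcf = _peak(chrom, mid_member.interval.midpoint,
                                 cfg.ctcf_peak_width, cfg.chrom_len,
                                 signal=float(rng.uniform(20, 60)),
                                 name=f"{gene}_{cell}_se_ctcf")
                ctcf[cell].append(enh_ctcf)
                truth.planted_loops.append(
                    (cell, dock_peak.interval, enh_ctcf.interval, float(cfg.pet_loop_lambda))
                )
            if expression[cell] > 0:
                # promoter H3K27Ac (dropped by the promoter filter downstream)
                h3k27ac[cell].append(_peak(chrom, tss_pos, 2_000, cfg.chrom_len,
                                           signal=float(rng.uniform(10, 30)),
                                           name=f"{gene}_{cell}_prom"))
                if rng.random() < 0.5:  # an unlooped typical enhancer
                    d = int(rng.uniform(20_000, territory // 2 - 10_000))
                    side = 1 if rng.random() < 0.5 else -1
                    h3k27ac[cell].append(_peak(chrom, tss_pos + side * d,
                                               int(rng.integers(800, 2000)),
                                               cfg.chrom_len,
                                               signal=float(rng.uniform(1, 8)),
                                               name=f"{gene}_{cell}_te"))

    # backbone CTCF peaks with exponential spacing; ~half constitutive
    for chrom in chroms:
        pos = 0.0
        idx = 0
        while True:
            pos += rng.exponential(cfg.ctcf_spacing_mean) + cfg.ctcf_peak_width
            if pos + cfg.ctcf_peak_width >= cfg.chrom_len:
                break
            peak = _peak(chrom, int(pos), cfg.ctcf_peak_width, cfg.chrom_len,
                         signal=float(rng.uniform(5, 50)), name=f"{chrom}_bb{idx}")
            idx += 1
            if rng.random() < 0.5:
                for cell in cells:
                    ctcf[cell].append(peak)
            else:
                present = [cell for cell in cells if rng.random() < 0.6]
                for cell in present:
                    ctcf[cell].append(peak)

    for cell in cells:
        ctcf[cell].sort(key=lambda p: (p.chrom, p.start, p.end))
        h3k27ac[cell].sort(key=lambda p: (p.chrom, p.start, p.end))

    # 4C truth: viewpoint at the first docking gene of the first cell type,
    # quantification regions at that cell type's SE hulls on the same chromosome
    first_cell = cells[0]
    vp_genes = sorted(truth.docking_tss[first_cell])
    if vp_genes:
        vp_gene = vp_genes[0]
        for cell_list in (ctcf[first_cell],):
            for p in cell_list:
                if p.name == f"{vp_gene}_dock":
                    truth.fourc_viewpoint = p.interval
                    break
        vp_chrom = truth.fourc_viewpoint.chrom
        regions = [se_clusters[(g, first_cell)] for g in vp_genes
                   if se_clusters[(g, first_cell)].chrom == vp_chrom]
        truth.fourc_true_regions = [(r, cfg.deletion_contact_scale) for r in regions[:4]]

    return GenomeData(config=cfg, chrom_sizes=chrom_sizes, tss_catalog=tss_catalog,
                      ctcf=ctcf, h3k27ac=h3k27ac, truth=truth)


def _sample_powerlaw(rng: np.random.Generator, n: int, alpha: float,
                     dmin: float, dmax: float) -> np.ndarray:
    """Inverse-CDF samples from density proportional to d**-alpha on [dmin, dmax]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-9:
        return dmin * (dmax / dmin) ** u
    e = 1.0 - alpha
    return (dmin ** e + u * (dmax ** e - dmin ** e)) ** (1.0 / e)


def generate_pets(genome: GenomeData, cell_type: str,
                  seed: int | None = None) -> list:
    """PETs for one cell type: distance-decaying background anchored in the
    cell's CTCF peaks, Poisson loop PETs at every planted loop, and a
    configurable fraction of exact duplicates."""
    from .interactions import PairedTag

    cfg = genome.config
    rng = substream(cfg.seed if seed is None else seed, f"pets:{cell_type}")
    anchors = genome.ctcf[cell_type]
    chrom_len = cfg.chrom_len
    pets: list[PairedTag] = []

    n_bg = int(round(cfg.pet_background_rate * len(anchors)))
    if n_bg > 0:
        which = rng.integers(0, len(anchors), n_bg)
        starts = np.array([anchors[i].start for i in which])
        widths = np.array([len(anchors[i].interval) for i in which])
        chrom_names = [anchors[i].chrom for i in which]
        pos1 = starts + rng.integers(0, widths)
        d = _sample_powerlaw(rng, n_bg, cfg.decay_exponent,
                             cfg.min_pet_span, chrom_len - 1)
        sign = np.where(rng.random(n_bg) < 0.5, 1, -1)
        pos2 = pos1 + (sign * d).astype(int)
        bad = (pos2 < 0) | (pos2 >= chrom_len)
        while bad.any():  # redraw out-of-chromosome partners
            nb = int(bad.sum())
            d = _sample_powerlaw(rng, nb, cfg.decay_exponent,
                                 cfg.min_pet_span, chrom_len - 1)
            sign = np.where(rng.random(nb) < 0.5, 1, -1)
            pos2[bad] = pos1[bad] + (sign * d).astype(int)
            bad = (pos2 < 0) | (pos2 >= chrom_len)
        s1 = np.where(rng.random(n_bg) < 0.5, "+", "-")
        s2 = np.where(rng.random(n_bg) < 0.5, "+", "-")
        for i in range(n_bg):
            pets.append(PairedTag.make(chrom_names[i], int(pos1[i]), str(s1[i]),
                                       chrom_names[i], int(pos2[i]), str(s2[i])))

    for cell, a, b, lam in genome.truth.planted_loops:
        if cell != cell_type or lam <= 0:
            continue
        n = int(rng.poisson(lam))
        pa = rng.integers(a.start, a.end, n)
        pb = rng.integers(b.start, b.end, n)
        sa = np.where(rng.random(n) < 0.5, "+", "-")
        sb = np.where(rng.random(n) < 0.5, "+", "-")
        for i in range(n):
            pets.append(PairedTag.make(a.chrom, int(pa[i]), str(sa[i]),
                                       b.chrom, int(pb[i]), str(sb[i])))

    if cfg.duplicate_fraction > 0 and pets:
        n_dup = int(round(cfg.duplicate_fraction / (1 - cfg.duplicate_fraction) * len(pets)))
        for i in rng.integers(0, len(pets), n_dup):
            pets.append(pets[int(i)])
    order = rng.permutation(len(pets))
    return [pets[int(i)] for i in order]


def generate_fourc(
    genome: GenomeData,
    condition: str = "wild_type",
    viewpoint: GenomicInterval | None = None,
    seed: int | None = None,
) -> tuple[FragmentMap, dict[str, np.ndarray]]:
    """One 4C experiment: a fragment map on the viewpoint chromosome and
    per-replicate mapped-read positions.

    Per-fragment expectations decay with distance from the viewpoint
    (power law, floored at 4 kb), multiplied by ``fourc_enrichment`` over
    the planted true regions, and by ``deletion_contact_scale`` over those
    regions in the ``deleted`` condition; replicate counts are Poisson.
    """
    if condition not in ("wild_type", "deleted"):
        raise ValueError("condition must be 'wild_type' or 'deleted'")
    cfg = genome.config
    vp = viewpoint or genome.truth.fourc_viewpoint
    if vp is None:
        raise ValueError("no viewpoint: supply one or plant docking genes")
    root = cfg.seed if seed is None else seed
    chrom = vp.chrom
    chrom_len = genome.chrom_sizes[chrom]
    if not (0 <= vp.start and vp.end <= chrom_len):
        raise ValueError("viewpoint outside the chromosome")

    # primary cutter: exponential fragment lengths; no cut inside the
    # viewpoint. The digest is a property of the genome, so the fragment map
    # substream is shared by both conditions — only the counts differ.
    rng_map = substream(root, "fourc:fragments")
    n_draw = int(chrom_len / cfg.fourc_frag_len_mean * 2) + 100
    cuts = np.cumsum(rng_map.exponential(cfg.fourc_frag_len_mean, n_draw)).astype(int)
    cuts = np.unique(cuts[(cuts > 0) & (cuts < chrom_len)])
    cuts = cuts[(cuts <= vp.start) | (cuts >= vp.end)]
    bounds = np.concatenate([[0], cuts, [chrom_len]])
    frags = [GenomicInterval(chrom, int(a), int(b)) for a, b in zip(bounds, bounds[1:])]
    blind = rng_map.random(len(frags)) < cfg.blind_fraction
    fmap = FragmentMap(fragments={chrom: frags}, blind={chrom: blind})
    rng = substream(root, f"fourc:{condition}")

    mids = np.array([f.midpoint for f in frags], dtype=float)
    d = np.abs(mids - vp.midpoint)
    mu = np.maximum(d, 4_000.0) ** (-cfg.decay_exponent)
    for region, scale in genome.truth.fourc_true_regions:
        if region.chrom != chrom:
            continue
        sel = (mids >= region.start) & (mids < region.end)
        mu[sel] *= cfg.fourc_enrichment
        if condition == "deleted":
            mu[sel] *= scale
    # depth calibrated on the wild-type expectation so that losing contact
    # in the deleted condition lowers its total signal, as it would on a
    # fixed-efficiency library, rather than being renormalized away
    mu_wt_total = (np.maximum(d, 4_000.0) ** (-cfg.decay_exponent)).sum()
    for region, _ in genome.truth.fourc_true_regions:
        if region.chrom != chrom:
            continue
        sel = (mids >= region.start) & (mids < region.end)
        base = np.maximum(d[sel], 4_000.0) ** (-cfg.decay_exponent)
        mu_wt_total += base.sum() * (cfg.fourc_enrichment - 1.0)
    mu *= cfg.fourc_reads_per_rep / mu_wt_total

    starts = bounds[:-1]
    lengths = np.diff(bounds)
    reads: dict[str, np.ndarray] = {}
    for r in range(cfg.fourc_n_reps):
        counts = rng.poisson(mu)
        pos = (np.repeat(starts, counts)
               + np.floor(rng.random(int(counts.sum())) * np.repeat(lengths, counts)).astype(int))
        reads[f"rep{r + 1}"] = pos
    return fmap, reads


def synthetic_ctcf_pwm() -> np.ndarray:
    """A synthetic 19-column CTCF-like count matrix (NOT a database motif):
    a strongly informative core with a few degenerate columns, adequate for
    exercising the scanner and the conservation meta-profile."""
    consensus = "CCACCAGGGGGCGCTAGTT"
    pwm = np.full((4, len(consensus)), 4.0)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for j, base in enumerate(consensus):
        pwm[idx[base], j] = 88.0
    for j in (4, 11, 17):  # degenerate columns
        pwm[:, j] = 25.0
    return pwm


def generate_sequence_with_motifs(
    pwm: np.ndarray,
    placements: Sequence[tuple[str, int, str]],
    record_lengths: dict[str, int],
    seed: int = 0,
    baseline: float = 0.1,
    elevated: float = 0.8,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Random sequences with motif instances planted at given placements.

    Background bases are i.i.d. uniform; each placement ``(record, offset,
    strand)`` receives an instance sampled column-wise from the PWM's count
    frequencies, reverse-complemented for - strand placements. The second
    return value is a bedGraph-style conservation table: ``baseline``
    everywhere, ``elevated`` over motif bases. Overlapping placements
    within a record are an error.
    """
    pwm = np.asarray(pwm, dtype=float)
    if np.any(pwm.sum(axis=0) <= 0):
        raise ValueError("PWM columns must have positive sums")
    width = pwm.shape[1]
    probs = pwm / pwm.sum(axis=0)
    rng = substream(seed, "sequence")
    bases = np.array(list("ACGT"))

    by_record: dict[str, list[tuple[int, str]]] = {}
    for record, offset, strand in placements:
        if record not in record_lengths:
            raise ValueError(f"unknown record {record!r}")
        if not (0 <= offset and offset + width <= record_lengths[record]):
            raise ValueError(f"placement at {record}:{offset} exceeds the record")
        by_record.setdefault(record, []).append((offset, strand))
    for record, placed in by_record.items():
        placed.sort()
        for (o1, _), (o2, _) in zip(placed, placed[1:]):
            if o2 < o1 + width:
                raise ValueError(f"overlapping placements in {record!r}")

    records: list[SeqRecord] = []
    cons_rows = []
    for record in record_lengths:
        length = record_lengths[record]
        seq = bases[rng.integers(0, 4, length)]
        for offset, strand in by_record.get(record, []):
            inst = np.array([bases[rng.choice(4, p=probs[:, j])] for j in range(width)])
            if strand == "-":
                inst = np.array(list(str(Seq("".join(inst)).reverse_complement())))
            seq[offset:offset + width] = inst
        records.append(SeqRecord(Seq("".join(seq)), id=record, description=""))
        pos = 0
        for offset, _ in by_record.get(record, []):
            if offset > pos:
                cons_rows.append((record, pos, offset, baseline))
            cons_rows.append((record, offset, offset + width, elevated))
            pos = offset + width
        if pos < length:
            cons_rows.append((record, pos, length, baseline))
    cons = pd.DataFrame(cons_rows, columns=["chrom", "start", "end", "value"])
    return records, cons


def sequences_for_peaks(
    pwm: np.ndarray,
    peaks: Sequence[Peak],
    seed: int = 0,
    flank: int = 500,
) -> tuple[list[SeqRecord], pd.DataFrame, list[tuple[str, int, str]]]:
    """Sequence neighbourhoods (peak +/- ``flank``) with one motif planted
    at each peak's centre on a random strand; returns (records,
    conservation table, placements). Record ids encode the peak span."""
    width = np.asarray(pwm).shape[1]
    rng = substream(seed, "placements")
    record_lengths: dict[str, int] = {}
    placements: list[tuple[str, int, str]] = []
    for p in peaks:
        name = f"{p.chrom}_{p.start}_{p.end}"
        length = len(p.interval) + 2 * flank
        record_lengths[name] = length
        offset = (length - width) // 2
        strand = "+" if rng.random() < 0.5 else "-"
        placements.append((name, offset, strand))
    records, cons = generate_sequence_with_motifs(pwm, placements, record_lengths, seed=seed)
    return records, cons, placements
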