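"""Enhancer-docking-site discovery and characterization.

A gene has a putative CTCF enhancer-docking site when (i) its TSS is
active in the cell type under study, (ii) a CTCF peak lies within a small
radius of the TSS (2.5 kb by default), and (iii) a filtered chromatin
interaction links that peak to at least one active enhancer. The module
also provides the characterizations used around the docking-site call:
constitutive-CTCF intersection across cell types, Venn decomposition of
docking gene sets, PWM motif scanning with JASPAR-style relative scores,
and strand-oriented conservation meta-profiles over best motif hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, Peak, Tss, overlap_join, overlaps, window_around
from .interactions import ChromatinInteraction
from .enhancers import Enhancer
from .io import ValueTrack

__all__ = [
    "DockingCall",
    "MotifHit",
    "classify_active_tss",
    "find_docking_tss",
    "docking_gene_sets",
    "constitutive_ctcf",
    "docking_overlap_venn",
    "scan_motifs",
    "best_motif_per_peak",
    "conservation_metaprofile",
]


@dataclass(frozen=True)
class DockingCall:
    """An active TSS linked through a nearby CTCF peak to >=1 active enhancer."""

    tss: Tss
    ctcf_peak: Peak
    supporting: tuple[ChromatinInteraction, ...]
    cell_type: str

    def __post_init__(self) -> None:
        if not self.supporting:
            raise ValueError("docking call requires >=1 supporting interaction")


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    strand: str
    log_odds: float
    relative_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.relative_score <= 1.0 + 1e-12):
            raise ValueError("relative_score must lie in [0, 1]")


def classify_active_tss(
    tss_catalog: Sequence[Tss], cell_type: str, threshold: float
) -> list[Tss]:
    """TSSs whose expression in ``cell_type`` is >= ``threshold``."""
    missing = [t for t in tss_catalog if cell_type not in t.expression]
    if missing:
        raise KeyError(f"no expression column for cell type {cell_type!r}")
    return [t for t in tss_catalog if t.expression[cell_type] >= threshold]


def find_docking_tss(
    active_tss: Sequence[Tss],
    ctcf_peaks: Sequence[Peak],
    interactions: Sequence[ChromatinInteraction],
    enhancers: Sequence[Enhancer],
    chrom_sizes: Mapping[str, int],
    cell_type: str = ".",
    radius: int = 2500,
    summit_mode: bool = False,
) -> list[DockingCall]:
    """The docking-site caller.

    For each active TSS, CTCF peaks intersecting TSS +/- ``radius`` are
    candidate docking peaks (``summit_mode`` requires the peak summit inside
    the window instead); a call is made per (TSS, peak) when some supplied
    interaction has one anchor overlapping the peak and the other anchor
    overlapping >=1 enhancer. Interactions are expected to be pre-filtered
    to the analysis thresholds.
    """
    if not interactions:
        return []
    peak_ivs = [p.interval for p in ctcf_peaks]
    enh_ivs = [e.interval for e in enhancers]
    anchorA_ivs = [x.anchorA.interval for x in interactions]
    anchorB_ivs = [x.anchorB.interval for x in interactions]

    a_enh = {i for i, _ in overlap_join(anchorA_ivs, enh_ivs)}
    b_enh = {i for i, _ in overlap_join(anchorB_ivs, enh_ivs)}
    # interactions attached to each CTCF peak through either anchor, with the
    # partner anchor's enhancer status resolved per side
    peak_to_support: dict[int, list[int]] = {}
    for k, x in overlap_join(peak_ivs, anchorA_ivs):
        if x in b_enh:
            peak_to_support.setdefault(k, []).append(x)
    for k, x in overlap_join(peak_ivs, anchorB_ivs):
        if x in a_enh:
            peak_to_support.setdefault(k, []).append(x)

    calls: list[DockingCall] = []
    for t in active_tss:
        clen = chrom_sizes.get(t.chrom)
        if clen is None or not (0 <= t.pos < clen):
            continue
        win = window_around(t.pos, radius, t.chrom, clen)
        for k, p in enumerate(ctcf_peaks):
            if summit_mode:
                near = p.chrom == win.chrom and win.contains(p.summit)
            else:
                near = overlaps(win, p.interval)
            if not near:
                continue
            support = sorted(set(peak_to_support.get(k, [])))
            if support:
                calls.append(DockingCall(
                    tss=t, ctcf_peak=p,
                    supporting=tuple(interactions[x] for x in support),
                    cell_type=cell_type,
                ))
    return calls


def docking_gene_sets(calls: Sequence[DockingCall]) -> dict[str, set[str]]:
    """Docking gene ids per cell type; a gene counts once regardless of how
    many nearby peaks support it."""
    out: dict[str, set[str]] = {}
    for c in calls:
        out.setdefault(c.cell_type, set()).add(c.tss.gene)
    return out


def constitutive_ctcf(peak_sets: Sequence[Sequence[Peak]]) -> list[Peak]:
    """Peaks of the first (reference) set that are overlapped (>=1 bp) by at
    least one peak in every other set. With a single input set every
    reference peak is constitutive (vacuous quantifier)."""
    if not peak_sets:
        raise ValueError("need >= 1 peak set")
    reference = list(peak_sets[0])
    keep = set(range(len(reference)))
    ref_ivs = [p.interval for p in reference]
    for other in peak_sets[1:]:
        hit = {i for i, _ in overlap_join(ref_ivs, [p.interval for p in other])}
        keep &= hit
    return [reference[i] for i in sorted(keep)]


def docking_overlap_venn(sets: Mapping[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Venn-region counts over 2 or 3 gene-id sets.

    Keys are sorted tuples of set names; the value is the number of ids in
    exactly that membership pattern. Region counts sum to |union|.
    """
    names = sorted(sets)
    if not (2 <= len(names) <= 3):
        raise ValueError("Venn decomposition supports 2 or 3 sets; tabulate larger families")
    universe = set().union(*sets.values())
    regions: dict[tuple[str, ...], int] = {}
    for gene in universe:
        pattern = tuple(n for n in names if gene in sets[n])
        regions[pattern] = regions.get(pattern, 0) + 1
    # report every non-empty pattern explicitly, including zero-count ones
    from itertools import combinations
    for r in range(1, len(names) + 1):
        for pattern in combinations(names, r):
            regions.setdefault(pattern, 0)
    return regions


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _log_odds_matrix(pwm: np.ndarray, background: np.ndarray) -> np.ndarray:
    pwm = np.asarray(pwm, dtype=float)
    colsum = pwm.sum(axis=0)
    if np.any(pwm < 0) or np.any(colsum <= 0):
        raise ValueError("PWM counts must be >= 0 with positive column sums")
    pseudo = 0.01 * colsum
    probs = (pwm + pseudo) / (colsum + 4 * pseudo)
    return np.log2(probs / background[:, None])


def scan_motifs(
    sequence: str,
    pwm: np.ndarray,
    background: Sequence[float] | None = None,
    chrom: str = "seq",
    offset: int = 0,
) -> list[MotifHit]:
    """Scan both strands of ``sequence`` at every offset with a count PWM.

    log-odds use column probabilities ``(count + pseudo) / (colsum +
    4*pseudo)`` with ``pseudo = 0.01 * colsum`` against the background base
    frequencies (uniform 0.25 by default); the relative score rescales the
    log-odds to [0, 1] between the matrix's minimum and maximum attainable
    values. Windows containing a non-ACGT base are skipped with a warning.
    Hits are returned for every scanned offset on both strands, sorted by
    position; ``offset`` shifts reported coordinates (e.g. a peak's start).
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    lom = _log_odds_matrix(pwm, bg)
    width = lom.shape[1]
    if len(sequence) < width:
        raise ValueError("sequence shorter than PWM width")
    lo_min = lom.min(axis=0).sum()
    lo_max = lom.max(axis=0).sum()
    span = lo_max - lo_min
    # reverse strand: score the reverse complement of each window in place
    lom_rc = lom[::-1, ::-1]

    codes = np.array([_BASE_INDEX.get(b, -1) for b in sequence.upper()], dtype=int)
    bad = codes < 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} non-ACGT base(s); overlapping windows skipped")
    hits: list[MotifHit] = []
    for i in range(len(codes) - width + 1):
        window = codes[i:i + width]
        if (window < 0).any():
            continue
        for strand, matrix in (("+", lom), ("-", lom_rc)):
            lo = float(matrix[window, np.arange(width)].sum())
            rel = (lo - lo_min) / span if span > 0 else 1.0
            hits.append(MotifHit(
                interval=GenomicInterval(chrom, offset + i, offset + i + width),
                strand=strand, log_odds=lo,
                relative_score=float(min(max(rel, 0.0), 1.0)),
            ))
    return hits


def best_motif_per_peak(
    peaks: Sequence[Peak], hits: Sequence[MotifHit]
) -> dict[int, MotifHit]:
    """Highest-relative-score hit fully inside each peak, keyed by peak
    index; ties break to the leftmost start, then the + strand. Peaks with
    no hit are omitted."""
    best: dict[int, MotifHit] = {}
    for k, p in enumerate(peaks):
        candidates = [
            h for h in hits
            if h.interval.chrom == p.chrom
            and h.interval.start >= p.start and h.interval.end <= p.end
        ]
        if not candidates:
            continue
        best[k] = min(
            candidates,
            key=lambda h: (-h.relative_score, h.interval.start, 0 if h.strand == "+" else 1),
        )
    return best


def conservation_metaprofile(
    best_hits: Sequence[MotifHit], track: ValueTrack, flank: int = 250
) -> np.ndarray:
    """Positionwise mean conservation over strand-oriented motif windows.

    Each hit contributes its motif +/- ``flank`` window, reversed for -
    strand hits so that output position 0 always aligns to the motif start.
    Bases the track does not cover read as 0 and are counted. Output length
    is ``motif_width + 2*flank``.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if not best_hits:
        raise ValueError("no motif hits to profile")
    widths = {len(h.interval) for h in best_hits}
    if len(widths) != 1:
        raise ValueError("hits must share one motif width")
    rows = []
    for h in best_hits:
        vals = track.values(h.interval.chrom, h.interval.start - flank,
                            h.interval.end + flank)
        rows.append(vals[::-1] if h.strand == "-" else vals)
    return np.mean(rows, axis=0)
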