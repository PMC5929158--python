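"""4C-seq fragment quantification, smoothing and condition comparison.

The unit of measurement throughout is the primary restriction fragment:
reads are counted per fragment, fragments without an internal secondary-
cutter site ("blind" fragments) are excluded, fragments near the viewpoint
are masked, counts are scaled to reads-per-fragment-per-million, the
profile is smoothed with a running mean over a stepped grid (6 kb window,
500 bp steps by default), and regions of interest are quantified as the
mean per-fragment signal of the fragments whose midpoints they contain.
Wild-type and perturbed conditions are compared per region with a
two-sided pooled-variance Student's t test across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval

__all__ = [
    "FragmentMap",
    "FragmentProfile",
    "build_fragment_map",
    "count_reads_per_fragment",
    "normalize_per_million",
    "smooth_profile",
    "quantify_regions",
    "compare_conditions",
    "confidence_band",
    "RegionComparison",
]


@dataclass
class FragmentMap:
    """Primary restriction fragments tiling each chromosome, with a blind
    flag per fragment (no secondary-cutter site strictly inside)."""

    fragments: dict[str, list[GenomicInterval]]
    blind: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, frags in self.fragments.items():
            if len(frags) != len(self.blind[chrom]):
                raise ValueError(f"{chrom}: blind flags do not match fragments")
            for a, b in zip(frags, frags[1:]):
                if a.end != b.start:
                    raise ValueError(f"{chrom}: fragments must tile without gaps/overlaps")

    def midpoints(self, chrom: str) -> np.ndarray:
        return np.array([f.midpoint for f in self.fragments[chrom]])


def build_fragment_map(
    cut_positions: dict[str, Sequence[int]],
    secondary_cut_positions: dict[str, Sequence[int]],
    chrom_sizes: dict[str, int],
) -> FragmentMap:
    """Fragment geometry from primary-cutter positions; a fragment is blind
    when no secondary-cutter position lies strictly inside it."""
    fragments: dict[str, list[GenomicInterval]] = {}
    blind: dict[str, np.ndarray] = {}
    for chrom, length in chrom_sizes.items():
        cuts = sorted(int(c) for c in cut_positions.get(chrom, []))
        if len(set(cuts)) != len(cuts):
            raise ValueError(f"{chrom}: duplicate cut positions")
        if cuts and (cuts[0] <= 0 or cuts[-1] >= length):
            raise ValueError(f"{chrom}: cut positions must lie strictly inside the chromosome")
        bounds = [0, *cuts, length]
        frags = [GenomicInterval(chrom, a, b) for a, b in zip(bounds, bounds[1:])]
        sec = np.sort(np.asarray(list(secondary_cut_positions.get(chrom, [])), dtype=int))
        flags = np.empty(len(frags), dtype=bool)
        for k, f in enumerate(frags):
            lo = np.searchsorted(sec, f.start, side="right")
            hi = np.searchsorted(sec, f.end - 1, side="left")
            flags[k] = hi <= lo  # no secondary cut strictly inside (start, end)
        fragments[chrom] = frags
        blind[chrom] = flags
    return FragmentMap(fragments=fragments, blind=blind)


@dataclass
class FragmentProfile:
    """Per-fragment 4C counts for one replicate on the viewpoint chromosome."""

    fragment_map: FragmentMap
    chrom: str
    viewpoint: GenomicInterval
    counts: np.ndarray
    masked: np.ndarray            # viewpoint-proximal fragments, excluded throughout
    replicate_id: str = "rep1"
    condition: str = "wild_type"
    rpm: np.ndarray | None = None
    # count-conservation audit
    n_input: int = 0
    n_retained: int = 0
    n_blind_discarded: int = 0
    n_masked_discarded: int = 0
    n_out_of_range: int = 0

    @property
    def eligible(self) -> np.ndarray:
        """Fragments contributing to totals: non-blind and non-masked."""
        return ~self.fragment_map.blind[self.chrom] & ~self.masked

    def audit_ok(self) -> bool:
        return self.n_input == (self.n_retained + self.n_blind_discarded
                                + self.n_masked_discarded + self.n_out_of_range)


def count_reads_per_fragment(
    read_positions: np.ndarray,
    fragment_map: FragmentMap,
    chrom: str,
    viewpoint: GenomicInterval,
    exclusion_radius: int = 10_000,
    replicate_id: str = "rep1",
    condition: str = "wild_type",
) -> FragmentProfile:
    """Assign reads to fragments; discard blind-fragment reads and mask
    fragments intersecting viewpoint +/- ``exclusion_radius``."""
    if exclusion_radius < 0:
        raise ValueError("exclusion_radius must be >= 0")
    frags = fragment_map.fragments[chrom]
    chrom_len = frags[-1].end
    positions = np.asarray(read_positions, dtype=int)
    if positions.size and (positions.min() < 0 or positions.max() >= chrom_len):
        raise ValueError(f"read position beyond chromosome {chrom} (len {chrom_len})")
    starts = np.array([f.start for f in frags])
    idx = np.searchsorted(starts, positions, side="right") - 1
    raw = np.bincount(idx, minlength=len(frags)).astype(int)

    blind = fragment_map.blind[chrom]
    if viewpoint.chrom == chrom:
        vp_lo = max(0, viewpoint.start - exclusion_radius)
        vp_hi = viewpoint.end + exclusion_radius
        masked = np.array([f.start < vp_hi and vp_lo < f.end for f in frags])
    else:
        masked = np.zeros(len(frags), dtype=bool)

    counts = raw.copy()
    counts[blind] = 0
    counts[masked] = 0
    n_blind = int(raw[blind].sum())
    n_masked = int(raw[~blind & masked].sum())
    return FragmentProfile(
        fragment_map=fragment_map, chrom=chrom, viewpoint=viewpoint,
        counts=counts, masked=masked, replicate_id=replicate_id, condition=condition,
        n_input=int(positions.size), n_retained=int(counts.sum()),
        n_blind_discarded=n_blind, n_masked_discarded=n_masked, n_out_of_range=0,
    )


def normalize_per_million(profile: FragmentProfile) -> FragmentProfile:
    """Scale counts to reads-per-fragment-per-million-sequenced-reads:
    ``rpm_i = counts_i * 1e6 / total input reads``.

    The denominator is every mapped read of the replicate — including those
    later discarded as blind or viewpoint-proximal — so the scale reflects
    sequencing depth, not the filtering. ``sum(rpm)`` therefore equals
    ``1e6 * retained / input``.
    """
    total = profile.n_input
    if total <= 0 or profile.counts.sum() <= 0:
        raise ValueError("no reads: cannot normalize")
    return replace(profile, rpm=profile.counts * 1e6 / total)


def smooth_profile(
    profile: FragmentProfile, window: int = 6000, step: int = 500
) -> tuple[np.ndarray, np.ndarray]:
    """Running mean of per-fragment rpm over a stepped genomic grid.

    At each grid position ``p`` (multiples of ``step``) the value is the
    mean rpm of eligible fragments whose midpoints fall in
    ``[p - window/2, p + window/2)``; grid positions with no eligible
    fragment emit no point. Returns (positions, values).
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be > 0")
    if profile.rpm is None:
        raise ValueError("normalize the profile before smoothing")
    eligible = profile.eligible
    mids = profile.fragment_map.midpoints(profile.chrom)[eligible]
    vals = profile.rpm[eligible]
    order = np.argsort(mids)
    mids, vals = mids[order], vals[order]
    chrom_len = profile.fragment_map.fragments[profile.chrom][-1].end
    grid = np.arange(0, chrom_len + 1, step)
    lo = np.searchsorted(mids, grid - window / 2, side="left")
    hi = np.searchsorted(mids, grid + window / 2, side="left")
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    n = hi - lo
    keep = n > 0
    values = (csum[hi[keep]] - csum[lo[keep]]) / n[keep]
    return grid[keep], values


def quantify_regions(
    profile: FragmentProfile, regions: Sequence[GenomicInterval]
) -> list[float | None]:
    """Mean rpm over the eligible fragments whose midpoints lie inside each
    region; ``None`` (missing, not zero) when a region holds no eligible
    fragment. Midpoint assignment makes the quantification partition-like."""
    if profile.rpm is None:
        raise ValueError("normalize the profile before quantifying")
    mids = profile.fragment_map.midpoints(profile.chrom)
    eligible = profile.eligible
    out: list[float | None] = []
    for r in regions:
        if r.chrom != profile.chrom:
            out.append(None)
            continue
        inside = eligible & (mids >= r.start) & (mids < r.end)
        out.append(float(profile.rpm[inside].mean()) if inside.any() else None)
    return out


@dataclass(frozen=True)
class RegionComparison:
    t: float
    p: float
    significant: bool
    mean_ratio: float
    degenerate: bool = False


def compare_conditions(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = 0.05,
) -> RegionComparison:
    """Two-sided pooled-variance Student's t test of condition B vs A for
    one region, across replicates; ``mean_ratio = mean_B / mean_A``.

    Degenerate inputs: zero pooled variance with equal means gives
    t = 0, p = 1; zero pooled variance with unequal means is flagged and
    reported as p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    mean_ratio = float(b.mean() / a.mean()) if a.mean() != 0 else float("nan")
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
    if pooled == 0:
        if a.mean() == b.mean():
            return RegionComparison(0.0, 1.0, False, mean_ratio)
        return RegionComparison(float("inf"), 0.0, True, mean_ratio, degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return RegionComparison(float(t), float(p), bool(p < alpha), mean_ratio)


def confidence_band(
    tracks: Sequence[tuple[np.ndarray, np.ndarray]], level: float = 0.90
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise confidence band over replicate smoothed tracks.

    Positions present in fewer than 2 replicates are omitted; at each kept
    position the band is ``mean +/- t_{(1+level)/2, n-1} * sd / sqrt(n)``.
    Returns (positions, mean, lo, hi).
    """
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    if len(tracks) < 2:
        raise ValueError("need >= 2 replicate tracks")
    maps = [dict(zip(pos.tolist(), val.tolist())) for pos, val in tracks]
    all_pos = sorted({p for m in maps for p in m})
    out_pos, out_mean, out_lo, out_hi = [], [], [], []
    for p in all_pos:
        vals = np.array([m[p] for m in maps if p in m])
        if len(vals) < 2:
            continue
        mean = vals.mean()
        half = stats.t.ppf((1 + level) / 2, len(vals) - 1) * vals.std(ddof=1) / np.sqrt(len(vals))
        out_pos.append(p)
        out_mean.append(mean)
        out_lo.append(mean - half)
        out_hi.append(mean + half)
    return (np.array(out_pos), np.array(out_mean), np.array(out_lo), np.array(out_hi))
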