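"""Chromatin-interaction calling from paired-end tags (PETs).

The stages mirror a ChIA-PET/HiChIP pipeline downstream of alignment:
duplicate removal, self-ligation filtering, assignment of tag ends to
(merged) anchor peaks, an empirical distance-decay background, and a
per-anchor-pair enrichment score.

Scoring model
-------------
For anchors ``i, j`` on the same chromosome with midpoint separation
``d_ij``, the background expectation is

    lambda_ij = N * m_i * m_j * decay(d_ij) / Z

where ``m_i`` is anchor i's marginal assigned-end count, taken leave-one-out
(the pair's own PETs are subtracted before forming the product, so a strong
loop cannot absorb itself into its own expectation) and then regularized by
Gamma-Poisson empirical-Bayes shrinkage toward the mean marginal (raw
Poisson counting noise in the marginals otherwise biases ``1/lambda``
upward and makes the test anti-conservative), ``decay`` the fitted
contact-decay step function,
``N`` the total assigned PET count and ``Z`` chosen so that the
expectations sum to ``N`` over the candidate-pair universe (all
same-chromosome anchor pairs with span in a configured window). The
per-pair p-value is the exact randomized upper tail of the Poisson null,

    p = P(X > k | lambda) + U * P(X = k | lambda),   U ~ Uniform(0, 1),

which is exactly uniform under the null — the property that makes the
downstream false-discovery control meaningful for a discrete count test.
The uniform draws come from a dedicated generator seeded by the caller, so
scoring is deterministic. ``tail="sf"`` gives the conservative plain tail
``P(X >= k)`` instead. Scores are ``1 - q`` with q the Benjamini-Hochberg
adjusted p over the candidate universe, so "score >= 0.9" reads as
"FDR <= 0.1".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, Peak

__all__ = [
    "PairedTag",
    "ChromatinInteraction",
    "dedup_pets",
    "filter_self_ligation",
    "merge_anchors",
    "assign_pets_to_anchors",
    "PairTable",
    "DecayModel",
    "fit_distance_decay",
    "score_interactions",
    "ScoredPairs",
    "filter_interactions",
]


@dataclass(frozen=True)
class PairedTag:
    """One mapped PET; ends are stored in canonical (lexicographic) order so
    that (A, B) and (B, A) compare equal."""

    end1: tuple[str, int, str]
    end2: tuple[str, int, str]

    @classmethod
    def make(cls, chrom1: str, pos1: int, strand1: str,
             chrom2: str, pos2: int, strand2: str) -> "PairedTag":
        a = (chrom1, int(pos1), strand1)
        b = (chrom2, int(pos2), strand2)
        if (b[0], b[1]) < (a[0], a[1]):
            a, b = b, a
        return cls(a, b)

    @property
    def is_intra(self) -> bool:
        return self.end1[0] == self.end2[0]

    @property
    def span(self) -> int | None:
        """Separation in bp for intra-chromosomal PETs, else None."""
        return abs(self.end2[1] - self.end1[1]) if self.is_intra else None


def dedup_pets(pets: Sequence[PairedTag]) -> list[PairedTag]:
    """Remove exact duplicates (same canonicalized ends including strands),
    keeping first occurrences in input order. Idempotent."""
    return list(dict.fromkeys(pets))


def filter_self_ligation(pets: Iterable[PairedTag], min_span: int = 4000) -> list[PairedTag]:
    """Drop short intra-chromosomal PETs (span < ``min_span``), the
    self-ligation/self-circle products; inter-chromosomal PETs are kept."""
    if min_span < 0:
        raise ValueError("min_span must be >= 0")
    return [p for p in pets if not p.is_intra or p.span >= min_span]


def merge_anchors(anchors: Sequence[Peak]) -> list[Peak]:
    """Merge overlapping anchor peaks (>=1 shared base) into disjoint
    anchors; merged signal is the sum, summit that of the strongest part."""
    merged: list[Peak] = []
    for p in sorted(anchors, key=lambda p: (p.chrom, p.start, p.end)):
        if merged and merged[-1].chrom == p.chrom and p.start < merged[-1].end:
            last = merged[-1]
            best = last if last.signal >= p.signal else p
            merged[-1] = Peak(
                GenomicInterval(last.chrom, last.start, max(last.end, p.end)),
                summit=best.summit,
                signal=last.signal + p.signal,
                name=last.name,
            )
        else:
            merged.append(p)
    return merged


@dataclass
class PairTable:
    """PET counts aggregated over unordered merged-anchor pairs, plus the
    bookkeeping needed for the count-conservation audit."""

    anchors: list[Peak]
    counts: dict[tuple[int, int], int]
    marginals: np.ndarray  # assigned PET ends per anchor
    n_input: int
    n_assigned: int
    n_unanchored: int   # >=1 end in no anchor
    n_self_pair: int    # both ends in the same anchor

    def audit_ok(self) -> bool:
        return self.n_input == self.n_assigned + self.n_unanchored + self.n_self_pair


def assign_pets_to_anchors(pets: Sequence[PairedTag], anchors: Sequence[Peak]) -> PairTable:
    """Assign each PET to the (unordered) pair of merged anchors containing
    its two ends. PETs with an end outside every anchor, or with both ends
    in the same anchor, contribute nothing (but are audited)."""
    merged = merge_anchors(anchors)
    for a, b in zip(merged, merged[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError("anchors overlap after merge")  # unreachable by construction

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in merged}:
        idx = np.array([i for i, p in enumerate(merged) if p.chrom == chrom])
        starts = np.array([merged[i].start for i in idx])
        ends = np.array([merged[i].end for i in idx])
        by_chrom[chrom] = (idx, starts, ends)

    def locate(chrom: str, pos: int) -> int:
        if chrom not in by_chrom:
            return -1
        idx, starts, ends = by_chrom[chrom]
        k = int(np.searchsorted(starts, pos, side="right")) - 1
        if k >= 0 and pos < ends[k]:
            return int(idx[k])
        return -1

    counts: dict[tuple[int, int], int] = {}
    marginals = np.zeros(len(merged), dtype=float)
    n_assigned = n_unanchored = n_self = 0
    for pet in pets:
        i = locate(pet.end1[0], pet.end1[1])
        j = locate(pet.end2[0], pet.end2[1])
        if i < 0 or j < 0:
            n_unanchored += 1
        elif i == j:
            n_self += 1
        else:
            key = (i, j) if i < j else (j, i)
            counts[key] = counts.get(key, 0) + 1
            marginals[i] += 1
            marginals[j] += 1
            n_assigned += 1
    return PairTable(
        anchors=merged, counts=counts, marginals=marginals,
        n_input=len(pets), n_assigned=n_assigned,
        n_unanchored=n_unanchored, n_self_pair=n_self,
    )


@dataclass
class DecayModel:
    """Empirical contact decay: a non-increasing step function over
    log-spaced span bins, on a per-bp density scale."""

    edges: np.ndarray    # bin edges, bp
    values: np.ndarray   # per-bp relative propensity per bin, > 0
    bin_counts: np.ndarray

    def __call__(self, span) -> np.ndarray:
        span = np.asarray(span, dtype=float)
        k = np.clip(np.searchsorted(self.edges, span, side="right") - 1,
                    0, len(self.values) - 1)
        return self.values[k]

    def loglog_slope(self, span_min: float = 10_000, span_max: float = 500_000) -> float:
        """OLS slope of log10(density) on log10(bin geometric center) over
        populated mid-range bins — recovers the decay exponent's sign and
        magnitude for a power-law contact process."""
        centers = np.sqrt(self.edges[:-1] * self.edges[1:])
        keep = (centers >= span_min) & (centers <= span_max) & (self.bin_counts > 0)
        if keep.sum() < 3:
            raise ValueError("too few populated bins for a slope estimate")
        x = np.log10(centers[keep])
        y = np.log10(self.values[keep])
        return float(np.polyfit(x, y, 1)[0])


def fit_distance_decay(
    pair_table: PairTable,
    span_min: int = 4_000,
    span_max: int = 10_000_000,
    bins_per_decade: int = 10,
) -> DecayModel:
    """Fit the decay of PET frequency with genomic separation.

    PET counts are pooled into log-spaced span bins, converted to per-bp
    densities, normalized, and made non-increasing by pool-adjacent-
    violators (isotonic regression weighted by bin counts). Empty bins
    inherit the value of the nearest populated bin toward shorter spans, so
    the returned propensity is strictly positive everywhere.
    """
    mids = np.array([a.interval.midpoint for a in pair_table.anchors])
    chroms = np.array([a.chrom for a in pair_table.anchors])
    spans, weights = [], []
    for (i, j), c in pair_table.counts.items():
        if chroms[i] == chroms[j]:
            spans.append(abs(mids[j] - mids[i]))
            weights.append(c)
    if not spans:
        raise ValueError("no intra-chromosomal anchor pairs: cannot fit decay")
    spans = np.asarray(spans, dtype=float)
    weights = np.asarray(weights, dtype=float)

    n_bins = int(np.ceil(np.log10(span_max / span_min) * bins_per_decade))
    edges = np.logspace(np.log10(span_min), np.log10(span_max), n_bins + 1)
    k = np.clip(np.searchsorted(edges, np.clip(spans, span_min, span_max - 1),
                                side="right") - 1, 0, n_bins - 1)
    bin_counts = np.bincount(k, weights=weights, minlength=n_bins)
    widths = np.diff(edges)
    density = bin_counts / widths
    total = density.sum()
    density = density / total if total > 0 else density

    populated = bin_counts > 0
    if populated.sum() >= 2:
        iso = IsotonicRegression(increasing=False)
        centers = np.sqrt(edges[:-1] * edges[1:])
        density[populated] = iso.fit_transform(
            centers[populated], density[populated],
            sample_weight=bin_counts[populated],
        )
    # fill empty bins from the left; strictly positive floor
    floor = density[populated].max() * 1e-9 if populated.any() else 1e-12
    last = density[populated][0] if populated.any() else floor
    values = np.empty(n_bins)
    for b in range(n_bins):
        if populated[b]:
            last = max(density[b], floor)
        values[b] = max(last, floor)
    return DecayModel(edges=edges, values=values, bin_counts=bin_counts)


@dataclass(frozen=True)
class ChromatinInteraction:
    """A scored anchor-pair loop call."""

    anchorA: Peak
    anchorB: Peak
    pet_count: int
    expected: float
    score: float
    span: int

    def __post_init__(self) -> None:
        if self.pet_count < 0 or not (0.0 <= self.score <= 1.0):
            raise ValueError("invalid interaction: need pet_count >= 0 and score in [0,1]")
        if (self.anchorB.chrom, self.anchorB.start) < (self.anchorA.chrom, self.anchorA.start):
            raise ValueError("anchorA must precede anchorB in genome order")


@dataclass
class ScoredPairs:
    """Scoring result over the full candidate-pair universe.

    ``table`` has one row per candidate pair (columns: i, j, chrom, span,
    pet_count, expected, p, q, score) including zero-count pairs, which is
    what calibration checks need; :meth:`interactions` materialises the
    pairs with at least one PET as interaction calls.
    """

    anchors: list[Peak]
    table: pd.DataFrame

    def interactions(self, min_count: int = 1) -> list[ChromatinInteraction]:
        sub = self.table[self.table["pet_count"] >= min_count]
        out = []
        for row in sub.itertuples(index=False):
            out.append(ChromatinInteraction(
                anchorA=self.anchors[int(row.i)], anchorB=self.anchors[int(row.j)],
                pet_count=int(row.pet_count), expected=float(row.expected),
                score=float(row.score), span=int(row.span),
            ))
        return out


def score_interactions(
    pair_table: PairTable,
    decay: DecayModel,
    min_span: int = 4_000,
    max_span: int = 2_000_000,
    tail: str = "randomized",
    seed: int = 0,
) -> ScoredPairs:
    """Score every candidate anchor pair against the Poisson background.

    The candidate universe is all same-chromosome merged-anchor pairs with
    midpoint span in ``[min_span, max_span]``; the BH correction runs over
    that whole universe (see module docstring for the model).
    """
    anchors = pair_table.anchors
    mids = np.array([a.interval.midpoint for a in anchors])
    chrom_of = np.array([a.chrom for a in anchors])
    m = pair_table.marginals

    ii, jj, spans = [], [], []
    for chrom in pd.unique(chrom_of):
        idx = np.flatnonzero(chrom_of == chrom)
        if len(idx) < 2:
            continue
        a, b = np.triu_indices(len(idx), k=1)
        s = np.abs(mids[idx[b]] - mids[idx[a]])
        keep = (s >= min_span) & (s <= max_span)
        ii.append(idx[a[keep]])
        jj.append(idx[b[keep]])
        spans.append(s[keep])
    if not ii:
        raise ValueError("no candidate anchor pairs in the span window")
    ii = np.concatenate(ii)
    jj = np.concatenate(jj)
    spans = np.concatenate(spans).astype(float)

    counts = np.array([pair_table.counts.get((int(i), int(j)), 0)
                       for i, j in zip(ii, jj)], dtype=float)
    n_total = pair_table.n_assigned
    # leave-one-out marginals, then EB shrinkage calibrated on the raw ones
    mbar = float(m.mean()) if len(m) else 0.0
    excess = float(m.var()) - mbar if len(m) else 0.0
    mi = np.maximum(m[ii] - counts, 0.0)
    mj = np.maximum(m[jj] - counts, 0.0)
    if mbar <= 0:
        mi = np.ones_like(mi)
        mj = np.ones_like(mj)
    elif excess <= 0:
        mi = np.full_like(mi, mbar)
        mj = np.full_like(mj, mbar)
    else:
        prior = mbar * mbar / excess
        mi = (mi + prior) / (1.0 + mbar / excess)
        mj = (mj + prior) / (1.0 + mbar / excess)
    w = mi * mj * decay(spans)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("all candidate pairs have zero expectation")
    lam = np.maximum(n_total * w / wsum, 1e-12)

    if tail == "randomized":
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x5C0E)))
        u = rng.random(len(lam))
        p = stats.poisson.sf(counts, lam) + u * stats.poisson.pmf(counts, lam)
    elif tail == "sf":
        p = stats.poisson.sf(counts - 1, lam)
    else:
        raise ValueError(f"unknown tail method {tail!r}")
    p = np.clip(p, 0.0, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    score = 1.0 - q

    table = pd.DataFrame({
        "i": ii, "j": jj, "chrom": chrom_of[ii], "span": spans.astype(int),
        "pet_count": counts.astype(int), "expected": lam,
        "p": p, "q": q, "score": score,
    })
    return ScoredPairs(anchors=list(anchors), table=table)


def filter_interactions(
    interactions: Sequence[ChromatinInteraction],
    min_score: float = 0.9,
    min_pet: int = 9,
) -> list[ChromatinInteraction]:
    """Keep interactions with ``score >= min_score`` and
    ``pet_count >= min_pet`` (order preserved)."""
    if not (0.0 <= min_score <= 1.0):
        raise ValueError("min_score must be in [0, 1]")
    return [x for x in interactions if x.score >= min_score and x.pet_count >= min_pet]
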