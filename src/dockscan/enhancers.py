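"""Active-enhancer and super-enhancer definition from H3K27Ac peaks.

An enhancer is an H3K27Ac peak that does not overlap a promoter window
(TSS +/- 2.5 kb by default). Nearby enhancers are stitched (12.5 kb gap by
default) and the stitched regions ranked by total signal; the rank-ordering
"tangent" rule — the point on the min-max-rescaled signal-vs-rank curve
where the slope first exceeds 1 — separates super-enhancers from typical
enhancers, following the standard super-enhancer convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval, Peak, Tss, overlap_join, window_around

__all__ = [
    "Enhancer",
    "define_active_enhancers",
    "stitch_enhancers",
    "rank_super_enhancers",
]


@dataclass(frozen=True)
class Enhancer:
    interval: GenomicInterval
    signal: float
    n_constituents: int = 1
    is_super: bool = False

    def __post_init__(self) -> None:
        if self.signal < 0 or self.n_constituents < 1:
            raise ValueError("enhancer needs signal >= 0 and n_constituents >= 1")


def define_active_enhancers(
    h3k27ac_peaks: Sequence[Peak],
    tss_catalog: Sequence[Tss],
    chrom_sizes: dict[str, int],
    promoter_radius: int = 2500,
) -> list[Enhancer]:
    """H3K27Ac peaks minus promoter-proximal signal.

    Peaks overlapping any TSS +/- ``promoter_radius`` window are dropped;
    the remainder become single-constituent enhancers.
    """
    if promoter_radius < 0:
        raise ValueError("promoter_radius must be >= 0")
    promoter_windows = []
    if promoter_radius > 0:
        for t in tss_catalog:
            clen = chrom_sizes.get(t.chrom)
            if clen is None or not (0 <= t.pos < clen):
                continue
            promoter_windows.append(window_around(t.pos, promoter_radius, t.chrom, clen))
    peak_ivs = [p.interval for p in h3k27ac_peaks]
    promoter_hit = {i for i, _ in overlap_join(peak_ivs, promoter_windows)}
    return [
        Enhancer(interval=p.interval, signal=p.signal)
        for i, p in enumerate(h3k27ac_peaks)
        if i not in promoter_hit
    ]


def stitch_enhancers(enhancers: Sequence[Enhancer], gap: int = 12500) -> list[Enhancer]:
    """Transitively merge same-chromosome enhancers whose end-to-start
    distance is within ``gap``; merged signal is the sum, the interval the
    hull. Idempotent and signal-conserving."""
    if gap < 0:
        raise ValueError("gap must be >= 0")
    ordered = sorted(enhancers, key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end))
    out: list[Enhancer] = []
    for e in ordered:
        if out and out[-1].interval.chrom == e.interval.chrom \
                and e.interval.start - out[-1].interval.end <= gap:
            last = out[-1]
            out[-1] = Enhancer(
                interval=GenomicInterval(last.interval.chrom, last.interval.start,
                                         max(last.interval.end, e.interval.end)),
                signal=last.signal + e.signal,
                n_constituents=last.n_constituents + e.n_constituents,
            )
        else:
            out.append(e)
    return out


def rank_super_enhancers(stitched: Sequence[Enhancer]) -> list[Enhancer]:
    """Flag super-enhancers by the rank-curve tangent rule.

    Regions are sorted ascending by signal; rank and signal are rescaled to
    [0, 1]; the cutoff is the first inter-point segment whose slope exceeds
    1, and every region past it is flagged. With all signals equal there is
    no elbow: nothing is flagged and a warning is emitted. Output preserves
    the input's order.
    """
    n = len(stitched)
    if n == 0:
        return []
    signals = np.array([e.signal for e in stitched], dtype=float)
    smin, smax = signals.min(), signals.max()
    if smax == smin:
        warnings.warn("all stitched enhancer signals equal; no super-enhancers flagged")
        return [Enhancer(e.interval, e.signal, e.n_constituents, False) for e in stitched]
    order = np.argsort(signals, kind="stable")
    y = (signals[order] - smin) / (smax - smin)
    x = np.arange(n) / (n - 1)
    cutoff_rank = n  # past the end: nothing flagged unless a slope exceeds 1
    for k in range(n - 1):
        slope = (y[k + 1] - y[k]) / (x[k + 1] - x[k])
        if slope > 1:
            cutoff_rank = k + 1
            break
    is_super = np.zeros(n, dtype=bool)
    is_super[order[cutoff_rank:]] = True
    return [
        Enhancer(e.interval, e.signal, e.n_constituents, bool(flag))
        for e, flag in zip(stitched, is_super)
    ]
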