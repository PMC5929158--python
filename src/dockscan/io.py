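"""Readers and writers for the plain-text formats the pipeline exchanges.

BED-family files are parsed natively (0-based half-open). Track lines,
browser lines and ``#`` comments are skipped. Malformed coordinate lines
raise :class:`ParseError` naming the offending line number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Peak, Tss

__all__ = [
    "ParseError",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_tss_catalog",
    "write_tss_catalog",
    "read_bedgraph",
    "write_bedgraph",
    "ValueTrack",
    "read_pwm",
    "write_pwm",
]


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line."""


_SKIP_PREFIXES = ("track", "browser", "#")


def _is_skippable(line: str) -> bool:
    s = line.strip()
    return not s or any(s.startswith(p) for p in _SKIP_PREFIXES)


def read_bed(path: str | Path) -> list[Peak]:
    """Parse BED3/BED6/narrowPeak into :class:`Peak` records.

    Column handling beyond chrom/start/end: column 4 is the name, column 5
    the signal (0 when absent or non-numeric placeholder ``.``). For
    10-column narrowPeak lines the signal comes from column 7 and the summit
    from ``start + column 10`` (when that offset is >= 0). A 6-column line
    whose last field is a non-negative integer is read as a summit offset;
    otherwise the summit defaults to the interval midpoint.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if _is_skippable(raw):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ParseError(f"{path}:{lineno}: require 0 <= start < end")
            name = fields[3] if len(fields) > 3 and fields[3] else "."
            signal = 0.0
            if len(fields) > 4:
                try:
                    signal = float(fields[4])
                except ValueError:
                    signal = 0.0
            summit = (start + end) // 2
            if len(fields) >= 10:  # narrowPeak
                try:
                    signal = float(fields[6])
                except ValueError:
                    pass
                try:
                    offset = int(fields[9])
                    if offset >= 0:
                        summit = start + offset
                except ValueError:
                    pass
            elif len(fields) == 6:
                try:
                    offset = int(fields[5])
                    if offset >= 0:
                        summit = start + offset
                except ValueError:
                    pass  # a strand or other annotation, not a summit
            peaks.append(
                Peak(GenomicInterval(chrom, start, end), summit=summit,
                     signal=max(signal, 0.0), name=name)
            )
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as 6-column BED: chrom, start, end, name, signal,
    summit offset (the layout :func:`read_bed` round-trips)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.signal:g}\t"
                f"{p.summit - p.start}\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if _is_skippable(raw):
                continue
            fields = raw.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer length") from exc
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_tss_catalog(path: str | Path) -> list[Tss]:
    """TSS catalog TSV: gene, chrom, pos, strand, then one ``expr_<cell>``
    column per cell type."""
    df = pd.read_csv(path, sep="\t")
    cells = [c[len("expr_"):] for c in df.columns if c.startswith("expr_")]
    out = []
    for row in df.itertuples(index=False):
        expr = {cell: float(getattr(row, f"expr_{cell}")) for cell in cells}
        out.append(Tss(str(row.gene), str(row.chrom), int(row.pos), str(row.strand), expr))
    return out


def write_tss_catalog(tss_list: Sequence[Tss], path: str | Path) -> None:
    cells = sorted({c for t in tss_list for c in t.expression})
    rows = []
    for t in tss_list:
        row = {"gene": t.gene, "chrom": t.chrom, "pos": t.pos, "strand": t.strand}
        for cell in cells:
            row[f"expr_{cell}"] = t.expression.get(cell, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False,
              columns=["chrom", "start", "end", "value"])


@dataclass
class ValueTrack:
    """Per-base lookup over a bedGraph-style table; absent bases read as 0.

    The zero-fill mirrors wiggle-track absence semantics; callers that need
    to distinguish "missing" may consult :meth:`covered`.
    """

    _chrom_index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ValueTrack":
        index = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            index[str(chrom)] = (
                sub["start"].to_numpy(int),
                sub["end"].to_numpy(int),
                sub["value"].to_numpy(float),
            )
        return cls(index)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over ``[start, end)``; uncovered bases are 0."""
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._chrom_index:
            return out
        starts, ends, vals = self._chrom_index[chrom]
        lo = max(0, int(np.searchsorted(ends, start, side="right")))
        hi = int(np.searchsorted(starts, end, side="left"))
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], vals[lo:hi]):
            a, b = max(s, start), min(e, end)
            if a < b:
                out[a - start: b - start] = v
        return out

    def covered(self, chrom: str, start: int, end: int) -> np.ndarray:
        mask = np.zeros(end - start, dtype=bool)
        if chrom not in self._chrom_index:
            return mask
        starts, ends, _ = self._chrom_index[chrom]
        lo = max(0, int(np.searchsorted(ends, start, side="right")))
        hi = int(np.searchsorted(starts, end, side="left"))
        for s, e in zip(starts[lo:hi], ends[lo:hi]):
            a, b = max(s, start), min(e, end)
            if a < b:
                mask[a - start: b - start] = True
        return mask


def read_pets(path: str | Path):
    """PET TSV with 8 columns: chrom1, pos1, strand1, chrom2, pos2, strand2,
    cell_type, tag. Returns a list of canonicalized PairedTag records."""
    from .interactions import PairedTag

    pets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if _is_skippable(raw):
                continue
            f = raw.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 columns")
            try:
                pets.append(PairedTag.make(f[0], int(f[1]), f[2], f[3], int(f[4]), f[5]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad PET line") from exc
    return pets


def write_pets(pets, path: str | Path, cell_type: str = ".", tag: str = ".") -> None:
    with open(path, "w") as fh:
        for p in pets:
            fh.write("\t".join([
                p.end1[0], str(p.end1[1]), p.end1[2],
                p.end2[0], str(p.end2[1]), p.end2[2],
                cell_type, tag,
            ]) + "\n")


def write_interactions_bedpe(interactions, path: str | Path) -> None:
    """BEDPE loops: chrom1, start1, end1, chrom2, start2, end2, name,
    pet_count, score."""
    with open(path, "w") as fh:
        for k, x in enumerate(interactions):
            fh.write("\t".join(map(str, [
                x.anchorA.chrom, x.anchorA.start, x.anchorA.end,
                x.anchorB.chrom, x.anchorB.start, x.anchorB.end,
                f"loop{k + 1}", x.pet_count, f"{x.score:.6g}",
            ])) + "\n")


def read_interactions_bedpe(path: str | Path):
    from .interactions import ChromatinInteraction

    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if _is_skippable(raw):
                continue
            f = raw.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 BEDPE columns")
            try:
                a = GenomicInterval(f[0], int(f[1]), int(f[2]))
                b = GenomicInterval(f[3], int(f[4]), int(f[5]))
                count, score = int(f[7]), float(f[8])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad BEDPE line") from exc
            pa = Peak(a, summit=a.midpoint, name=f[6] + "_A")
            pb = Peak(b, summit=b.midpoint, name=f[6] + "_B")
            span = abs(b.midpoint - a.midpoint) if a.chrom == b.chrom else 0
            out.append(ChromatinInteraction(
                anchorA=pa, anchorB=pb, pet_count=count,
                expected=1.0, score=score, span=span,
            ))
    return out


def write_enhancers(enhancers, path: str | Path) -> None:
    """Enhancer BED: chrom, start, end, signal, n_constituents, is_super."""
    with open(path, "w") as fh:
        for e in enhancers:
            fh.write(f"{e.interval.chrom}\t{e.interval.start}\t{e.interval.end}\t"
                     f"{e.signal:g}\t{e.n_constituents}\t{int(e.is_super)}\n")


def read_enhancers(path: str | Path):
    from .enhancers import Enhancer

    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if _is_skippable(raw):
                continue
            f = raw.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 enhancer columns")
            try:
                out.append(Enhancer(
                    interval=GenomicInterval(f[0], int(f[1]), int(f[2])),
                    signal=float(f[3]), n_constituents=int(f[4]),
                    is_super=bool(int(f[5])),
                ))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad enhancer line") from exc
    return out


def read_fragment_map(path: str | Path):
    """Fragment-map BED: chrom, start, end, blind flag (0/1) in column 4."""
    from .fourc import FragmentMap

    frags: dict[str, list[GenomicInterval]] = {}
    blind: dict[str, list[bool]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if _is_skippable(raw):
                continue
            f = raw.rstrip("\n").split("\t")
            if len(f) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
                b = bool(int(f[3]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad fragment line") from exc
            frags.setdefault(f[0], []).append(iv)
            blind.setdefault(f[0], []).append(b)
    return FragmentMap(fragments=frags, blind={c: np.array(v) for c, v in blind.items()})


def write_fragment_map(fragment_map, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, frags in fragment_map.fragments.items():
            for iv, b in zip(frags, fragment_map.blind[chrom]):
                fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{int(b)}\n")


def read_read_positions(path: str | Path) -> dict[str, np.ndarray]:
    """4C mapped-read positions TSV: chrom, pos (one read per line)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "pos"], dtype={"chrom": str, "pos": int})
    return {str(c): sub["pos"].to_numpy(int) for c, sub in df.groupby("chrom", sort=False)}


def write_read_positions(reads: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, positions in reads.items():
            for pos in positions:
                fh.write(f"{chrom}\t{int(pos)}\n")


_PWM_ROWS = "ACGT"


def read_pwm(path: str | Path) -> np.ndarray:
    """Read a JASPAR-style count matrix (4 rows A/C/G/T) into a 4 x w array.

    Accepts both the bracketed JASPAR layout (``A [ 1 2 3 ]``) and bare
    whitespace-separated rows; a leading ``>`` header line is ignored.
    """
    rows: dict[str, list[float]] = {}
    order: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(">"):
                continue
            base = line[0].upper()
            if base in _PWM_ROWS and (len(line) == 1 or not line[1].isdigit()):
                body = line[1:]
            else:
                base = _PWM_ROWS[len(order)]
                body = line
            body = body.replace("[", " ").replace("]", " ")
            rows[base] = [float(x) for x in body.split()]
            order.append(base)
    if set(rows) != set(_PWM_ROWS):
        raise ParseError(f"{path}: expected 4 PWM rows A/C/G/T, got {sorted(rows)}")
    widths = {len(v) for v in rows.values()}
    if len(widths) != 1:
        raise ParseError(f"{path}: PWM rows have unequal widths {widths}")
    pwm = np.array([rows[b] for b in _PWM_ROWS], dtype=float)
    if np.any(pwm < 0) or np.any(pwm.sum(axis=0) <= 0):
        raise ParseError(f"{path}: PWM counts must be >= 0 with positive column sums")
    return pwm


def write_pwm(pwm: np.ndarray, path: str | Path, name: str = "motif") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for base, row in zip(_PWM_ROWS, np.asarray(pwm, dtype=float)):
            fh.write(f"{base} [ " + " ".join(f"{x:g}" for x in row) + " ]\n")
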