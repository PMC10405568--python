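"""Per-base score tracks: read depth and phyloP conservation.

Depth tracks count reads overlapping the non-exon-overlapping intron blocks,
after discarding linearly-spliced reads whose splice gap spans the intron.
Conservation tracks carry signed phyloP scores where absent positions are
*missing* (excluded from means), whereas absent depth positions are zero.
Anchored profiles summarise scores per transcript-oriented offset around the
5' splice site, branch point, or 3' splice site, and per-offset group
contrasts use the pseudocounted log2 fold change of group means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._io import write_table
from .annotation import Interval, IntronRecord
from .branchpoint import tail_length

log = logging.getLogger(__name__)

DEPTH = "depth"
PHYLOP = "phylop"


# ---------------------------------------------------------------------------
# read blocks


@dataclass(frozen=True)
class ReadBlocks:
    """An aligned read as its blocks; gaps between blocks are splices."""

    read_id: str
    chrom: str
    strand: str
    blocks: tuple[Interval, ...]

    @property
    def gaps(self) -> tuple[Interval, ...]:
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        )

    def spans_gap_over(self, start: int, end: int) -> bool:
        """True if any splice gap covers the whole [start, end) interval."""
        return any(gs <= start and ge >= end for gs, ge in self.gaps)


def read_blocks_tsv(path: str | Path) -> list[ReadBlocks]:
    """Read the simplified alignment format: read_id, chrom, strand,
    blockStarts (comma-separated), blockSizes."""
    out: list[ReadBlocks] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            rid, chrom, strand, starts, sizes = line.rstrip("\n").split("\t")[:5]
            ss = [int(x) for x in starts.split(",") if x]
            zz = [int(x) for x in sizes.split(",") if x]
            out.append(
                ReadBlocks(rid, chrom, strand, tuple((s, s + z) for s, z in zip(ss, zz)))
            )
    return out


def write_blocks_tsv(reads: Iterable[ReadBlocks], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# sisrna/read_blocks/v1\n")
        fh.write("#read_id\tchrom\tstrand\tblockStarts\tblockSizes\n")
        for r in reads:
            starts = ",".join(str(s) for s, _ in r.blocks)
            sizes = ",".join(str(e - s) for s, e in r.blocks)
            fh.write(f"{r.read_id}\t{r.chrom}\t{r.strand}\t{starts}\t{sizes}\n")


# ---------------------------------------------------------------------------
# score tracks


class ScoreTrack:
    """Sparse per-chromosome map from 0-based position to score.

    For ``kind='depth'`` an absent position means 0; for ``kind='phylop'``
    it is missing and excluded from means (phyloP is signed, so zero is a
    meaningful value, not a fill).
    """

    def __init__(self, kind: str = DEPTH, label: str = ""):
        if kind not in (DEPTH, PHYLOP):
            raise ValueError(f"unknown track kind {kind!r}")
        self.kind = kind
        self.label = label
        self._data: dict[str, dict[int, float]] = {}

    def set(self, chrom: str, pos: int, score: float) -> None:
        if pos < 0:
            raise ValueError("positions must be non-negative")
        self._data.setdefault(chrom, {})[pos] = score

    def add(self, chrom: str, pos: int, score: float = 1.0) -> None:
        d = self._data.setdefault(chrom, {})
        d[pos] = d.get(pos, 0.0) + score

    def get(self, chrom: str, pos: int) -> float | None:
        """Score at a position; 0 for missing depth, None for missing phyloP."""
        val = self._data.get(chrom, {}).get(pos)
        if val is None:
            return 0.0 if self.kind == DEPTH else None
        return val

    def positions(self, chrom: str) -> list[int]:
        return sorted(self._data.get(chrom, {}))

    def chroms(self) -> list[str]:
        return sorted(self._data)

    # -- bedGraph I/O (0-based half-open) -----------------------------------

    @classmethod
    def from_bedgraph(cls, path: str | Path, kind: str, label: str = "") -> "ScoreTrack":
        track = cls(kind, label or Path(path).stem)
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end, value = line.split()[:4]
                v = float(value)
                d = track._data.setdefault(chrom, {})
                for pos in range(int(start), int(end)):
                    d[pos] = v
        return track

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms():
                d = self._data[chrom]
                run_start = run_end = None
                run_val = None
                for pos in sorted(d):
                    v = d[pos]
                    if run_start is not None and pos == run_end and v == run_val:
                        run_end += 1
                        continue
                    if run_start is not None:
                        fh.write(f"{chrom}\t{run_start}\t{run_end}\t{run_val:g}\n")
                    run_start, run_end, run_val = pos, pos + 1, v
                if run_start is not None:
                    fh.write(f"{chrom}\t{run_start}\t{run_end}\t{run_val:g}\n")


def average_tracks(tracks: Sequence[ScoreTrack]) -> ScoreTrack:
    """Position-wise mean across per-sample tracks (union of positions).

    Depth semantics: a sample missing a position contributes 0; the
    denominator is always the number of samples.
    """
    if not tracks:
        raise ValueError("no tracks to average")
    out = ScoreTrack(tracks[0].kind, "mean")
    n = len(tracks)
    chroms = sorted({c for t in tracks for c in t.chroms()})
    for chrom in chroms:
        positions = set()
        for t in tracks:
            positions.update(t._data.get(chrom, {}))
        for pos in positions:
            total = sum(t._data.get(chrom, {}).get(pos, 0.0) for t in tracks)
            out.set(chrom, pos, total / n)
    return out


# ---------------------------------------------------------------------------
# depth from aligned blocks


def intron_depth_from_blocks(
    reads: Iterable[ReadBlocks], introns: Sequence[IntronRecord], label: str = ""
) -> ScoreTrack:
    """Per-sample intronic depth track.

    A read is excluded from an intron when one of its splice gaps spans the
    whole intron (it is a linearly-spliced read across the intron); remaining
    reads add +1 to each covered kept-block position.
    """
    trees: dict[str, IntervalTree] = {}
    for intron in introns:
        trees.setdefault(intron.chrom, IntervalTree()).addi(
            intron.start, intron.end, intron
        )
    track = ScoreTrack(DEPTH, label)
    for read in reads:
        tree = trees.get(read.chrom)
        if tree is None:
            continue
        touched: set[int] = set()  # read contributes at most +1 per position
        cands: dict[str, IntronRecord] = {}
        for bs, be in read.blocks:
            for iv in tree.overlap(bs, be):
                cands[iv.data.intron_id] = iv.data
        for intron in cands.values():
            if read.spans_gap_over(intron.start, intron.end):
                continue
            for bs, be in read.blocks:
                for ks, ke in intron.kept_blocks:
                    for pos in range(max(bs, ks), min(be, ke)):
                        if pos not in touched:
                            track.add(read.chrom, pos)
                            touched.add(pos)
    return track


# ---------------------------------------------------------------------------
# whole-intron means


def whole_intron_mean(
    track: ScoreTrack, intron: IntronRecord, trim: int = 10
) -> float | None:
    """Mean score over kept-block positions, trimming ``trim`` bases at both
    splice-site ends of the span.  Missing phyloP positions are excluded from
    both numerator and denominator; returns None when nothing is scored."""
    lo, hi = intron.start + trim, intron.end - trim
    total = 0.0
    n = 0
    for ks, ke in intron.kept_blocks:
        for pos in range(max(ks, lo), min(ke, hi)):
            v = track.get(intron.chrom, pos)
            if v is None:
                continue
            total += v
            n += 1
    return total / n if n else None


# ---------------------------------------------------------------------------
# anchored profiles


@dataclass
class ProfileMatrix:
    """Mean score and contributing-intron count per transcript offset."""

    label: str
    anchor: str
    frame: pd.DataFrame  # index: offsets; columns: mean, n

    @property
    def offsets(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    @property
    def means(self) -> pd.Series:
        return self.frame["mean"]

    def write_tsv(self, path: str | Path) -> None:
        df = self.frame.reset_index().rename(columns={"index": "offset"})
        df.insert(0, "group", self.label)
        df.insert(1, "anchor", self.anchor)
        write_table(df, path, "profile")


def anchored_profile(
    track: ScoreTrack,
    introns: Sequence[IntronRecord],
    anchor: str,
    offsets: Iterable[int],
    bp_by_intron: Mapping[str, int] | None = None,
    min_tail: int = 10,
    trim_ends: int = 10,
    label: str = "",
) -> ProfileMatrix:
    """Strand-aware positional mean of a track around an anchor.

    An intron contributes at an offset only when the mapped genomic position
    lies inside the intron span and its kept blocks; BP-anchored profiles
    additionally drop introns with a 3' tail below ``min_tail`` and exclude
    positions within ``trim_ends`` bases of the span ends (splice-site
    signal).  Depth tracks treat unscored positions as 0; phyloP tracks skip
    them.
    """
    if not introns:
        raise ValueError(f"empty intron group for profile {label!r}")
    offsets = list(offsets)
    sums = np.zeros(len(offsets))
    ns = np.zeros(len(offsets), dtype=int)
    for intron in introns:
        if anchor == "donor":
            apos = intron.five_prime_pos
        elif anchor == "acceptor_3ss":
            apos = intron.three_prime_pos
        elif anchor == "bp":
            apos = None if bp_by_intron is None else bp_by_intron.get(intron.intron_id)
            if apos is None or tail_length(apos, intron) < min_tail:
                continue
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
        for j, k in enumerate(offsets):
            pos = apos + k if intron.strand == "+" else apos - k
            if not (intron.start <= pos < intron.end):
                continue
            if not intron.covers(pos):
                continue
            if anchor == "bp" and trim_ends and not (
                intron.start + trim_ends <= pos < intron.end - trim_ends
            ):
                continue
            v = track.get(intron.chrom, pos)
            if v is None:
                continue
            sums[j] += v
            ns[j] += 1
    means = np.divide(sums, ns, out=np.full(len(offsets), np.nan), where=ns > 0)
    frame = pd.DataFrame({"mean": means, "n": ns}, index=pd.Index(offsets, name="offset"))
    return ProfileMatrix(label=label, anchor=anchor, frame=frame)


# ---------------------------------------------------------------------------
# group contrasts


@dataclass
class LogFCProfile:
    logfc: pd.Series  # per offset
    exceedance_fraction: float
    threshold: float


def profile_logfc(
    profile_a: ProfileMatrix | pd.Series,
    profile_b: ProfileMatrix | pd.Series,
    pseudocount: float = 1e-6,
    threshold: float = 1.0,
    exceed_window: tuple[int, int] | None = (-50, 50),
    exclude_zero: bool = True,
) -> LogFCProfile:
    """Per-offset log2 fold change of group means, with exceedance fraction.

    The exceedance fraction is the share of offsets (within
    ``exceed_window``, excluding offset 0 by default — the anchor itself)
    whose log FC is strictly above ``threshold``.
    """
    a = profile_a.means if isinstance(profile_a, ProfileMatrix) else profile_a
    b = profile_b.means if isinstance(profile_b, ProfileMatrix) else profile_b
    if not a.index.equals(b.index):
        raise ValueError("profiles have mismatched offsets")
    with np.errstate(invalid="ignore", divide="ignore"):
        logfc = np.log2((a + pseudocount) / (b + pseudocount))
    sel = logfc.dropna()
    if exceed_window is not None:
        sel = sel[(sel.index >= exceed_window[0]) & (sel.index <= exceed_window[1])]
    if exclude_zero:
        sel = sel[sel.index != 0]
    frac = float((sel > threshold).mean()) if len(sel) else float("nan")
    return LogFCProfile(logfc=logfc, exceedance_fraction=frac, threshold=threshold)
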