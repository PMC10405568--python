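"""Branch-point assignment, 3' tails, sequence context, and motif scanning.

The branch point (BP) is the intronic nucleotide (canonically adenine)
attacked during the first splicing transesterification; for a stable lariat
the circle's 3' end marks the BP, while an external experimentally-mapped BP
table can provide an independent annotation.  This module assigns map BPs to
introns, computes 3' tail lengths (BP to 3' splice site distance), extracts
strand-aware sequence windows anchored at the donor, BP, or 3' splice site,
summarises per-position nucleotide frequencies and information content
(Kullback-Leibler divergence against a uniform background, in bits), and
scans BP-centred windows for degenerate IUPAC motifs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._io import read_table, write_table
from .annotation import IntronRecord

log = logging.getLogger(__name__)

RNA_ALPHABET = "ACGU"

IUPAC_RNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: default anchored windows (transcript-oriented offsets)
DONOR_WINDOW = range(0, 21)
ACCEPTOR_WINDOW = range(-20, 1)
BP_WINDOW = range(-10, 11)
BP_SCAN_WINDOW = range(-50, 51)  # 101-nt BP-centred scanning window


# ---------------------------------------------------------------------------
# branch-point records and assignment


@dataclass(frozen=True)
class BranchPointRecord:
    chrom: str
    pos: int  # 0-based
    strand: str
    source: str  # 'caller' | 'external_map'
    support: float = 0.0
    nucleotide: str | None = None


class BranchPointMap:
    """External BP table (chrom, pos, strand, support) indexed per chrom/strand."""

    def __init__(self, records: Iterable[BranchPointRecord]):
        self._by_key: dict[tuple[str, str], list[BranchPointRecord]] = {}
        for r in records:
            self._by_key.setdefault((r.chrom, r.strand), []).append(r)
        self._pos: dict[tuple[str, str], np.ndarray] = {}
        for key, recs in self._by_key.items():
            recs.sort(key=lambda r: r.pos)
            self._pos[key] = np.array([r.pos for r in recs])

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BranchPointMap":
        df = read_table(path)
        return cls(
            BranchPointRecord(
                chrom=row.chrom,
                pos=int(row.pos),
                strand=row.strand,
                source="external_map",
                support=float(getattr(row, "support", 0.0)),
            )
            for row in df.itertuples()
        )

    def in_span(self, intron: IntronRecord) -> list[BranchPointRecord]:
        key = (intron.chrom, intron.strand)
        if key not in self._pos:
            return []
        pos = self._pos[key]
        lo, hi = np.searchsorted(pos, [intron.start, intron.end])
        return self._by_key[key][lo:hi]

    def assign(self, intron: IntronRecord) -> BranchPointRecord | None:
        return assign_bp(intron, self.in_span(intron))


def assign_bp(
    intron: IntronRecord, candidates: Iterable[BranchPointRecord]
) -> BranchPointRecord | None:
    """Pick the max-support BP inside the intron span.

    Ties break by proximity to the 3' splice site, then leftmost position.
    """
    in_span = [
        r
        for r in candidates
        if r.chrom == intron.chrom
        and r.strand == intron.strand
        and intron.start <= r.pos < intron.end
    ]
    if not in_span:
        return None
    tss = intron.three_prime_pos
    return min(in_span, key=lambda r: (-r.support, abs(r.pos - tss), r.pos))


# ---------------------------------------------------------------------------
# 3' tails


def tail_length(bp_pos: int, intron: IntronRecord) -> int:
    """Number of intronic bases strictly 3' of the BP (negative if upstream)."""
    if intron.strand == "+":
        return intron.end - 1 - bp_pos
    return bp_pos - intron.start


def tail_is_discarded(tail: int, intron: IntronRecord | None = None) -> bool:
    """Tails <=1 bp (including negative) are annotation artefacts and dropped.

    When the intron is supplied, a BP lying outside the span (upstream gives
    a tail at least the span length, downstream gives a negative tail) is
    also discarded.
    """
    if tail <= 1:
        return True
    return intron is not None and tail >= intron.span_length


def bp_concordance(
    caller_bps: Mapping[str, int],
    map_bps: Mapping[str, int],
    threshold: int = 20,
) -> dict:
    """Per-intron |caller - map| BP distance summary over the joined introns."""
    shared = sorted(set(caller_bps) & set(map_bps))
    dists = np.array([abs(caller_bps[i] - map_bps[i]) for i in shared], dtype=float)
    if dists.size == 0:
        return {"n": 0, "median": None, "mean": None, "frac_below": None,
                "threshold": threshold}
    return {
        "n": int(dists.size),
        "median": float(np.median(dists)),
        "mean": float(dists.mean()),
        "frac_below": float((dists < threshold).mean()),
        "threshold": threshold,
    }


# ---------------------------------------------------------------------------
# genome access


def _fetch_base(genome, chrom: str, pos: int) -> str:
    """Return the DNA base (upper case) or 'N' when out of bounds."""
    try:
        seq = genome[chrom]
    except KeyError:
        return "N"
    if pos < 0 or pos >= len(seq):
        return "N"
    base = str(seq[pos : pos + 1]).upper()
    return base if base in "ACGTN" else "N"


def _to_rna(base: str, strand: str) -> str:
    if strand == "-":
        base = base.translate(_DNA_COMPLEMENT)
    return "U" if base == "T" else base


def bp_nucleotide(genome, chrom: str, pos: int, strand: str) -> str:
    """RNA nucleotide at a BP position (reverse-complemented on minus strand)."""
    return _to_rna(_fetch_base(genome, chrom, pos), strand)


def bp_nucleotide_distribution(nucleotides: Iterable[str]) -> dict[str, float]:
    """Fractions over {A, C, G, U}; raises on an empty input set."""
    nts = [n for n in nucleotides if n in RNA_ALPHABET]
    if not nts:
        raise ValueError("no branch-point nucleotides to summarise")
    n = len(nts)
    return {a: nts.count(a) / n for a in RNA_ALPHABET}


# ---------------------------------------------------------------------------
# sequence windows


@dataclass(frozen=True)
class SequenceWindow:
    """Transcript-oriented sequence around an anchor (negative = upstream)."""

    intron_id: str
    chrom: str
    strand: str
    anchor: str  # 'donor' | 'acceptor_3ss' | 'bp'
    anchor_pos: int  # genomic
    offsets: tuple[int, ...]
    sequence: str  # RNA alphabet, 5'->3' in transcript orientation
    mask: tuple[bool, ...]  # True = excluded from summaries

    def genomic_position(self, offset: int) -> int:
        return self.anchor_pos + offset if self.strand == "+" else self.anchor_pos - offset


def _anchor_position(
    intron: IntronRecord, anchor: str, bp_pos: int | None
) -> int | None:
    if anchor == "donor":
        return intron.five_prime_pos
    if anchor == "acceptor_3ss":
        return intron.three_prime_pos
    if anchor == "bp":
        return bp_pos
    raise ValueError(f"unknown anchor {anchor!r}")


def extract_windows(
    introns: Iterable[IntronRecord],
    genome,
    anchor: str,
    offsets: Iterable[int],
    bp_by_intron: Mapping[str, int] | None = None,
    min_tail: int = 10,
    mask_near_3ss: int | None = 10,
) -> list[SequenceWindow]:
    """Extract strand-aware anchored windows, 5'->3' of the transcript.

    BP-anchored windows drop introns whose BP-to-3'SS distance is below
    ``min_tail`` and mask in-window positions within ``mask_near_3ss`` nt of
    the 3' splice site.  Positions outside the intron span or the chromosome
    are masked (sequence 'N').
    """
    offsets = tuple(offsets)
    out: list[SequenceWindow] = []
    for intron in introns:
        bp_pos = None if bp_by_intron is None else bp_by_intron.get(intron.intron_id)
        if anchor == "bp":
            if bp_pos is None:
                continue
            if tail_length(bp_pos, intron) < min_tail:
                continue
        apos = _anchor_position(intron, anchor, bp_pos)
        if apos is None:
            continue
        seq = []
        mask = []
        for k in offsets:
            pos = apos + k if intron.strand == "+" else apos - k
            base = _to_rna(_fetch_base(genome, intron.chrom, pos), intron.strand)
            masked = base == "N" or not (intron.start <= pos < intron.end)
            if (
                anchor == "bp"
                and mask_near_3ss is not None
                and abs(pos - intron.three_prime_pos) <= mask_near_3ss
            ):
                masked = True
            seq.append(base)
            mask.append(masked)
        out.append(
            SequenceWindow(
                intron_id=intron.intron_id,
                chrom=intron.chrom,
                strand=intron.strand,
                anchor=anchor,
                anchor_pos=apos,
                offsets=offsets,
                sequence="".join(seq),
                mask=tuple(mask),
            )
        )
    return out


# ---------------------------------------------------------------------------
# positional profiles and information content


@dataclass
class PositionProfile:
    offsets: tuple[int, ...]
    frequencies: pd.DataFrame  # offsets x ACGU, rows sum to 1 where n > 0
    bits: pd.Series
    n_sequences: pd.Series


def information_content(
    frequencies: np.ndarray | Sequence[float], background: float | Sequence[float] = 0.25
) -> np.ndarray | float:
    """Kullback-Leibler divergence from the background, in bits per offset.

    ``frequencies`` is (..., 4) over A/C/G/U; 0 * log(0) := 0.  A background
    with a zero entry is rejected.
    """
    p = np.asarray(frequencies, dtype=float)
    q = np.broadcast_to(np.asarray(background, dtype=float), p.shape)
    if np.any(q <= 0):
        raise ValueError("background frequencies must be strictly positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / q), 0.0)
    bits = terms.sum(axis=-1)
    return float(bits) if bits.ndim == 0 else bits


def position_profile(windows: Sequence[SequenceWindow]) -> PositionProfile:
    """Per-offset nucleotide frequencies, information content, and coverage."""
    if not windows:
        raise ValueError("no sequence windows supplied")
    offsets = windows[0].offsets
    counts = np.zeros((len(offsets), 4), dtype=float)
    idx = {a: i for i, a in enumerate(RNA_ALPHABET)}
    for w in windows:
        if w.offsets != offsets:
            raise ValueError("windows have mismatched offsets")
        for j, (base, masked) in enumerate(zip(w.sequence, w.mask)):
            if not masked and base in idx:
                counts[j, idx[base]] += 1
    n = counts.sum(axis=1)
    freqs = np.divide(counts, n[:, None], out=np.zeros_like(counts), where=n[:, None] > 0)
    bits = np.where(n > 0, information_content(freqs), np.nan)
    freq_df = pd.DataFrame(freqs, index=list(offsets), columns=list(RNA_ALPHABET))
    return PositionProfile(
        offsets=offsets,
        frequencies=freq_df,
        bits=pd.Series(bits, index=list(offsets)),
        n_sequences=pd.Series(n.astype(int), index=list(offsets)),
    )


# ---------------------------------------------------------------------------
# IUPAC motif scanning


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int  # hit start relative to the anchor (negative = upstream)
    match: str


@dataclass
class MotifScan:
    motif: str
    hits: list[MotifHit]
    n_sequences: int
    hits_per_sequence: pd.Series  # indexed by sequence id, all sequences

    def summary(self) -> dict:
        counts = self.hits_per_sequence
        offsets = [h.offset for h in self.hits]
        with_hit = counts[counts > 0]
        return {
            "n_sequences": self.n_sequences,
            "frac_with_hit": float((counts > 0).mean()) if len(counts) else 0.0,
            "frac_single_hit": (
                float((with_hit == 1).mean()) if len(with_hit) else float("nan")
            ),
            "median_offset": float(np.median(offsets)) if offsets else float("nan"),
            "hit_count_histogram": counts.value_counts().sort_index().to_dict(),
        }


def _check_motif(motif: str) -> str:
    motif = motif.upper().replace("T", "U")
    bad = [c for c in motif if c not in IUPAC_RNA]
    if bad:
        raise ValueError(f"invalid IUPAC code(s) {bad} in motif {motif!r}")
    return motif


def iupac_scan(
    sequences: Sequence[SequenceWindow] | Sequence[str] | Mapping[str, str],
    motif: str,
) -> MotifScan:
    """Exact degenerate matching of an IUPAC motif on the given strand.

    All (possibly overlapping) matches are reported.  For
    :class:`SequenceWindow` inputs, hit offsets are the window offset of the
    match start (e.g. negative = upstream of the BP anchor).
    """
    motif = _check_motif(motif)
    sets = [IUPAC_RNA[c] for c in motif]
    m = len(motif)

    items: list[tuple[str, str, Sequence[int]]] = []
    if isinstance(sequences, Mapping):
        for sid, seq in sequences.items():
            items.append((sid, seq.upper().replace("T", "U"), range(len(seq))))
    else:
        for i, s in enumerate(sequences):
            if isinstance(s, SequenceWindow):
                items.append((s.intron_id, s.sequence, s.offsets))
            else:
                items.append((f"seq{i}", s.upper().replace("T", "U"), range(len(s))))

    hits: list[MotifHit] = []
    per_seq: dict[str, int] = {}
    for sid, seq, offs in items:
        n = 0
        for i in range(len(seq) - m + 1):
            if all(seq[i + j] in sets[j] for j in range(m)):
                hits.append(MotifHit(sid, offs[i], seq[i : i + m]))
                n += 1
        per_seq[sid] = n
    return MotifScan(
        motif=motif,
        hits=hits,
        n_sequences=len(items),
        hits_per_sequence=pd.Series(per_seq, dtype=int),
    )


def write_motif_hits(scan: MotifScan, path: str | Path) -> None:
    df = pd.DataFrame(
        [(h.sequence_id, h.offset, h.match) for h in scan.hits],
        columns=["sequence_id", "offset", "match"],
    )
    write_table(df, path, "motif_hits")
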