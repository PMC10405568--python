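"""Expression quantification and enrichment statistics.

Covers stranded loose-overlap read counting over intron/gene features,
RPM/FPKM normalization, the pseudocounted relative intron expression
(intron FPKM / parent-gene FPKM) and log fold change, RNase-R enrichment of
circular versus linear junctions with a Fisher exact association test, and
Spearman rank correlation for junction-versus-intron coupling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from ._io import read_table, write_table
from .annotation import IntronRecord
from .tracks import ReadBlocks

log = logging.getLogger(__name__)

PSEUDOCOUNT = 1e-6


class Feature(NamedTuple):
    """A stranded genomic feature for read counting."""

    feature_id: str
    chrom: str
    strand: str
    start: int
    end: int

    @classmethod
    def from_intron(cls, intron: IntronRecord) -> "Feature":
        return cls(intron.intron_id, intron.chrom, intron.strand, intron.start, intron.end)


@dataclass
class ExpressionMatrix:
    """Features x samples values with a normalization state."""

    values: pd.DataFrame
    normalization: str = "raw"  # raw | RPM | FPKM
    lengths: pd.Series | None = None

    def rpm(self, library_sizes: Mapping[str, float]) -> "ExpressionMatrix":
        from .junctions import rpm_normalize

        return ExpressionMatrix(
            rpm_normalize(self.values, library_sizes), "RPM", self.lengths
        )

    def fpkm(self, library_sizes: Mapping[str, float]) -> "ExpressionMatrix":
        return fpkm(self, library_sizes)

    def write_tsv(self, path: str | Path) -> None:
        df = self.values.reset_index().rename(columns={"index": "feature_id"})
        write_table(df, path, f"matrix.{self.normalization}")

    @classmethod
    def read_tsv(
        cls, path: str | Path, normalization: str = "raw", lengths: pd.Series | None = None
    ) -> "ExpressionMatrix":
        df = read_table(path)
        df = df.set_index(df.columns[0])
        return cls(df, normalization, lengths)


# ---------------------------------------------------------------------------
# counting


def count_reads(
    reads_by_sample: Mapping[str, Iterable[ReadBlocks]],
    features: Sequence[Feature | IntronRecord],
    mode: str = "loose",
) -> ExpressionMatrix:
    """Stranded feature counting with loose overlap semantics.

    In ``loose`` mode a read counts toward a feature when any aligned base
    overlaps the feature span on the same strand, so partially overlapping
    pre-mRNA reads are counted and a read may count toward multiple features
    (no unique assignment).  ``within`` requires the read to lie entirely
    inside the feature.
    """
    if mode not in ("loose", "within"):
        raise ValueError(f"unknown counting mode {mode!r}")
    feats = [
        f if isinstance(f, Feature) else Feature.from_intron(f) for f in features
    ]
    trees: dict[tuple[str, str], IntervalTree] = {}
    for f in feats:
        trees.setdefault((f.chrom, f.strand), IntervalTree()).addi(f.start, f.end, f)

    samples = list(reads_by_sample)
    counts = pd.DataFrame(
        0, index=[f.feature_id for f in feats], columns=samples, dtype=int
    )
    for sample, reads in reads_by_sample.items():
        for read in reads:
            tree = trees.get((read.chrom, read.strand))
            if tree is None:
                continue
            hit: set[str] = set()
            for bs, be in read.blocks:
                for iv in tree.overlap(bs, be):
                    hit.add(iv.data.feature_id)
            if mode == "within" and hit:
                lo = read.blocks[0][0]
                hi = read.blocks[-1][1]
                hit = {
                    fid
                    for fid in hit
                    for f in [next(x for x in feats if x.feature_id == fid)]
                    if f.start <= lo and hi <= f.end
                }
            for fid in hit:
                counts.loc[fid, sample] += 1
    lengths = pd.Series({f.feature_id: f.end - f.start for f in feats})
    return ExpressionMatrix(counts, "raw", lengths)


# ---------------------------------------------------------------------------
# normalization and ratios


def fpkm(
    matrix: ExpressionMatrix, library_sizes: Mapping[str, float]
) -> ExpressionMatrix:
    """Fragments per kilobase per million: count * 1e9 / (length * library)."""
    if matrix.lengths is None:
        raise ValueError("FPKM requires feature lengths")
    lengths = matrix.lengths.reindex(matrix.values.index)
    if lengths.isna().any() or (lengths <= 0).any():
        bad = lengths.index[lengths.isna() | (lengths <= 0)].tolist()
        raise ValueError(f"missing or non-positive lengths for features: {bad[:5]}")
    missing = [s for s in matrix.values.columns if s not in library_sizes]
    if missing:
        raise KeyError(f"missing library size for sample(s): {missing}")
    out = matrix.values.astype(float).copy()
    for s in out.columns:
        out[s] = out[s] * 1e9 / (lengths * library_sizes[s])
    return ExpressionMatrix(out, "FPKM", matrix.lengths)


def relative_intron_expression(intron_fpkm, gene_fpkm, pseudocount: float = PSEUDOCOUNT):
    """(intron FPKM + pc) / (parent gene FPKM + pc); element-wise on arrays."""
    a = np.asarray(intron_fpkm, dtype=float)
    b = np.asarray(gene_fpkm, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("FPKM values must be non-negative")
    ratio = (a + pseudocount) / (b + pseudocount)
    return float(ratio) if ratio.ndim == 0 else ratio


def logfc(mean_a1: float, mean_a2: float, pseudocount: float = PSEUDOCOUNT) -> float:
    """log2((a1 + 1e-06) / (a2 + 1e-06)) on non-negative group means."""
    if mean_a1 < 0 or mean_a2 < 0:
        raise ValueError("group means must be non-negative")
    return math.log2((mean_a1 + pseudocount) / (mean_a2 + pseudocount))


# ---------------------------------------------------------------------------
# statistics


class FisherResult(NamedTuple):
    odds_ratio: float
    p: float


def fisher_2x2(table) -> FisherResult:
    """Two-sided conditional Fisher exact test with the sample odds ratio.

    The p-value sums hypergeometric tables (fixed margins) whose point
    probability does not exceed the observed table's.  A zero margin yields
    p = 1 and an undefined (NaN) odds ratio.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    (a, b), (c, d) = t
    if min(a + b, c + d, a + c, b + d) == 0:
        return FisherResult(float("nan"), 1.0)
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = float("inf")
    else:
        odds = float("nan")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return FisherResult(odds, float(p))


def spearman(x, y) -> float:
    """Spearman rank correlation (mid-ranks on ties); NaN when undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


# ---------------------------------------------------------------------------
# RNase R enrichment


@dataclass
class EnrichmentResult:
    per_junction: pd.DataFrame  # junction_id, kind, ratio, enriched
    contingency: np.ndarray  # rows: circular, linear; cols: enriched, not
    odds_ratio: float
    p: float
    n_circular: int
    n_linear: int

    @property
    def frac_circular_enriched(self) -> float:
        n = self.contingency[0].sum()
        return self.contingency[0, 0] / n if n else float("nan")

    @property
    def frac_linear_enriched(self) -> float:
        n = self.contingency[1].sum()
        return self.contingency[1, 0] / n if n else float("nan")


def rnase_r_enrichment(
    circular: pd.DataFrame,
    linear: pd.DataFrame,
    library_sizes: Mapping[str, float],
    min_reads: int = 2,
) -> EnrichmentResult:
    """RNase-R enrichment of circular junctions against linear counterparts.

    Inputs carry columns ``junction_id``, ``treated``, ``control`` (raw
    junction reads); linear junction ids name the circular counterpart's
    intron.  Circular junctions must be present (>= ``min_reads`` reads) in
    both treated and control samples; linear junctions are included only
    when their circular counterpart is.  Enrichment is a treated/control RPM
    ratio strictly above one (a zero-control junction is enriched, ratio
    +inf).  The association between junction type and enrichment is tested
    with a two-sided Fisher exact test.
    """
    for name in ("treated", "control"):
        if name not in library_sizes:
            raise KeyError(f"missing library size for condition {name!r}")

    circ = circular.set_index("junction_id")
    keep = circ[(circ["treated"] >= min_reads) & (circ["control"] >= min_reads)]

    lin = linear.set_index("junction_id")
    lin = lin[lin.index.isin(keep.index)]
    lin = lin[(lin["treated"] + lin["control"]) > 0]

    rows = []
    for kind, df in (("circular", keep), ("linear", lin)):
        t_rpm = df["treated"] * 1e6 / library_sizes["treated"]
        c_rpm = df["control"] * 1e6 / library_sizes["control"]
        with np.errstate(divide="ignore"):
            ratio = np.where(c_rpm > 0, t_rpm / c_rpm, np.inf)
        for jid, r in zip(df.index, ratio):
            rows.append({"junction_id": jid, "kind": kind, "ratio": r, "enriched": r > 1})
    per = pd.DataFrame(rows, columns=["junction_id", "kind", "ratio", "enriched"])

    def _cell(kind: str, enriched: bool) -> int:
        return int(((per["kind"] == kind) & (per["enriched"] == enriched)).sum())

    table = np.array(
        [
            [_cell("circular", True), _cell("circular", False)],
            [_cell("linear", True), _cell("linear", False)],
        ]
    )
    fr = fisher_2x2(table)
    return EnrichmentResult(
        per_junction=per,
        contingency=table,
        odds_ratio=fr.odds_ratio,
        p=fr.p,
        n_circular=int(len(keep)),
        n_linear=int(len(lin)),
    )
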