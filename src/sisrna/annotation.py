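"""Unique, non-exon-overlapping intron annotation.

Circular stable intronic sequence RNAs (sisRNAs) are interpreted against a
*collapsed* intron universe: per gene, intron annotations from all isoforms
are union-merged, and any position covered by an exon (of an alternative
isoform, or optionally of any gene on the same strand) is subtracted from the
intron so that downstream read-depth and conservation summaries are not
contaminated by exonic signal.  Host-candidate introns are those with a
collapsed span between 100 and 10 000 bp.

All coordinates are 0-based half-open genomic intervals.  GTF input
(1-based, inclusive) is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from ._io import SCHEMA_VERSION

log = logging.getLogger(__name__)

Interval = tuple[int, int]

#: host-candidate span-length bounds (collapsed span, not kept-block total)
MIN_HOST_INTRON_LEN = 100
MAX_HOST_INTRON_LEN = 10_000


# ---------------------------------------------------------------------------
# interval arithmetic


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union-merge possibly overlapping half-open intervals."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return [(s, e) for s, e in out]


def subtract_intervals(span: Interval, mask: Sequence[Interval]) -> list[Interval]:
    """Return the parts of ``span`` not covered by the merged ``mask``."""
    start, end = span
    out: list[Interval] = []
    cur = start
    for ms, me in mask:
        if me <= cur or ms >= end:
            continue
        if ms > cur:
            out.append((cur, min(ms, end)))
        cur = max(cur, me)
        if cur >= end:
            break
    if cur < end:
        out.append((cur, end))
    return out


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GeneModel:
    """A gene with one exon-interval list per transcript.

    Exons within a transcript must be disjoint and sorted; all exons share
    the gene's chromosome and strand.
    """

    gene_id: str
    biotype: str
    chrom: str
    strand: str
    transcripts: tuple[tuple[Interval, ...], ...]


@dataclass(frozen=True)
class IntronRecord:
    """A collapsed intron with exon-masked kept blocks."""

    intron_id: str
    chrom: str
    strand: str
    start: int
    end: int
    kept_blocks: tuple[Interval, ...]
    gene_id: str

    @property
    def span_length(self) -> int:
        return self.end - self.start

    @property
    def kept_length(self) -> int:
        return sum(e - s for s, e in self.kept_blocks)

    @property
    def five_prime_pos(self) -> int:
        """Genomic position of the 5' splice site (first intronic base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime_pos(self) -> int:
        """Genomic position of the 3' splice site (last intronic base)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def is_host_candidate(self) -> bool:
        return MIN_HOST_INTRON_LEN <= self.span_length <= MAX_HOST_INTRON_LEN

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end

    def covers(self, pos: int) -> bool:
        """True if ``pos`` lies in one of the kept (non-exonic) blocks."""
        return any(s <= pos < e for s, e in self.kept_blocks)


# ---------------------------------------------------------------------------
# intron building


def _transcript_introns(exons: Sequence[Interval]) -> list[Interval]:
    prev_end = None
    out: list[Interval] = []
    for s, e in exons:
        if e <= s:
            raise ValueError(f"empty or inverted exon ({s}, {e})")
        if prev_end is not None:
            if s < prev_end:
                raise ValueError("exons overlap or are unsorted")
            if s > prev_end:
                out.append((prev_end, s))
        prev_end = e
    return out


def build_unique_introns(
    genes: Iterable[GeneModel], mask_scope: str = "gene"
) -> list[IntronRecord]:
    """Collapse isoform introns per gene and subtract exonic positions.

    ``mask_scope='gene'`` subtracts exons of the intron's own gene only
    (alternative isoforms); ``mask_scope='strand'`` subtracts exons of every
    gene on the same chromosome and strand.

    Transcripts with fewer than two exons yield no introns; transcripts with
    malformed exon order are rejected with a logged report.
    """
    if mask_scope not in ("gene", "strand"):
        raise ValueError(f"unknown mask_scope {mask_scope!r}")
    genes = list(genes)

    strand_exons: dict[tuple[str, str], list[Interval]] = {}
    if mask_scope == "strand":
        for g in genes:
            acc = strand_exons.setdefault((g.chrom, g.strand), [])
            for tx in g.transcripts:
                acc.extend(tx)
        strand_exons = {k: merge_intervals(v) for k, v in strand_exons.items()}

    records: list[IntronRecord] = []
    n_rejected = 0
    for g in genes:
        introns: list[Interval] = []
        own_exons: list[Interval] = []
        for tx in g.transcripts:
            own_exons.extend(tx)
            try:
                introns.extend(_transcript_introns(tx))
            except ValueError as exc:
                n_rejected += 1
                log.warning("rejected transcript of %s: %s", g.gene_id, exc)
        spans = merge_intervals(introns)
        if not spans:
            continue
        if mask_scope == "gene":
            mask = merge_intervals(own_exons)
        else:
            mask = strand_exons[(g.chrom, g.strand)]
        # ordinal along transcription direction
        ordered = spans if g.strand == "+" else spans[::-1]
        for i, (s, e) in enumerate(ordered, start=1):
            kept = tuple(subtract_intervals((s, e), mask))
            records.append(
                IntronRecord(
                    intron_id=f"{g.gene_id}_intron{i}",
                    chrom=g.chrom,
                    strand=g.strand,
                    start=s,
                    end=e,
                    kept_blocks=kept,
                    gene_id=g.gene_id,
                )
            )
    if n_rejected:
        log.warning("rejected %d malformed transcripts", n_rejected)
    return records


def filter_host_candidates(
    introns: Iterable[IntronRecord],
    min_len: int = MIN_HOST_INTRON_LEN,
    max_len: int = MAX_HOST_INTRON_LEN,
) -> list[IntronRecord]:
    return [r for r in introns if min_len <= r.span_length <= max_len]


# ---------------------------------------------------------------------------
# host-intron assignment


@dataclass(frozen=True)
class HostAssignment:
    intron: IntronRecord
    concordant_5p: bool
    offset_5p: int


class IntronIndex:
    """Interval index over introns for host assignment."""

    def __init__(self, introns: Iterable[IntronRecord]):
        self.introns: list[IntronRecord] = list(introns)
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self.by_id: dict[str, IntronRecord] = {}
        for rec in self.introns:
            tree = self._trees.setdefault((rec.chrom, rec.strand), IntervalTree())
            tree.addi(rec.start, rec.end, rec)
            self.by_id[rec.intron_id] = rec

    def containing(
        self, chrom: str, start: int, end: int, strand: str
    ) -> list[IntronRecord]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        hits = tree.overlap(start, end)
        return [iv.data for iv in hits if iv.begin <= start and iv.end >= end]

    def assign_host(
        self,
        chrom: str,
        start: int,
        end: int,
        strand: str,
        max_5p_offset: int = 10,
    ) -> HostAssignment | None:
        """Return the shortest intron fully containing the query interval.

        Ties on span length break on smaller start, then lexicographic
        intron_id.  The 5'-concordance flag marks queries whose 5' end lies
        within ``max_5p_offset`` of the host intron's 5' splice site.
        """
        cands = self.containing(chrom, start, end, strand)
        if not cands:
            return None
        host = min(cands, key=lambda r: (r.span_length, r.start, r.intron_id))
        q5 = start if strand == "+" else end - 1
        off = abs(q5 - host.five_prime_pos)
        return HostAssignment(host, off <= max_5p_offset, off)


# ---------------------------------------------------------------------------
# GTF reading


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene/transcript/exon features) from a GTF file.

    1-based inclusive GTF coordinates are converted to 0-based half-open.
    The gene biotype is taken from ``gene_type`` or ``gene_biotype``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        biotype = (
            gene.attributes.get("gene_type") or gene.attributes.get("gene_biotype") or ["unknown"]
        )[0]
        transcripts = []
        for tx in db.children(gene, featuretype="transcript", order_by="start"):
            exons = tuple(
                sorted(
                    (ex.start - 1, ex.end)
                    for ex in db.children(tx, featuretype="exon")
                )
            )
            if exons:
                transcripts.append(exons)
        if transcripts:
            genes.append(
                GeneModel(
                    gene_id=gene.id,
                    biotype=biotype,
                    chrom=gene.seqid,
                    strand=gene.strand,
                    transcripts=tuple(transcripts),
                )
            )
    return genes


# ---------------------------------------------------------------------------
# BED12 round trip


def write_intron_bed(introns: Iterable[IntronRecord], path: str | Path) -> None:
    """Write introns as BED12 + gene_id, kept_blocks as blockStarts/Sizes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# sisrna/introns.bed12/v{SCHEMA_VERSION}\n")
        fh.write(
            "#chrom\tstart\tend\tname\tscore\tstrand\tthickStart\tthickEnd"
            "\titemRgb\tblockCount\tblockSizes\tblockStarts\tgene_id\n"
        )
        for r in sorted(introns, key=lambda r: (r.chrom, r.start, r.end, r.intron_id)):
            sizes = ",".join(str(e - s) for s, e in r.kept_blocks)
            starts = ",".join(str(s - r.start) for s, e in r.kept_blocks)
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.intron_id}\t0\t{r.strand}"
                f"\t{r.start}\t{r.end}\t0\t{len(r.kept_blocks)}\t{sizes}\t{starts}"
                f"\t{r.gene_id}\n"
            )


def read_intron_bed(path: str | Path) -> list[IntronRecord]:
    out: list[IntronRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            start, end = int(f[1]), int(f[2])
            sizes = [int(x) for x in f[10].split(",") if x]
            starts = [int(x) for x in f[11].split(",") if x]
            blocks = tuple(
                (start + off, start + off + size) for off, size in zip(starts, sizes)
            )
            out.append(
                IntronRecord(
                    intron_id=f[3],
                    chrom=f[0],
                    strand=f[5],
                    start=start,
                    end=end,
                    kept_blocks=blocks,
                    gene_id=f[12] if len(f) > 12 else "",
                )
            )
    return out
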