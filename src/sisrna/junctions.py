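"""Circular junction parsing, filtering, collapsing, and classification.

A circular sisRNA junction joins the intron's 5' splice site (donor) to a
3'-most circularized base: the branch point for a stable lariat (2'-5' bond)
or the 3' splice site for a full-length intronic circle (3'-5' bond).
Reverse transcriptase frequently stumbles over the 2'-5' linkage, so calls
from the same intron often share the donor but scatter in their 3' end; such
calls are collapsed into one cluster represented by the end with the most
supporting junction-spanning reads.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from ._io import write_table
from .annotation import HostAssignment, IntronIndex, IntronRecord

log = logging.getLogger(__name__)

MITOCHONDRIAL_CHROMS = frozenset({"chrM", "chrMT", "M", "MT"})

#: circle-length bounds (|acceptor - donor| + 1)
MIN_CIRCLE_LEN = 30
MAX_CIRCLE_LEN = 10_000


@dataclass(frozen=True)
class JunctionCall:
    """One per-sample circular junction call."""

    sample_id: str
    chrom: str
    strand: str
    donor_pos: int
    acceptor_pos: int
    read_count: int
    caller: str = ""

    @property
    def circle_length(self) -> int:
        return abs(self.acceptor_pos - self.donor_pos) + 1


class ClusterMember(NamedTuple):
    end: int
    reads: int
    n_samples: int


@dataclass
class SisRNACluster:
    """Collapsed junction evidence for one (host intron, donor) pair."""

    cluster_id: str
    intron: IntronRecord
    donor_pos: int
    members: tuple[ClusterMember, ...]
    representative_end: int
    counts: dict[str, int]
    n_samples_expressed: int
    high_confidence: bool
    cls: str | None = None  # 'stable_lariat' | 'intronic_circle'

    @property
    def chrom(self) -> str:
        return self.intron.chrom

    @property
    def strand(self) -> str:
        return self.intron.strand

    @property
    def total_reads(self) -> int:
        return sum(m.reads for m in self.members)

    @property
    def circle_length(self) -> int:
        return abs(self.representative_end - self.donor_pos) + 1


# ---------------------------------------------------------------------------
# parsing


def read_junction_table(
    path: str | Path,
    dialect: str,
    sample_id: str | None = None,
    caller: str = "",
) -> list[JunctionCall]:
    """Parse a per-sample circular junction table.

    ``circexplorer2_bed``: BED columns chrom/start/end/name/score/strand with
    the junction-read count in the score column.  ``generic_tsv``: headered
    TSV with columns chrom, start, end, strand, read_count.  On the minus
    strand the donor is the interval end - 1 and the acceptor the start.
    Unparseable rows (including end < start) are skipped with a logged count.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    calls: list[JunctionCall] = []
    skipped = 0
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if dialect == "circexplorer2_bed":
                    chrom, start, end = f[0], int(f[1]), int(f[2])
                    reads, strand = int(f[4]), f[5]
                elif dialect == "generic_tsv":
                    if not header_seen and not f[1].lstrip("-").isdigit():
                        header_seen = True
                        continue
                    chrom, start, end, strand = f[0], int(f[1]), int(f[2]), f[3]
                    reads = int(f[4])
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
                if end <= start or strand not in "+-" or reads < 0:
                    raise ValueError("invalid row")
            except (ValueError, IndexError):
                if dialect not in ("circexplorer2_bed", "generic_tsv"):
                    raise
                skipped += 1
                continue
            donor = start if strand == "+" else end - 1
            acceptor = end - 1 if strand == "+" else start
            calls.append(
                JunctionCall(sample_id, chrom, strand, donor, acceptor, reads, caller)
            )
    if skipped:
        log.warning("%s: skipped %d unparseable rows", path, skipped)
    return calls


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterCounts:
    input: int = 0
    kept: int = 0
    removed_mito: int = 0
    removed_length: int = 0
    removed_no_host: int = 0
    removed_biotype: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass(frozen=True)
class AnnotatedCall:
    call: JunctionCall
    intron: IntronRecord
    concordant_5p: bool


def filter_junctions(
    calls: Iterable[JunctionCall],
    index: IntronIndex,
    biotype_by_gene: Mapping[str, str],
    min_len: int = MIN_CIRCLE_LEN,
    max_len: int = MAX_CIRCLE_LEN,
    max_5p_offset: int = 10,
) -> tuple[list[AnnotatedCall], FilterCounts]:
    """Apply the sisRNA call filters and assign host introns.

    Removes mitochondrial calls, circle lengths outside [min_len, max_len],
    calls with no containing intron, and calls hosted by non-protein-coding
    genes.  The >=2-samples rule is applied later at cluster level.
    """
    counts = FilterCounts()
    kept: list[AnnotatedCall] = []
    for call in calls:
        counts.input += 1
        if call.chrom in MITOCHONDRIAL_CHROMS:
            counts.removed_mito += 1
            continue
        if not (min_len <= call.circle_length <= max_len):
            counts.removed_length += 1
            continue
        lo = min(call.donor_pos, call.acceptor_pos)
        hi = max(call.donor_pos, call.acceptor_pos) + 1
        host = index.assign_host(call.chrom, lo, hi, call.strand, max_5p_offset)
        if host is None:
            counts.removed_no_host += 1
            continue
        if biotype_by_gene.get(host.intron.gene_id, "") != "protein_coding":
            counts.removed_biotype += 1
            continue
        counts.kept += 1
        kept.append(AnnotatedCall(call, host.intron, host.concordant_5p))
    return kept, counts


# ---------------------------------------------------------------------------
# collapsing


def collapse_junctions(annotated: Iterable[AnnotatedCall]) -> list[SisRNACluster]:
    """Collapse calls sharing (host intron, donor) into clusters.

    Member ends are aggregated across samples; the representative end is the
    member with the most total reads (ties: seen in more samples, then
    smaller distance to the annotated 3' splice site, then leftmost).
    Evidence-free (zero-read) calls are dropped here.
    """
    groups: dict[tuple[str, int], list[AnnotatedCall]] = defaultdict(list)
    for ac in annotated:
        if ac.call.read_count <= 0:
            continue
        groups[(ac.intron.intron_id, ac.call.donor_pos)].append(ac)

    clusters: list[SisRNACluster] = []
    for (intron_id, donor), acs in sorted(groups.items()):
        intron = acs[0].intron
        by_end: dict[int, dict[str, int]] = defaultdict(lambda: defaultdict(int))
        counts: dict[str, int] = defaultdict(int)
        for ac in acs:
            by_end[ac.call.acceptor_pos][ac.call.sample_id] += ac.call.read_count
            counts[ac.call.sample_id] += ac.call.read_count
        members = tuple(
            sorted(
                (
                    ClusterMember(end, sum(per.values()), len(per))
                    for end, per in by_end.items()
                ),
                key=lambda m: m.end,
            )
        )
        tss = intron.three_prime_pos
        rep = min(
            members,
            key=lambda m: (-m.reads, -m.n_samples, abs(m.end - tss), m.end),
        )
        clusters.append(
            SisRNACluster(
                cluster_id=f"{intron_id}:{donor}",
                intron=intron,
                donor_pos=donor,
                members=members,
                representative_end=rep.end,
                counts=dict(counts),
                n_samples_expressed=sum(1 for v in counts.values() if v > 0),
                high_confidence=any(ac.concordant_5p for ac in acs),
            )
        )
    return clusters


def expressed_in_min_samples(
    clusters: Iterable[SisRNACluster], min_samples: int = 2
) -> list[SisRNACluster]:
    """Keep clusters with nonzero junction reads in >= min_samples samples."""
    return [c for c in clusters if c.n_samples_expressed >= min_samples]


# ---------------------------------------------------------------------------
# classification

STABLE_LARIAT = "stable_lariat"
INTRONIC_CIRCLE = "intronic_circle"


class ClassificationError(ValueError):
    """Representative end falls outside the host intron span."""


def classify_cluster(cluster: SisRNACluster, tol_3ss: int = 0) -> str:
    """Classify a cluster as intronic circle or stable lariat.

    A cluster is a full-length intronic circle iff its representative end
    lies within ``tol_3ss`` bases of the intron's 3' splice site; otherwise
    the 3' end is an internal branch point and the cluster is a stable
    lariat.
    """
    intron = cluster.intron
    end = cluster.representative_end
    if not (intron.start <= end < intron.end):
        raise ClassificationError(
            f"{cluster.cluster_id}: representative end {end} outside intron span"
        )
    if abs(end - intron.three_prime_pos) <= tol_3ss:
        return INTRONIC_CIRCLE
    return STABLE_LARIAT


def classify_clusters(
    clusters: Iterable[SisRNACluster], tol_3ss: int = 0
) -> tuple[list[SisRNACluster], list[SisRNACluster]]:
    """Classify all clusters; return (classified, excluded-with-report)."""
    ok: list[SisRNACluster] = []
    bad: list[SisRNACluster] = []
    for c in clusters:
        try:
            c.cls = classify_cluster(c, tol_3ss)
            ok.append(c)
        except ClassificationError as exc:
            log.warning("excluded cluster: %s", exc)
            bad.append(c)
    return ok, bad


# ---------------------------------------------------------------------------
# matrices

def counts_matrix(
    clusters: Sequence[SisRNACluster], samples: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-sample junction-read count matrix (clusters x samples)."""
    if samples is None:
        samples = sorted({s for c in clusters for s in c.counts})
    data = {
        c.cluster_id: [c.counts.get(s, 0) for s in samples] for c in clusters
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=list(samples)
    ).sort_index()


def rpm_normalize(
    counts: pd.DataFrame, library_sizes: Mapping[str, float]
) -> pd.DataFrame:
    """Reads per million mapped reads: count * 1e6 / library size."""
    missing = [s for s in counts.columns if s not in library_sizes]
    if missing:
        raise KeyError(f"missing library size for sample(s): {missing}")
    bad = [s for s in counts.columns if library_sizes[s] <= 0]
    if bad:
        raise ValueError(f"non-positive library size for sample(s): {bad}")
    factors = pd.Series({s: 1e6 / library_sizes[s] for s in counts.columns})
    return counts * factors


# ---------------------------------------------------------------------------
# caller agreement

ClusterKey = tuple[str, str, int, int]  # chrom, strand, donor, representative end


@dataclass
class OverlapSummary:
    per_caller: dict[str, float]
    overall: float
    n_per_caller: dict[str, int]


def caller_overlap(
    cluster_sets: Mapping[str, Iterable[ClusterKey]], tol: int = 0
) -> OverlapSummary:
    """Cross-caller agreement of cluster coordinates.

    A cluster is supported by another caller when that caller has a cluster
    on the same chrom/strand with donor and representative end each within
    ``tol``.  Reports, per caller and pooled, the fraction of clusters
    supported by at least two callers (itself plus >=1 other).
    """
    sets = {c: list(v) for c, v in cluster_sets.items()}
    if len(sets) < 2:
        raise ValueError("need cluster sets from at least two callers")
    grouped: dict[str, dict[tuple[str, str], list[tuple[int, int]]]] = {}
    for caller, keys in sets.items():
        g: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
        for chrom, strand, donor, end in keys:
            g[(chrom, strand)].append((donor, end))
        grouped[caller] = g

    def supported(caller: str, key: ClusterKey) -> bool:
        chrom, strand, donor, end = key
        for other, g in grouped.items():
            if other == caller:
                continue
            for d, e in g.get((chrom, strand), ()):
                if abs(d - donor) <= tol and abs(e - end) <= tol:
                    return True
        return False

    per_caller: dict[str, float] = {}
    n_per: dict[str, int] = {}
    tot = hit = 0
    for caller, keys in sets.items():
        n_per[caller] = len(keys)
        if not keys:
            per_caller[caller] = float("nan")
            continue
        k = sum(supported(caller, key) for key in keys)
        per_caller[caller] = k / len(keys)
        tot += len(keys)
        hit += k
    return OverlapSummary(per_caller, hit / tot if tot else float("nan"), n_per)


# ---------------------------------------------------------------------------
# output


def write_clusters(clusters: Sequence[SisRNACluster], path: str | Path) -> None:
    import json

    rows = []
    for c in sorted(clusters, key=lambda c: c.cluster_id):
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "chrom": c.chrom,
                "strand": c.strand,
                "donor_pos": c.donor_pos,
                "representative_end": c.representative_end,
                "cls": c.cls or "",
                "intron_id": c.intron.intron_id,
                "gene_id": c.intron.gene_id,
                "total_reads": c.total_reads,
                "n_samples_expressed": c.n_samples_expressed,
                "high_confidence": int(c.high_confidence),
                "circle_length": c.circle_length,
                "members": json.dumps([list(m) for m in c.members]),
            }
        )
    write_table(pd.DataFrame(rows), path, "clusters")
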