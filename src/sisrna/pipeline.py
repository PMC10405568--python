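"""End-to-end pipeline: annotation -> junctions -> features -> cohort.

``run_pipeline`` executes the stages in dependency order on whatever inputs
the configuration provides, writes machine-readable outputs plus a manifest
(stage, parameters, record counts in/out per filter), and returns the
in-memory results.  No stage mutates its inputs; filter counts in the
manifest are conserved (input = kept + removed per category).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import annotation, branchpoint, cohort, expression, junctions, tracks
from ._io import write_table

log = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """All fixed analysis constants, each overridable."""

    min_circle_len: int = 30
    max_circle_len: int = 10_000
    min_intron_len: int = 100
    max_intron_len: int = 10_000
    min_cluster_samples: int = 2
    tol_3ss: int = 0
    max_5p_offset: int = 10
    de_min_reads: int = 10
    de_min_samples: int = 10
    q_threshold: float = 0.1
    pseudocount: float = 1e-6
    trim: int = 10
    mask_near_3ss: int = 10
    min_tail: int = 10
    bp_scan_halfwidth: int = 50
    detection_min_reads: int = 2
    survival_cutoff: str | float = "median"


@dataclass
class RunConfig:
    annotation: str | Path
    junction_dir: str | Path
    metadata: str | Path
    outdir: str | Path
    genome: str | Path | None = None
    bp_map: str | Path | None = None
    conservation: str | Path | None = None
    depth: Sequence[str | Path] = ()
    intron_counts: str | Path | None = None
    gene_counts: str | Path | None = None
    rnase_circular: str | Path | None = None
    rnase_linear: str | Path | None = None
    junction_dialect: str = "circexplorer2_bed"
    motif: str | None = "AYAUUAUUAAU"
    mask_scope: str = "gene"
    thresholds: Thresholds = field(default_factory=Thresholds)


@dataclass
class PipelineResult:
    introns: list
    index: annotation.IntronIndex
    clusters: list
    counts: pd.DataFrame
    rpm: pd.DataFrame
    metadata: pd.DataFrame
    manifest: dict
    bp_assigned: dict[str, int] = field(default_factory=dict)
    bp_concordance: dict | None = None
    tails: pd.DataFrame | None = None
    de: pd.DataFrame | None = None
    survival: cohort.KMResult | None = None
    tissue: cohort.TissueSummary | None = None
    fraction: cohort.FractionSummary | None = None
    motif_host_counts: pd.Series | None = None
    motif_control_counts: pd.Series | None = None
    motif_fisher: expression.FisherResult | None = None
    relative_expression: pd.Series | None = None
    junction_intron_spearman: float | None = None
    rnase: expression.EnrichmentResult | None = None
    conservation_logfc: tracks.LogFCProfile | None = None


def run_pipeline(config: RunConfig) -> PipelineResult:
    th = config.thresholds
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "parameters": dataclasses.asdict(th)}

    # ----- stage: annotation -------------------------------------------------
    gtf = Path(config.annotation)
    if not gtf.exists():
        raise FileNotFoundError(f"annotation file not found: {gtf}")
    genes = annotation.read_gtf(gtf)
    introns = annotation.build_unique_introns(genes, mask_scope=config.mask_scope)
    kept_introns = annotation.filter_host_candidates(
        introns, th.min_intron_len, th.max_intron_len
    )
    index = annotation.IntronIndex(kept_introns)
    biotypes = {g.gene_id: g.biotype for g in genes}
    annotation.write_intron_bed(kept_introns, outdir / "introns.bed")
    manifest["stages"]["annotation"] = {
        "n_genes": len(genes),
        "n_introns": len(introns),
        "n_introns_length_filtered": len(kept_introns),
        "median_intron_length": (
            float(np.median([r.span_length for r in introns])) if introns else None
        ),
    }

    # ----- stage: junctions --------------------------------------------------
    meta = cohort.read_metadata(config.metadata)
    jdir = Path(config.junction_dir)
    if not jdir.exists():
        raise FileNotFoundError(f"junction directory not found: {jdir}")
    calls = []
    files = sorted(jdir.glob("*.bed")) + sorted(jdir.glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no junction tables under {jdir}")
    for path in files:
        calls.extend(
            junctions.read_junction_table(path, config.junction_dialect, path.stem)
        )
    annotated, fc = junctions.filter_junctions(
        calls,
        index,
        biotypes,
        min_len=th.min_circle_len,
        max_len=th.max_circle_len,
        max_5p_offset=th.max_5p_offset,
    )
    clusters = junctions.collapse_junctions(annotated)
    n_collapsed = len(clusters)
    clusters = junctions.expressed_in_min_samples(clusters, th.min_cluster_samples)
    clusters, excluded = junctions.classify_clusters(clusters, th.tol_3ss)
    junctions.write_clusters(clusters, outdir / "clusters.tsv")
    cls_counts = pd.Series([c.cls for c in clusters]).value_counts().to_dict()
    manifest["stages"]["junctions"] = {
        "filters": fc.as_dict(),
        "n_clusters_collapsed": n_collapsed,
        "n_clusters_min_samples": len(clusters) + len(excluded),
        "n_clusters_classified": len(clusters),
        "n_clusters_excluded_classification": len(excluded),
        "class_counts": cls_counts,
    }

    cohort_samples = [
        s for s in meta["sample_id"]
        if (jdir / f"{s}.bed").exists() or (jdir / f"{s}.tsv").exists()
    ]
    counts = junctions.counts_matrix(clusters, cohort_samples)
    libsizes = meta["library_size"].to_dict()
    rpm = junctions.rpm_normalize(counts, libsizes)
    counts.reset_index(names="cluster_id").pipe(
        write_table, outdir / "junction_counts.tsv", "junction_counts"
    )
    rpm.reset_index(names="cluster_id").pipe(
        write_table, outdir / "junction_rpm.tsv", "junction_rpm"
    )

    result = PipelineResult(
        introns=kept_introns,
        index=index,
        clusters=clusters,
        counts=counts,
        rpm=rpm,
        metadata=meta,
        manifest=manifest,
    )

    host_ids = {c.intron.intron_id for c in clusters}
    lariat_hosts = [c.intron for c in clusters if c.cls == junctions.STABLE_LARIAT]
    by_id = {r.intron_id: r for r in kept_introns}

    # ----- stage: branch points ---------------------------------------------
    bp_map = None
    if config.bp_map:
        bp_map = branchpoint.BranchPointMap.read_tsv(config.bp_map)
        assigned: dict[str, int] = {}
        tail_rows = []
        for rec in kept_introns:
            bp = bp_map.assign(rec)
            if bp is None:
                continue
            assigned[rec.intron_id] = bp.pos
            t = branchpoint.tail_length(bp.pos, rec)
            tail_rows.append(
                {
                    "intron_id": rec.intron_id,
                    "bp_pos": bp.pos,
                    "tail": t,
                    "discarded": branchpoint.tail_is_discarded(t),
                }
            )
        result.bp_assigned = assigned
        result.tails = pd.DataFrame(tail_rows)
        caller_bps = {
            c.intron.intron_id: c.representative_end
            for c in clusters
            if c.cls == junctions.STABLE_LARIAT
        }
        result.bp_concordance = branchpoint.bp_concordance(caller_bps, assigned)
        write_table(result.tails, outdir / "bp_tails.tsv", "bp_tails")
        manifest["stages"]["branchpoint"] = {
            "n_introns_with_map_bp": len(assigned),
            "concordance": result.bp_concordance,
        }

    # ----- stage: sequence context / motif ----------------------------------
    genome = None
    if config.genome:
        from pyfaidx import Fasta

        genome = Fasta(str(config.genome), as_raw=True, sequence_always_upper=True)
    if genome is not None and bp_map is not None and config.motif:
        hw = th.bp_scan_halfwidth
        window = range(-hw, hw + 1)
        bp_by_intron = result.bp_assigned
        host_recs = [by_id[i] for i in sorted(host_ids) if i in bp_by_intron]
        lariat_ids = {r.intron_id for r in lariat_hosts}
        lariat_recs = [r for r in host_recs if r.intron_id in lariat_ids]
        control_recs = [
            r
            for r in kept_introns
            if r.intron_id not in host_ids and r.intron_id in bp_by_intron
        ]
        if lariat_recs and control_recs:
            w_host = branchpoint.extract_windows(
                lariat_recs, genome, "bp", window,
                bp_by_intron=bp_by_intron, min_tail=th.min_tail,
                mask_near_3ss=None,
            )
            w_ctrl = branchpoint.extract_windows(
                control_recs, genome, "bp", window,
                bp_by_intron=bp_by_intron, min_tail=th.min_tail,
                mask_near_3ss=None,
            )
            scan_host = branchpoint.iupac_scan(w_host, config.motif)
            scan_ctrl = branchpoint.iupac_scan(w_ctrl, config.motif)
            result.motif_host_counts = scan_host.hits_per_sequence
            result.motif_control_counts = scan_ctrl.hits_per_sequence
            table = [
                [int((scan_host.hits_per_sequence > 0).sum()),
                 int((scan_host.hits_per_sequence == 0).sum())],
                [int((scan_ctrl.hits_per_sequence > 0).sum()),
                 int((scan_ctrl.hits_per_sequence == 0).sum())],
            ]
            result.motif_fisher = expression.fisher_2x2(table)
            branchpoint.write_motif_hits(scan_host, outdir / "motif_hits_hosts.tsv")
            manifest["stages"]["motif"] = {
                "motif": config.motif,
                "n_host_windows": len(w_host),
                "n_control_windows": len(w_ctrl),
                "summary_hosts": scan_host.summary(),
                "fisher_p": result.motif_fisher.p,
                "odds_ratio": result.motif_fisher.odds_ratio,
            }

    # ----- stage: conservation / depth profiles ------------------------------
    if config.conservation and result.bp_assigned:
        track = tracks.ScoreTrack.from_bedgraph(config.conservation, tracks.PHYLOP)
        hw = th.bp_scan_halfwidth
        window = range(-hw, hw + 1)
        lariat_ids = {r.intron_id for r in lariat_hosts}
        lariat_recs = [by_id[i] for i in sorted(lariat_ids) if i in result.bp_assigned]
        control_recs = [
            r
            for r in kept_introns
            if r.intron_id not in host_ids and r.intron_id in result.bp_assigned
        ]
        if lariat_recs and control_recs:
            prof_l = tracks.anchored_profile(
                track, lariat_recs, "bp", window,
                bp_by_intron=result.bp_assigned, min_tail=th.min_tail,
                trim_ends=th.trim, label="stable_lariat",
            )
            prof_c = tracks.anchored_profile(
                track, control_recs, "bp", window,
                bp_by_intron=result.bp_assigned, min_tail=th.min_tail,
                trim_ends=th.trim, label="non_host",
            )
            prof_l.write_tsv(outdir / "conservation_profile_lariat.tsv")
            prof_c.write_tsv(outdir / "conservation_profile_nonhost.tsv")
            result.conservation_logfc = tracks.profile_logfc(
                prof_l, prof_c, pseudocount=th.pseudocount,
                exceed_window=(-hw, hw),
            )
            manifest["stages"]["conservation"] = {
                "bp_logfc_exceedance": result.conservation_logfc.exceedance_fraction,
            }

    # ----- stage: expression -------------------------------------------------
    if config.intron_counts and config.gene_counts:
        im = expression.ExpressionMatrix.read_tsv(config.intron_counts)
        gm = expression.ExpressionMatrix.read_tsv(config.gene_counts)
        im.lengths = pd.Series({r.intron_id: r.span_length for r in kept_introns})
        gene_spans: dict[str, int] = {}
        for g in genes:
            lo = min(s for tx in g.transcripts for s, _ in tx)
            hi = max(e for tx in g.transcripts for _, e in tx)
            gene_spans[g.gene_id] = hi - lo
        gm.lengths = pd.Series(gene_spans)
        im.lengths = im.lengths.reindex(im.values.index)
        gm.lengths = gm.lengths.reindex(gm.values.index)
        ifpkm = expression.fpkm(im, libsizes).values
        gfpkm = expression.fpkm(gm, libsizes).values
        shared = [s for s in ifpkm.columns if s in gfpkm.columns]
        rel = {}
        rhos = []
        for c in clusters:
            iid = c.intron.intron_id
            gid = c.intron.gene_id
            if iid not in ifpkm.index or gid not in gfpkm.index:
                continue
            imean = float(ifpkm.loc[iid, shared].mean())
            gmean = float(gfpkm.loc[gid, shared].mean())
            rel[c.cluster_id] = expression.relative_intron_expression(
                imean, gmean, th.pseudocount
            )
            jx = rpm.loc[c.cluster_id, shared].to_numpy(dtype=float)
            iv = ifpkm.loc[iid, shared].to_numpy(dtype=float)
            if np.unique(jx).size > 1 and np.unique(iv).size > 1:
                rho = expression.spearman(jx, iv)
                if not np.isnan(rho):
                    rhos.append(rho)
        result.relative_expression = pd.Series(rel)
        result.junction_intron_spearman = float(np.median(rhos)) if rhos else None
        manifest["stages"]["expression"] = {
            "n_relative_expression": len(rel),
            "n_ratio_above_1": int((result.relative_expression > 1).sum()),
            "median_junction_intron_spearman": result.junction_intron_spearman,
        }

    if config.rnase_circular and config.rnase_linear:
        from ._io import read_table

        circ = read_table(config.rnase_circular)
        lin = read_table(config.rnase_linear)
        result.rnase = expression.rnase_r_enrichment(
            circ, lin, {"treated": 1e7, "control": 1e7},
            min_reads=th.detection_min_reads,
        )
        manifest["stages"]["rnase"] = {
            "frac_circular_enriched": result.rnase.frac_circular_enriched,
            "frac_linear_enriched": result.rnase.frac_linear_enriched,
            "odds_ratio": result.rnase.odds_ratio,
            "p": result.rnase.p,
        }

    # ----- stage: cohort ------------------------------------------------------
    risk_meta = meta[meta["risk_class"].notna() & (meta["risk_class"] != "")]
    if len(risk_meta["risk_class"].unique()) >= 2:
        result.de = cohort.differential_expression(
            rpm, counts, risk_meta,
            min_reads=th.de_min_reads, min_samples=th.de_min_samples,
            q_threshold=th.q_threshold,
        )
        write_table(result.de, outdir / "differential_expression.tsv", "de")
        manifest["stages"]["cohort_de"] = {
            "n_tested": int(result.de.groupby(["group_a", "group_b"]).size().max())
            if len(result.de) else 0,
            "n_significant": int(result.de["significant"].sum()),
        }
    surv_meta = meta[meta["surv_time"].notna()]
    if len(surv_meta) >= 4:
        total = rpm[[s for s in rpm.columns if s in surv_meta.index]].sum(axis=0)
        try:
            result.survival = cohort.km_logrank(
                total, surv_meta, cutoff=th.survival_cutoff
            )
            result.survival.write_tsv(outdir / "survival_total_expression.tsv")
            manifest["stages"]["survival"] = {
                "cutoff_rpm": result.survival.cutoff,
                "chi2": result.survival.chi2,
                "p": result.survival.p,
            }
        except ValueError as exc:
            log.warning("survival stage skipped: %s", exc)
    tissue_meta = meta[(meta["tissue"].notna()) & (meta["tissue"] != "")]
    tissue_meta = tissue_meta[
        (tissue_meta["fraction"].isna())
        | (tissue_meta["fraction"] == "")
        | (tissue_meta["fraction"] == "whole")
    ]
    if len(tissue_meta):
        cols = [s for s in rpm.columns if s in tissue_meta.index]
        if cols:
            classes = pd.Series({c.cluster_id: c.cls for c in clusters})
            result.tissue = cohort.tissue_summary(
                rpm, counts, tissue_meta, classes, min_reads=th.detection_min_reads
            )
            write_table(result.tissue.per_tissue, outdir / "tissue_summary.tsv", "tissue")
    frac_meta = meta[meta["fraction"].isin(["nuclear", "cytoplasmic"])]
    if len(frac_meta):
        lengths = pd.Series({c.cluster_id: c.circle_length for c in clusters})
        result.fraction = cohort.fraction_summary(rpm, frac_meta, lengths)
        write_table(
            result.fraction.per_fraction, outdir / "fraction_summary.tsv", "fraction"
        )

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    result.manifest = manifest
    return result
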