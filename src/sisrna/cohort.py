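"""Cohort-level statistics: tissue specificity, cell-fraction localization,
risk-class differential expression, and progression-free survival.

Differential expression between prognostic risk classes uses the two-sided
Wilcoxon rank-sum test on per-sample RPM values with Benjamini-Hochberg FDR
control per class-pair family (q < 0.1 significant) and the pseudocounted
log2 fold change of class means.  Survival analysis dichotomizes patients at
the median expression (strictly greater = high group, so a zero median
splits zero versus nonzero) and compares Kaplan-Meier curves with a two-group
log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._io import read_table, write_table
from .expression import logfc

log = logging.getLogger(__name__)

METADATA_COLUMNS = [
    "sample_id",
    "library_size",
    "tissue",
    "fraction",
    "risk_class",
    "surv_time",
    "surv_event",
]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata table; survival fields must be jointly present."""
    df = read_table(path)
    if "sample_id" not in df.columns or "library_size" not in df.columns:
        raise ValueError("metadata requires sample_id and library_size columns")
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["risk_class"] = df["risk_class"].astype("string")
    bad = df["surv_time"].isna() != df["surv_event"].isna()
    if bad.any():
        raise ValueError(
            f"survival fields must be jointly present or missing: "
            f"{df.loc[bad, 'sample_id'].tolist()[:5]}"
        )
    return df.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# elementary tests


def wilcoxon_rank_sum(x, y, two_sided: bool = True, method: str | None = None) -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when n_x + n_y <= 12 without ties; otherwise the
    normal approximation with tie and continuity correction (``method``
    overrides the automatic choice).  Groups whose pooled values are
    constant are maximally indistinct (p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if method is None:
        method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x,
        y,
        alternative="two-sided" if two_sided else "greater",
        method=method,
        use_continuity=True,
    )
    return float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# differential expression


@dataclass
class DEResult:
    cluster_id: str
    group_a: str
    group_b: str
    p: float
    q: float
    logfc: float
    significant: bool


def differential_expression(
    rpm: pd.DataFrame,
    raw_counts: pd.DataFrame,
    metadata: pd.DataFrame,
    group_col: str = "risk_class",
    min_reads: int = 10,
    min_samples: int = 10,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Pairwise risk-class differential expression of junction RPM.

    Features enter testing when their total raw junction reads are strictly
    above ``min_reads`` AND they are detected (nonzero) in at least
    ``min_samples`` samples.  Per class pair, a two-sided Wilcoxon rank-sum
    test is applied to per-sample RPM and BH correction is performed within
    that pair's family.
    """
    meta = metadata.dropna(subset=[group_col])
    samples = [s for s in rpm.columns if s in meta.index]
    groups = sorted(meta.loc[samples, group_col].astype(str).unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups for differential expression")

    total = raw_counts[samples].sum(axis=1)
    detected = (raw_counts[samples] > 0).sum(axis=1)
    tested = rpm.index[(total > min_reads) & (detected >= min_samples)]

    rows: list[DEResult] = []
    for ga, gb in combinations(groups, 2):
        sa = [s for s in samples if str(meta.at[s, group_col]) == ga]
        sb = [s for s in samples if str(meta.at[s, group_col]) == gb]
        if len(sa) < 2 or len(sb) < 2:
            continue
        ps = []
        fcs = []
        for fid in tested:
            xa = rpm.loc[fid, sa].to_numpy(dtype=float)
            xb = rpm.loc[fid, sb].to_numpy(dtype=float)
            ps.append(wilcoxon_rank_sum(xa, xb))
            fcs.append(logfc(float(xa.mean()), float(xb.mean())))
        qs = bh_adjust(ps) if ps else np.array([])
        for fid, p, q, fc in zip(tested, ps, qs, fcs):
            rows.append(DEResult(fid, ga, gb, p, float(q), fc, bool(q < q_threshold)))
    return pd.DataFrame(
        [r.__dict__ for r in rows],
        columns=["cluster_id", "group_a", "group_b", "p", "q", "logfc", "significant"],
    )


# ---------------------------------------------------------------------------
# survival


@dataclass
class KMResult:
    curves: pd.DataFrame  # group, time, at_risk, survival
    chi2: float
    p: float
    cutoff: float
    n_high: int
    n_low: int

    def write_tsv(self, path: str | Path) -> None:
        write_table(self.curves, path, "survival")


def km_logrank(
    values: pd.Series,
    metadata: pd.DataFrame,
    cutoff: str | float = "median",
) -> KMResult:
    """Kaplan-Meier curves and log-rank test for expression-dichotomized groups.

    Samples with expression strictly greater than the cutoff (the median by
    default) form the high group; ties go low, so a median of 0 splits
    zero-expression from positive samples.  Events are progressions;
    censored samples contribute risk-set time only.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    meta = metadata.dropna(subset=["surv_time", "surv_event"])
    shared = [s for s in values.index if s in meta.index]
    if not shared:
        raise ValueError("no samples with both expression and survival data")
    v = values.loc[shared].astype(float)
    cut = float(np.median(v)) if cutoff == "median" else float(cutoff)
    high = v.index[v > cut]
    low = v.index[v <= cut]
    if len(high) == 0 or len(low) == 0:
        raise ValueError(
            f"cutoff {cut} leaves an empty group; choose a different cutoff"
        )
    t_h = meta.loc[high, "surv_time"].to_numpy(dtype=float)
    e_h = meta.loc[high, "surv_event"].to_numpy(dtype=int)
    t_l = meta.loc[low, "surv_time"].to_numpy(dtype=float)
    e_l = meta.loc[low, "surv_event"].to_numpy(dtype=int)

    res = logrank_test(t_h, t_l, event_observed_A=e_h, event_observed_B=e_l)

    frames = []
    for label, t, e in (("high", t_h, e_h), ("low", t_l, e_l)):
        kmf = KaplanMeierFitter()
        kmf.fit(t, event_observed=e, label=label)
        sf = kmf.survival_function_[label]
        at_risk = kmf.event_table["at_risk"].reindex(sf.index)
        frames.append(
            pd.DataFrame(
                {
                    "group": label,
                    "time": sf.index.to_numpy(),
                    "at_risk": at_risk.to_numpy(),
                    "survival": sf.to_numpy(),
                }
            )
        )
    curves = pd.concat(frames, ignore_index=True)
    return KMResult(
        curves=curves,
        chi2=float(res.test_statistic),
        p=float(res.p_value),
        cutoff=cut,
        n_high=int(len(high)),
        n_low=int(len(low)),
    )


# ---------------------------------------------------------------------------
# tissue and fraction summaries


@dataclass
class TissueSummary:
    per_tissue: pd.DataFrame  # tissue, n_samples, n_detected, total_rpm,
    #                           top_decile_contribution, circle_fraction
    tissues_per_feature: pd.Series  # feature -> number of tissues detected in


def tissue_summary(
    rpm: pd.DataFrame,
    raw_counts: pd.DataFrame,
    metadata: pd.DataFrame,
    classes: Mapping[str, str] | pd.Series | None = None,
    min_reads: int = 2,
) -> TissueSummary:
    """Per-tissue expression totals, detection counts, and concentration.

    Tissue expression of a feature is the mean RPM over that tissue's
    samples; a feature is detected in a tissue when its summed raw junction
    reads there reach ``min_reads``.  The top-decile contribution is the
    share of the tissue total carried by the ceil(0.1 * n) highest-expressed
    detected features; the circle fraction is the intronic-circle share of
    detected features.
    """
    meta = metadata.dropna(subset=["tissue"])
    rows = []
    det_matrix = {}
    for tissue, sub in meta.groupby("tissue"):
        samples = [s for s in sub["sample_id"] if s in rpm.columns]
        if not samples:
            continue
        mean_rpm = rpm[samples].mean(axis=1)
        detected = raw_counts[samples].sum(axis=1) >= min_reads
        det_matrix[tissue] = detected
        expr = mean_rpm[detected]
        total = float(expr.sum())
        n_det = int(detected.sum())
        if n_det:
            k = int(np.ceil(0.1 * n_det))
            top = float(expr.sort_values(ascending=False).head(k).sum())
            top_contrib = top / total if total > 0 else float("nan")
        else:
            top_contrib = float("nan")
        if classes is not None and n_det:
            cls = pd.Series(classes)
            det_ids = expr.index
            circ_frac = float(
                (cls.reindex(det_ids) == "intronic_circle").sum() / n_det
            )
        else:
            circ_frac = float("nan")
        rows.append(
            {
                "tissue": tissue,
                "n_samples": len(samples),
                "n_detected": n_det,
                "total_rpm": total,
                "top_decile_contribution": top_contrib,
                "circle_fraction": circ_frac,
            }
        )
    per_tissue = pd.DataFrame(rows)
    if det_matrix:
        det_df = pd.DataFrame(det_matrix)
        tissues_per_feature = det_df.sum(axis=1).astype(int)
    else:
        tissues_per_feature = pd.Series(dtype=int)
    return TissueSummary(per_tissue=per_tissue, tissues_per_feature=tissues_per_feature)


@dataclass
class FractionSummary:
    per_fraction: pd.DataFrame  # cell_line, fraction, n_detected, total_rpm,
    #                             median_length, iqr_length
    overlap: pd.DataFrame  # cell_line, n_nuclear, n_cytoplasmic, n_overlap


def fraction_summary(
    rpm: pd.DataFrame,
    metadata: pd.DataFrame,
    lengths: Mapping[str, float] | pd.Series,
    cell_line_col: str = "tissue",
) -> FractionSummary:
    """Per cell line x fraction totals, detected sets, nuclear/cytoplasmic
    overlap, and detected-feature length quartiles (linear interpolation)."""
    meta = metadata.dropna(subset=["fraction"])
    lengths = pd.Series(lengths)
    rows = []
    detected_sets: dict[tuple[str, str], set[str]] = {}
    for (line, fraction), sub in meta.groupby([cell_line_col, "fraction"]):
        samples = [s for s in sub["sample_id"] if s in rpm.columns]
        if not samples:
            continue
        totals = rpm[samples].sum(axis=1)
        detected = totals[totals > 0]
        detected_sets[(line, fraction)] = set(detected.index)
        ls = lengths.reindex(detected.index).dropna()
        rows.append(
            {
                "cell_line": line,
                "fraction": fraction,
                "n_detected": int(len(detected)),
                "total_rpm": float(totals.sum()),
                "median_length": float(np.median(ls)) if len(ls) else float("nan"),
                "iqr_length": (
                    float(np.percentile(ls, 75) - np.percentile(ls, 25))
                    if len(ls)
                    else float("nan")
                ),
            }
        )
    overlap_rows = []
    lines = sorted({line for line, _ in detected_sets})
    for line in lines:
        nuc = detected_sets.get((line, "nuclear"), set())
        cyt = detected_sets.get((line, "cytoplasmic"), set())
        overlap_rows.append(
            {
                "cell_line": line,
                "n_nuclear": len(nuc),
                "n_cytoplasmic": len(cyt),
                "n_overlap": len(nuc & cyt),
            }
        )
    return FractionSummary(
        per_fraction=pd.DataFrame(rows), overlap=pd.DataFrame(overlap_rows)
    )
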