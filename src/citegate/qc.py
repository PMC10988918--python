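"""Multi-omic per-cell QC metrics and group comparison.

Metrics are computed from RAW counts (detection = raw count > 0), so they are
invariant to whatever normalization was applied for gating:

* ``total_rna_counts``, ``n_genes_detected`` (RNA assay present),
* ``total_adt_counts``, ``n_antibodies_detected`` (ADT assay present).

Metrics for absent assays are omitted, not zero-filled. Group comparison is a
one-way fixed-effects ANOVA followed by all-pairs Tukey HSD: the honest
significant difference uses the studentized-range distribution with the
pooled within-group degrees of freedom (Tukey–Kramer standard error for
unequal group sizes), yielding family-wise adjusted p-values.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .container import OmicsContainer
from .errors import ValidationError

__all__ = ["compute_qc", "GroupComparison", "group_compare", "coexpression_table"]

log = logging.getLogger(__name__)


def compute_qc(container: OmicsContainer) -> pd.DataFrame:
    """Per-cell QC table (barcode-indexed), joined with cell metadata."""
    cols: dict[str, np.ndarray] = {}
    if "RNA" in container.assays:
        raw = container.assays["RNA"].raw
        cols["total_rna_counts"] = np.asarray(raw.sum(axis=1)).ravel()
        cols["n_genes_detected"] = np.asarray((raw > 0).sum(axis=1)).ravel()
    else:
        log.info("no RNA assay: RNA QC metrics omitted")
    if "ADT" in container.assays:
        raw = container.assays["ADT"].raw
        cols["total_adt_counts"] = np.asarray(raw.sum(axis=1)).ravel()
        cols["n_antibodies_detected"] = np.asarray((raw > 0).sum(axis=1)).ravel()
    else:
        log.info("no ADT assay: ADT QC metrics omitted")
    qc = pd.DataFrame(cols, index=container.barcodes)
    meta = container.cell_meta
    overlap = [c for c in meta.columns if c not in qc.columns]
    return qc.join(meta[overlap].set_axis(qc.index))


@dataclass
class GroupComparison:
    metric: str
    group_var: str
    groups: pd.DataFrame  # per group: n, mean, sd
    anova_f: float
    anova_p: float
    pairs: pd.DataFrame  # group_i, group_j, mean_diff, padj, significant
    alpha: float


def _tukey_pairs(
    names: list[str],
    means: np.ndarray,
    ns: np.ndarray,
    msw: float,
    df_within: int,
    alpha: float,
) -> pd.DataFrame:
    k = len(names)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[j] - means[i]
        if msw > 0:
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se
            padj = float(stats.studentized_range.sf(q, k, df_within))
            padj = min(max(padj, 0.0), 1.0)
        else:
            # degenerate: no within-group variance at all
            padj = 1.0 if diff == 0 else 0.0
        rows.append(
            {
                "group_i": names[i],
                "group_j": names[j],
                "mean_diff": float(diff),
                "padj": padj,
                "significant": padj < alpha,
            }
        )
    return pd.DataFrame(rows)


def group_compare(
    qc: pd.DataFrame, metric: str, group_var: str, alpha: float = 0.05
) -> GroupComparison:
    """One-way ANOVA + Tukey HSD of a QC metric across metadata groups.

    Groups with fewer than 2 cells are dropped with a warning; fewer than two
    usable groups is an error. With zero between-group variance the ANOVA is
    reported as F = 0, p = 1 (scipy returns NaN there).
    """
    if metric not in qc.columns:
        raise ValidationError(f"metric {metric!r} not in QC table")
    if group_var not in qc.columns:
        raise ValidationError(f"group variable {group_var!r} not in QC table")
    values = pd.to_numeric(qc[metric], errors="raise").to_numpy(dtype=float)
    labels = qc[group_var].astype(str).to_numpy()

    by_group: dict[str, np.ndarray] = {}
    for name in pd.unique(labels):
        v = values[labels == name]
        if len(v) < 2:
            warnings.warn(
                f"group {name!r} has {len(v)} cell(s); dropped from comparison",
                UserWarning,
                stacklevel=2,
            )
            continue
        by_group[str(name)] = v
    if len(by_group) < 2:
        raise ValidationError(
            f"need >= 2 groups with >= 2 cells; have {len(by_group)}"
        )

    names = sorted(by_group)
    ns = np.array([len(by_group[g]) for g in names])
    means = np.array([by_group[g].mean() for g in names])
    sds = np.array([by_group[g].std(ddof=1) for g in names])
    n_total = int(ns.sum())
    k = len(names)
    grand_mean = np.concatenate([by_group[g] for g in names]).mean()

    ss_between = float(np.sum(ns * (means - grand_mean) ** 2))
    ss_within = float(sum(((by_group[g] - by_group[g].mean()) ** 2).sum() for g in names))
    df_between, df_within = k - 1, n_total - k
    msb = ss_between / df_between
    msw = ss_within / df_within

    if msb == 0.0:
        f_stat, p_val = 0.0, 1.0
    elif msw == 0.0:
        f_stat, p_val = float("inf"), 0.0
    else:
        f_stat = msb / msw
        p_val = float(stats.f.sf(f_stat, df_between, df_within))

    pairs = _tukey_pairs(names, means, ns, msw, df_within, alpha)
    groups = pd.DataFrame({"group": names, "n": ns, "mean": means, "sd": sds})
    return GroupComparison(
        metric=metric,
        group_var=group_var,
        groups=groups,
        anova_f=f_stat,
        anova_p=p_val,
        pairs=pairs,
        alpha=alpha,
    )


def coexpression_table(
    container: OmicsContainer,
    assay_a: str,
    feature_a: str,
    assay_b: str,
    feature_b: str,
    thresholds: tuple[float, float] | None = None,
    value_source: str = "auto",
) -> pd.DataFrame:
    """Quadrant classification of every cell on a (possibly cross-assay) pair.

    A cell is positive for a feature when its value exceeds the feature's
    threshold; thresholds default to the per-feature upper quartile of the
    values in use. Quadrants: double_negative, a_only, b_only,
    double_positive.
    """
    va = container.feature_values(assay_a, feature_a, source=value_source)
    vb = container.feature_values(assay_b, feature_b, source=value_source)
    if thresholds is None:
        thresholds = (float(np.quantile(va, 0.75)), float(np.quantile(vb, 0.75)))
    ta, tb = thresholds
    pos_a, pos_b = va > ta, vb > tb
    quadrant = np.where(
        pos_a & pos_b,
        "double_positive",
        np.where(pos_a, "a_only", np.where(pos_b, "b_only", "double_negative")),
    )
    return pd.DataFrame(
        {
            f"{assay_a}:{feature_a}": va,
            f"{assay_b}:{feature_b}": vb,
            "positive_a": pos_a,
            "positive_b": pos_b,
            "quadrant": quadrant,
        },
        index=container.barcodes,
    )
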