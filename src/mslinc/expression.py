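"""FPKM matrix handling: low-expression filter, differential expression,
expression-class assignment and qPCR relative quantification.

Expression matrices are pandas DataFrames with transcripts as rows and
samples as columns (FPKM units); sample metadata is a DataFrame indexed by
sample id with a ``group`` column drawn from the closed vocabulary below.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TUMOR_GROUPS",
    "LUMINAL_GROUPS",
    "CONTROL_GROUPS",
    "low_expression_filter",
    "differential_expression",
    "assign_expression_class",
    "relative_expression_ddct",
    "descriptive_stats",
]

TUMOR_GROUPS = ("lumA", "lumB_her2neg", "lumB_her2pos", "her2", "tn")
LUMINAL_GROUPS = ("lumA", "lumB_her2neg", "lumB_her2pos")
ADJACENT_GROUPS = tuple(f"adjacent_{g}" for g in TUMOR_GROUPS)
CONTROL_GROUPS = ADJACENT_GROUPS + ("normal",)


def low_expression_filter(
    matrix: pd.DataFrame, fpkm_min: float = 0.01, frac: float = 0.75
) -> pd.DataFrame:
    """Drop transcripts with FPKM < ``fpkm_min`` in strictly more than
    ``frac`` of samples; the sample set is unchanged."""
    low_frac = (matrix < fpkm_min).mean(axis=1)
    return matrix.loc[low_frac <= frac]


def differential_expression(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    fc_min: float = 1.0,
) -> pd.DataFrame:
    """Welch two-sample test per transcript on log2(FPKM+1), BH-adjusted.

    ``log2fc`` is mean(B) - mean(A) on the transformed scale.  A transcript
    is ``significant`` when q < ``alpha`` and \\|log2fc\\| >= ``fc_min``.
    Degenerate zero-variance transcripts get p = 1 when the group means are
    equal and p = 0 when they differ (perfect separation).
    """
    samples_a = meta.index[meta["group"] == group_a]
    samples_b = meta.index[meta["group"] == group_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"groups need >= 2 samples each (got {len(samples_a)} for "
            f"{group_a!r}, {len(samples_b)} for {group_b!r})"
        )
    log_a = np.log2(matrix[samples_a].to_numpy() + 1.0)
    log_b = np.log2(matrix[samples_b].to_numpy() + 1.0)
    lfc = log_b.mean(axis=1) - log_a.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    p[degenerate & (np.abs(lfc) <= 1e-12)] = 1.0
    p[degenerate & (np.abs(lfc) > 1e-12)] = 0.0
    q = stats.false_discovery_control(p, method="bh")
    out = pd.DataFrame(
        {
            "transcript": matrix.index,
            "comparison": f"{group_b}_vs_{group_a}",
            "log2fc": lfc,
            "p": p,
            "q": q,
        }
    ).set_index("transcript")
    out["significant"] = (out["q"] < alpha) & (out["log2fc"].abs() >= fc_min)
    return out


def assign_expression_class(de_tables: Mapping[tuple[str, str], pd.DataFrame]) -> pd.Series:
    """Assign expression classes I/II/III from tumor-vs-control DE tables.

    ``de_tables`` maps ``(subtype, control)`` to the DE table of that
    comparison (log2fc oriented tumor-minus-control).  Class II transcripts
    are significantly up in every tumor subtype against both controls;
    Class I significantly down everywhere; Class III significantly up in all
    luminal comparisons and in none of the non-luminal ones.  Anything else
    is ``unclassified``; the labels partition the transcripts.
    """
    keys = list(de_tables)
    subtypes = {s for s, _ in keys}
    missing = set(TUMOR_GROUPS) - subtypes
    if missing:
        raise ValueError(f"missing comparisons for subtypes: {sorted(missing)}")
    idx = de_tables[keys[0]].index
    up = pd.DataFrame(
        {k: (t["significant"] & (t["log2fc"] > 0)).reindex(idx, fill_value=False)
         for k, t in de_tables.items()}
    )
    down = pd.DataFrame(
        {k: (t["significant"] & (t["log2fc"] < 0)).reindex(idx, fill_value=False)
         for k, t in de_tables.items()}
    )
    luminal_cols = [k for k in keys if k[0] in LUMINAL_GROUPS]
    nonluminal_cols = [k for k in keys if k[0] not in LUMINAL_GROUPS]
    class_ii = up.all(axis=1)
    class_i = down.all(axis=1)
    class_iii = up[luminal_cols].all(axis=1) & ~up[nonluminal_cols].any(axis=1)
    labels = pd.Series("unclassified", index=idx, name="expression_class")
    labels[class_iii] = "III"
    labels[class_i] = "I"
    labels[class_ii] = "II"
    return labels


def relative_expression_ddct(ct_target: float, ct_ref: float) -> float:
    """qPCR relative level by the 2^-dCT method: 2^-(Ct_target - Ct_ref)."""
    return float(2.0 ** -(ct_target - ct_ref))


def descriptive_stats(
    catalog,
    matrix: pd.DataFrame,
    classes: Mapping[str, str],
) -> pd.DataFrame:
    """Per-class descriptive summaries (Fig. 1-style).

    ``classes`` maps transcript id to a class label (e.g. SElincRNA,
    MElincRNA, coding, known_noncoding).  Reports per class: transcript
    count, mean exon count, median exon length, median mature length,
    median genomic span length and median FPKM.  Empty classes yield no row.
    """
    records: dict[str, dict[str, list]] = {}
    for t in catalog:
        cls = classes.get(t.id)
        if cls is None:
            continue
        rec = records.setdefault(
            cls,
            {"n_exons": [], "exon_lens": [], "mature": [], "span": [], "expr": []},
        )
        rec["n_exons"].append(t.n_exons)
        rec["exon_lens"].extend(b - a for a, b in t.exons)
        rec["mature"].append(t.mature_length)
        rec["span"].append(t.span_length)
        if t.id in matrix.index:
            rec["expr"].append(float(np.median(matrix.loc[t.id])))
    rows = []
    for cls in sorted(records):
        rec = records[cls]
        rows.append(
            {
                "class": cls,
                "n_transcripts": len(rec["mature"]),
                "mean_exon_count": float(np.mean(rec["n_exons"])),
                "median_exon_length": float(np.median(rec["exon_lens"])),
                "median_mature_length": float(np.median(rec["mature"])),
                "median_span_length": float(np.median(rec["span"])),
                "median_fpkm": float(np.median(rec["expr"])) if rec["expr"] else np.nan,
            }
        )
    columns = [
        "class", "n_transcripts", "mean_exon_count", "median_exon_length",
        "median_mature_length", "median_span_length", "median_fpkm",
    ]
    return pd.DataFrame(rows, columns=columns).set_index("class")
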