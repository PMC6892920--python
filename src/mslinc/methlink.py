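"""Promoter CpG methylation <-> expression linkage.

CpG sites within a 500-2000 bp band around a transcript's TSS are tested for
Pearson correlation between their beta values and the transcript's FPKM;
pairs with p < 0.01 are reported with their direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TranscriptModel

__all__ = [
    "promoter_cpg_sites",
    "methylation_expression_correlation",
    "significant_meth_regulators",
]


def _tss_distance(t: TranscriptModel, position: int) -> int:
    """Signed distance from the strand-aware TSS; positive = upstream."""
    if t.strand == "-":
        return position - t.tss
    return t.tss - position


def promoter_cpg_sites(
    transcript: TranscriptModel,
    sites: pd.DataFrame,
    window: tuple[int, int] = (500, 2000),
    upstream_only: bool = False,
) -> pd.DataFrame:
    """CpG sites whose distance to the TSS lies in ``window`` (inclusive).

    ``sites`` needs columns ``chrom`` and ``position`` (0-based) indexed by
    CpG id.  By default both sides of the TSS qualify; ``upstream_only``
    restricts to the strand-aware upstream side.
    """
    lo, hi = window
    on_chrom = sites[sites["chrom"] == transcript.chrom]
    signed = np.array([_tss_distance(transcript, p) for p in on_chrom["position"]])
    dist = signed if upstream_only else np.abs(signed)
    return on_chrom[(dist >= lo) & (dist <= hi)]


def methylation_expression_correlation(
    betas: np.ndarray, fpkms: np.ndarray
) -> tuple[float, float]:
    """Pearson r and two-sided p between beta values and FPKM.

    p comes from the t transform t = r*sqrt((n-2)/(1-r^2)) on n-2 df.
    Raises on fewer than 3 paired samples or a constant vector.
    """
    betas = np.asarray(betas, dtype=float)
    fpkms = np.asarray(fpkms, dtype=float)
    if betas.shape != fpkms.shape or betas.ndim != 1:
        raise ValueError("betas and fpkms must be 1-D arrays of equal length")
    if betas.size < 3:
        raise ValueError("correlation needs >= 3 paired samples")
    if np.ptp(betas) == 0 or np.ptp(fpkms) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(betas, fpkms)
    return float(r), float(p)


def significant_meth_regulators(
    transcripts,
    sites: pd.DataFrame,
    beta_matrix: pd.DataFrame,
    expr_matrix: pd.DataFrame,
    p_max: float = 0.01,
    window: tuple[int, int] = (500, 2000),
    upstream_only: bool = False,
) -> pd.DataFrame:
    """All promoter-window (CpG, transcript) pairs with p < ``p_max``.

    Only pairs measured in every shared sample are tested; the direction of
    each reported correlation (negative/positive) is recorded.
    """
    samples = beta_matrix.columns.intersection(expr_matrix.columns)
    rows = []
    for t in transcripts:
        if t.id not in expr_matrix.index:
            continue
        fpkm = expr_matrix.loc[t.id, samples].to_numpy(dtype=float)
        if np.ptp(fpkm) == 0:
            continue
        for cpg_id in promoter_cpg_sites(t, sites, window, upstream_only).index:
            if cpg_id not in beta_matrix.index:
                continue
            beta = beta_matrix.loc[cpg_id, samples].to_numpy(dtype=float)
            if np.ptp(beta) == 0:
                continue
            r, p = methylation_expression_correlation(beta, fpkm)
            if p < p_max:
                rows.append(
                    {
                        "cpg": cpg_id,
                        "transcript": t.id,
                        "r": r,
                        "p": p,
                        "direction": "negative" if r < 0 else "positive",
                    }
                )
    return pd.DataFrame(rows, columns=["cpg", "transcript", "r", "p", "direction"])
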