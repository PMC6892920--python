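"""Coding-potential scoring with a two-scorer "noncoding" consensus.

Two independent scorers mimic the decision semantics of running two
coding-potential predictors and intersecting their noncoding calls:

* scorer A: Fickett TESTCODE statistic + ORF features, combined by a
  logistic model;
* scorer B: in-frame hexamer usage log-likelihood ratio + ORF features,
  combined by a second logistic model.

A transcript counts as noncoding only when *both* scorers place its coding
probability below the threshold ``tau`` (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

__all__ = [
    "CodingPotentialResult",
    "HexamerTable",
    "ConsensusScorer",
    "fickett_score",
    "longest_orf",
    "hexamer_score",
    "train_scorers",
    "consensus_noncoding",
]

STOP_CODONS = ("TAA", "TAG", "TGA")

# Fickett (1982) TESTCODE lookup tables: probability of coding for ten bins
# of the position-asymmetry ratio and of the base-content fraction, with the
# published per-base weights.  Bin thresholds are descending; a value >= the
# i-th threshold falls in bin i.
_POSITION_PROB = {
    "A": [0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36],
    "C": [0.29, 0.44, 0.55, 0.49, 0.52, 0.60, 0.60, 0.56, 0.51, 0.38],
    "G": [0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.66, 0.66, 0.68, 0.48],
    "T": [0.51, 0.60, 0.69, 0.64, 0.62, 0.67, 0.58, 0.48, 0.39, 0.24],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_CONTENT_PROB = {
    "A": [0.40, 0.55, 0.58, 0.58, 0.52, 0.48, 0.45, 0.45, 0.38, 0.19],
    "C": [0.50, 0.63, 0.59, 0.50, 0.41, 0.31, 0.24, 0.30, 0.33, 0.23],
    "G": [0.21, 0.40, 0.47, 0.50, 0.52, 0.60, 0.57, 0.52, 0.41, 0.31],
    "T": [0.30, 0.49, 0.56, 0.75, 0.55, 0.40, 0.39, 0.24, 0.18, 0.20],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.17, 0.0, 0.0]


def _lookup(value: float, thresholds: Sequence[float], probs: Sequence[float]) -> float:
    for thr, p in zip(thresholds, probs):
        if value >= thr:
            return p
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic of a nucleotide sequence.

    Position values are max/(min+1) ratios of per-frame base counts;
    content values are base fractions; each is mapped through the published
    lookup tables and weighted.  ``N`` bases are ignored in the counts.
    """
    seq = seq.upper()
    if len(seq) < 6:
        raise ValueError("fickett_score requires a sequence of >= 6 nt")
    frame_counts = {b: [0, 0, 0] for b in "ACGT"}
    totals = {b: 0 for b in "ACGT"}
    for i, base in enumerate(seq):
        if base in frame_counts:
            frame_counts[base][i % 3] += 1
            totals[base] += 1
    n_counted = sum(totals.values())
    score = 0.0
    for base in "ACGT":
        counts = frame_counts[base]
        ratio = max(counts) / (min(counts) + 1)
        score += _lookup(ratio, _POSITION_PARA, _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        frac = totals[base] / n_counted if n_counted else 0.0
        score += _lookup(frac, _CONTENT_PARA, _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


def longest_orf(seq: str) -> tuple[int, float, int, int]:
    """Longest ATG->stop open reading frame on the sense strand.

    Returns ``(orf_len, orf_cov, frame, start)`` where ``orf_len`` counts
    nucleotides including the stop codon and ``orf_cov = orf_len/len(seq)``.
    ``(0, 0.0, -1, -1)`` when no complete ORF exists.
    """
    seq = seq.upper()
    n = len(seq)
    best = (0, -1, -1)  # (length, frame, start)
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS:
                length = pos + 3 - start
                if length > best[0]:
                    best = (length, frame, start)
                start = None
    if best[0] == 0:
        return 0, 0.0, -1, -1
    return best[0], best[0] / n, best[1], best[2]


@dataclass
class HexamerTable:
    """Hexamer frequency table for one sequence class."""

    freq: dict[str, float]
    pseudocount: float = 1.0

    @classmethod
    def from_sequences(cls, seqs: Iterable[str], pseudocount: float = 1.0) -> "HexamerTable":
        """Estimate from all overlapping hexamers (step 1) of the sequences."""
        counts: dict[str, float] = {}
        for seq in seqs:
            seq = seq.upper()
            for i in range(len(seq) - 5):
                h = seq[i : i + 6]
                if "N" in h:
                    continue
                counts[h] = counts.get(h, 0.0) + 1.0
        from itertools import product

        table = {
            "".join(h): counts.get("".join(h), 0.0) + pseudocount
            for h in product("ACGT", repeat=6)
        }
        total = sum(table.values())
        return cls({h: c / total for h, c in table.items()}, pseudocount)


def hexamer_score(seq: str, coding: HexamerTable, noncoding: HexamerTable) -> float:
    """Mean log-likelihood ratio (nats) of in-frame hexamers.

    Hexamers are read in steps of 3 over the longest ORF; when the sequence
    has no complete ORF, frame 0 of the full sequence is used.  Positive
    values indicate coding-like composition.
    """
    seq = seq.upper()
    if len(seq) < 6:
        raise ValueError("hexamer_score requires a sequence of >= 6 nt")
    orf_len, _, _, start = longest_orf(seq)
    region = seq[start : start + orf_len] if orf_len else seq
    total = 0.0
    n = 0
    for i in range(0, len(region) - 5, 3):
        h = region[i : i + 6]
        if "N" in h:
            continue
        total += np.log(coding.freq[h] / noncoding.freq[h])
        n += 1
    return total / n if n else 0.0


@dataclass
class CodingPotentialResult:
    id: str
    fickett: float
    hexamer: float
    orf_len: int
    orf_cov: float
    p_A: float
    p_B: float
    consensus_noncoding: bool


def consensus_noncoding(result: CodingPotentialResult, tau: float = 0.5) -> bool:
    """True iff both scorers call the transcript noncoding (p < tau, strict)."""
    return result.p_A < tau and result.p_B < tau


def _features_A(fickett: float, orf_len: int, orf_cov: float) -> list[float]:
    return [fickett, orf_cov, np.log1p(orf_len)]


def _features_B(hexamer: float, orf_len: int, orf_cov: float) -> list[float]:
    return [hexamer, orf_cov, np.log1p(orf_len)]


class ConsensusScorer:
    """Trained pair of logistic scorers with conjunction consensus."""

    def __init__(
        self,
        model_a: LogisticRegression,
        model_b: LogisticRegression,
        tables: tuple[HexamerTable, HexamerTable],
        tau: float = 0.5,
    ):
        self.model_a = model_a
        self.model_b = model_b
        self.coding_table, self.noncoding_table = tables
        self.tau = tau

    def score(self, tid: str, seq: str) -> CodingPotentialResult:
        fick = fickett_score(seq)
        orf_len, orf_cov, _, _ = longest_orf(seq)
        hexa = hexamer_score(seq, self.coding_table, self.noncoding_table)
        p_a = float(self.model_a.predict_proba([_features_A(fick, orf_len, orf_cov)])[0, 1])
        p_b = float(self.model_b.predict_proba([_features_B(hexa, orf_len, orf_cov)])[0, 1])
        return CodingPotentialResult(
            id=tid,
            fickett=fick,
            hexamer=hexa,
            orf_len=orf_len,
            orf_cov=orf_cov,
            p_A=p_a,
            p_B=p_b,
            consensus_noncoding=p_a < self.tau and p_b < self.tau,
        )

    def score_many(self, sequences: Mapping[str, str]) -> pd.DataFrame:
        rows = [vars(self.score(tid, seq)) for tid, seq in sequences.items()]
        return pd.DataFrame(rows)


def train_scorers(
    sequences: Sequence[str],
    labels: Sequence[int],
    tau: float = 0.5,
    pseudocount: float = 1.0,
) -> ConsensusScorer:
    """Fit both logistic scorers on labelled sequences (1 = coding).

    Hexamer tables are estimated from the training sequences of each class.
    Fitting is deterministic given the input order (lbfgs, fixed seed).
    """
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training requires both coding and noncoding examples")
    coding_tab = HexamerTable.from_sequences(
        (s for s, y in zip(sequences, labels) if y == 1), pseudocount
    )
    noncoding_tab = HexamerTable.from_sequences(
        (s for s, y in zip(sequences, labels) if y == 0), pseudocount
    )
    feats_a, feats_b = [], []
    for seq in sequences:
        fick = fickett_score(seq)
        orf_len, orf_cov, _, _ = longest_orf(seq)
        hexa = hexamer_score(seq, coding_tab, noncoding_tab)
        feats_a.append(_features_A(fick, orf_len, orf_cov))
        feats_b.append(_features_B(hexa, orf_len, orf_cov))
    kw = dict(solver="lbfgs", max_iter=2000, random_state=0)
    model_a = LogisticRegression(**kw).fit(np.array(feats_a), labels)
    model_b = LogisticRegression(**kw).fit(np.array(feats_b), labels)
    return ConsensusScorer(model_a, model_b, (coding_tab, noncoding_tab), tau)
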