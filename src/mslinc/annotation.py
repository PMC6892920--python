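"""Genomic transcript models, GTF I/O and the novel-lincRNA discovery filters.

A transcript is intergenic-lincRNA material when it (i) lies at least
``min_dist`` (default 2000 bp) away from every known gene, (ii) has a mature
(summed-exon) length of at least ``min_len`` (default 200 nt) and (iii) is
called noncoding by *both* coding-potential scorers.  Accepted transcripts are
partitioned into single-exon (SElincRNA) and multi-exon (MElincRNA) classes.

Internal coordinates are 0-based half-open; GTF I/O converts at the boundary
(GTF is 1-based inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptModel",
    "AnnotationCatalog",
    "GtfParseError",
    "parse_gtf",
    "write_gtf",
    "mature_length",
    "distance_to_nearest_known",
    "filter_novel_lincrnas",
    "nearest_gene_assignment",
]


class GtfParseError(ValueError):
    """Raised when a GTF record cannot be interpreted."""


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript.

    ``exons`` are ``[start, end)`` pairs in 0-based half-open coordinates,
    sorted and non-overlapping.  ``biotype`` is one of ``coding``,
    ``known_noncoding`` or ``candidate``.
    """

    id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "candidate"
    source: str = ""
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id!r} has no exons")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"transcript {self.id!r}: bad strand {self.strand!r}")
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        for a, b in exons:
            if b <= a:
                raise ValueError(f"transcript {self.id!r}: empty exon [{a}, {b})")
        for (_, b0), (a1, _) in zip(exons, exons[1:]):
            if a1 < b0:
                raise ValueError(f"transcript {self.id!r}: overlapping exons")
        self.exons = exons
        if not self.gene_id:
            self.gene_id = self.id

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span [start, end) covered by the transcript."""
        return self.start, self.end

    @property
    def span_length(self) -> int:
        return self.end - self.start

    @property
    def mature_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site (5' end by strand)."""
        return self.start if self.strand != "-" else self.end - 1


def mature_length(t: TranscriptModel) -> int:
    """Summed exon length in nucleotides."""
    return t.mature_length


class AnnotationCatalog:
    """A collection of transcripts with a per-chromosome span index."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self._transcripts: dict[str, TranscriptModel] = {}
        for t in transcripts:
            if t.id in self._transcripts:
                raise ValueError(f"duplicate transcript id {t.id!r}")
            self._transcripts[t.id] = t
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._transcripts.values())

    def __contains__(self, tid: str) -> bool:
        return tid in self._transcripts

    def __getitem__(self, tid: str) -> TranscriptModel:
        return self._transcripts[tid]

    @property
    def ids(self) -> list[str]:
        return list(self._transcripts)

    def _spans(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if self._index is None:
            index: dict[str, list[tuple[int, int]]] = {}
            for t in self:
                index.setdefault(t.chrom, []).append(t.span)
            self._index = {
                c: (
                    np.array([s for s, _ in sp], dtype=np.int64),
                    np.array([e for _, e in sp], dtype=np.int64),
                )
                for c, sp in index.items()
            }
        return self._index.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))


def _parse_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().strip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def parse_gtf(path: str | Path) -> AnnotationCatalog:
    """Read exon features from a GTF file into a catalog.

    Exons are grouped by ``transcript_id``; 1-based inclusive coordinates are
    converted to internal 0-based half-open.  The optional ``biotype``
    attribute is honoured, defaulting to ``candidate``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        try:
            tid = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise GtfParseError(
                f"{path}: exon at {feat.seqid}:{feat.start}-{feat.end} "
                "lacks a transcript_id attribute"
            ) from exc
        if feat.end < feat.start:
            raise GtfParseError(f"{path}: exon of {tid!r} has end < start")
        rec = grouped.setdefault(
            tid,
            {
                "chrom": feat.seqid,
                "strand": feat.strand or ".",
                "exons": [],
                "gene_id": (feat.attributes.get("gene_id") or [tid])[0],
                "biotype": (feat.attributes.get("biotype") or ["candidate"])[0],
                "source": feat.source or "",
            },
        )
        rec["exons"].append((feat.start - 1, feat.end))
    return AnnotationCatalog(
        TranscriptModel(
            id=tid,
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=rec["exons"],
            biotype=rec["biotype"],
            source=rec["source"],
            gene_id=rec["gene_id"],
        )
        for tid, rec in grouped.items()
    )


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GTF 2.2 (transcript + exon lines, 1-based inclusive)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.id}"; '
                f'biotype "{t.biotype}";'
            )
            src = t.source or "mslinc"
            fh.write(
                f"{t.chrom}\t{src}\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for a, b in t.exons:
                fh.write(
                    f"{t.chrom}\t{src}\texon\t{a + 1}\t{b}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def distance_to_nearest_known(t: TranscriptModel, catalog: AnnotationCatalog) -> float:
    """Minimum genomic gap (bp) between ``t`` and any catalog transcript span.

    Strand-agnostic, span-to-span. Returns 0 on any overlap and ``math.inf``
    when the chromosome carries no known transcript.
    """
    starts, ends = catalog._spans(t.chrom)
    if starts.size == 0:
        return math.inf
    s, e = t.span
    gaps = np.maximum(np.maximum(starts - e, s - ends), 0)
    return float(gaps.min())


def nearest_gene_assignment(
    lincrna: TranscriptModel,
    catalog: AnnotationCatalog,
    max_dist: int = 1_000_000,
) -> str | None:
    """Nearest coding gene within ``max_dist`` bp, or None.

    A gene's extent is the hull of its transcripts' spans.  Ties break by
    smaller gene start, then lexicographic gene id.
    """
    genes: dict[str, tuple[int, int]] = {}
    for t in catalog:
        if t.biotype != "coding" or t.chrom != lincrna.chrom:
            continue
        s, e = t.span
        if t.gene_id in genes:
            gs, ge = genes[t.gene_id]
            genes[t.gene_id] = (min(gs, s), max(ge, e))
        else:
            genes[t.gene_id] = (s, e)
    best: tuple[float, int, str] | None = None
    ls, le = lincrna.span
    for gid, (gs, ge) in genes.items():
        gap = max(gs - le, ls - ge, 0)
        if gap > max_dist:
            continue
        key = (gap, gs, gid)
        if best is None or key < best:
            best = key
    return best[2] if best else None


@dataclass
class DiscoveryResult:
    """Outcome of the lincRNA filter cascade."""

    accepted: list[str]
    audit: pd.DataFrame = field(repr=False)

    @property
    def se_lincrnas(self) -> list[str]:
        a = self.audit
        return list(a.loc[(a.verdict == "accepted") & (a.exon_class == "SElincRNA"), "id"])

    @property
    def me_lincrnas(self) -> list[str]:
        a = self.audit
        return list(a.loc[(a.verdict == "accepted") & (a.exon_class == "MElincRNA"), "id"])


def filter_novel_lincrnas(
    candidates: AnnotationCatalog,
    catalog: AnnotationCatalog,
    sequences: Mapping[str, str],
    scorer,
    min_dist: int = 2000,
    min_len: int = 200,
) -> DiscoveryResult:
    """Apply the intergenic / length / coding-potential cascade to candidates.

    ``scorer`` is a trained :class:`mslinc.codepot.ConsensusScorer`.  A
    candidate is accepted iff gap-to-known >= ``min_dist`` AND mature length
    >= ``min_len`` AND the two-scorer consensus calls it noncoding.  The audit
    table records, per candidate, the measured quantities and the first filter
    that rejected it (``distance`` < ``length`` < ``coding`` priority).
    """
    rows = []
    accepted = []
    for t in candidates:
        if t.id not in sequences:
            raise KeyError(f"candidate {t.id!r} has no sequence")
        gap = distance_to_nearest_known(t, catalog)
        mlen = t.mature_length
        res = scorer.score(t.id, sequences[t.id])
        reason = ""
        if gap < min_dist:
            reason = "distance"
        elif mlen < min_len:
            reason = "length"
        elif not res.consensus_noncoding:
            reason = "coding"
        verdict = "accepted" if not reason else "rejected"
        if verdict == "accepted":
            accepted.append(t.id)
        rows.append(
            {
                "id": t.id,
                "gap_bp": gap,
                "mature_len": mlen,
                "p_A": res.p_A,
                "p_B": res.p_B,
                "verdict": verdict,
                "reason": reason,
                "exon_class": "SElincRNA" if t.n_exons == 1 else "MElincRNA",
            }
        )
    audit = pd.DataFrame(
        rows,
        columns=[
            "id", "gap_bp", "mature_len", "p_A", "p_B",
            "verdict", "reason", "exon_class",
        ],
    )
    return DiscoveryResult(accepted=accepted, audit=audit)
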