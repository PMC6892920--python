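"""Synthetic study generator with planted, recorded ground truth.

Emulates the design of a 33-sample breast-cancer transcriptome study:
11 groups (five tumor subtypes, five matched adjacent-tissue groups, one
normal-breast group) of three samples each, a known-gene annotation, an
assembled candidate-transcript catalog containing true novel lincRNAs plus
decoys that violate each discovery filter, subtype-specific lincRNA
expression, promoter-methylation-repressed transcripts, correlated cis
lincRNA-gene pairs, a PPI stand-in network, and cluster-specific survival.

Every generator is a pure function of (design, seed); every planted signal
is recorded in a :class:`GroundTruth` so downstream stages can be scored
against the truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .annotation import AnnotationCatalog, TranscriptModel, write_gtf
from .codepot import STOP_CODONS, longest_orf
from .expression import CONTROL_GROUPS, LUMINAL_GROUPS, TUMOR_GROUPS

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "SizingError",
    "generate_annotation",
    "generate_sequences",
    "generate_training_sequences",
    "generate_expression",
    "generate_methylation",
    "generate_survival",
    "generate_ppi",
    "SimulatedStudy",
    "simulate",
]

_CHROMS = ("chr1", "chr2", "chr3", "chr4")
_INTERGENIC_GAP = 60_000
_CHROM_MARGIN = 10_000
_ORF_CAP = 240  # noncoding sequences never carry an ORF this long


class SizingError(ValueError):
    """Requested features do not fit on the synthetic chromosomes."""


@dataclass
class SimulationDesign:
    """Parameters of the synthetic study; defaults are the study conditions."""

    samples_per_group: int = 3
    n_known_genes: int = 200
    n_known_noncoding: int = 30
    n_novel_lincrna: int = 50
    n_decoy_near: int = 10
    n_decoy_short: int = 5
    n_decoy_coding: int = 20
    ms_lincrna_per_subtype: int = 5
    effect_log2fc: float = 3.0
    cis_pair_fraction: float = 0.3
    cis_latent_r: float = 0.8
    meth_regulated_fraction: float = 0.3
    meth_slope: float = 2.0
    n_class_transcripts: int = 10
    n_silent: int = 10
    n_coding_coexpressed_pairs: int = 10
    n_coexpression_modules: int = 2
    coexpression_module_size: int = 5
    noise_sd_log2: float = 0.5
    hazard_ratio_range: tuple[float, float] = (1.0, 8.0)
    baseline_median_survival: float = 60.0
    censor_horizon: float = 180.0
    n_validation_per_subtype: int = 50
    chrom_length: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.samples_per_group, self.n_known_genes, self.n_known_noncoding,
            self.n_novel_lincrna, self.n_decoy_near, self.n_decoy_short,
            self.n_decoy_coding, self.ms_lincrna_per_subtype,
            self.n_class_transcripts, self.n_silent,
            self.n_coding_coexpressed_pairs,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all design counts must be >= 0")
        if self.n_ms_total + self.n_cis_pairs > self.n_novel_lincrna:
            raise ValueError(
                "MS-lincRNA and cis-pair allocations exceed n_novel_lincrna"
            )
        if not 0 <= self.cis_latent_r < 1:
            raise ValueError("cis_latent_r must be in [0, 1)")

    @property
    def subtypes(self) -> tuple[str, ...]:
        return TUMOR_GROUPS

    @property
    def groups(self) -> list[str]:
        return list(TUMOR_GROUPS) + list(CONTROL_GROUPS)

    @property
    def n_samples(self) -> int:
        return len(self.groups) * self.samples_per_group

    @property
    def n_ms_total(self) -> int:
        return self.ms_lincrna_per_subtype * len(TUMOR_GROUPS)

    @property
    def n_cis_pairs(self) -> int:
        return int(round(self.cis_pair_fraction * self.n_novel_lincrna))

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, *stream]))


@dataclass
class GroundTruth:
    """Record of every planted signal, keyed by emitted identifiers."""

    novel_lincrna_ids: list[str] = field(default_factory=list)
    decoy_near_ids: list[str] = field(default_factory=list)
    decoy_short_ids: list[str] = field(default_factory=list)
    decoy_coding_ids: list[str] = field(default_factory=list)
    ms_lincrna_map: dict[str, list[str]] = field(default_factory=dict)
    cis_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    coding_coexpressed_pairs: list[tuple[str, str, bool]] = field(default_factory=list)
    coexpressed_modules: list[list[str]] = field(default_factory=list)
    planted_class: dict[str, str] = field(default_factory=dict)
    silent_ids: list[str] = field(default_factory=list)
    meth_regulated: list[tuple[str, str, str]] = field(default_factory=list)
    cluster_hazards: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["cis_pairs"] = [tuple(x) for x in raw["cis_pairs"]]
        raw["coding_coexpressed_pairs"] = [
            tuple(x) for x in raw["coding_coexpressed_pairs"]
        ]
        raw["meth_regulated"] = [tuple(x) for x in raw["meth_regulated"]]
        return cls(**raw)


# ---------------------------------------------------------------------------
# annotation


def _known_exons(rng, cursor: int, coding: bool) -> list[tuple[int, int]]:
    n_ex = int(rng.integers(3, 10)) if coding else int(rng.integers(1, 4))
    exons = []
    pos = cursor
    for i in range(n_ex):
        length = int(rng.integers(100, 400))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(500, 3000))
    return exons


def _split_exons(rng, start: int, mature: int, n_ex: int) -> list[tuple[int, int]]:
    if n_ex == 1:
        return [(start, start + mature)]
    cuts = np.sort(rng.choice(np.arange(1, mature), size=n_ex - 1, replace=False))
    lens = np.diff(np.concatenate([[0], cuts, [mature]])).astype(int)
    exons = []
    pos = start
    for i, ln in enumerate(lens):
        exons.append((pos, pos + int(ln)))
        pos += int(ln) + (int(rng.integers(500, 2000)) if i < n_ex - 1 else 0)
    return exons


def generate_annotation(
    design: SimulationDesign,
) -> tuple[AnnotationCatalog, AnnotationCatalog, GroundTruth]:
    """Lay out known genes and novel candidates on synthetic chromosomes.

    True novel lincRNAs sit >= 2000 bp from every known gene with mature
    length >= 200 nt (~96% single-exon); near-decoys sit < 2000 bp from a
    gene; short-decoys are < 200 nt; coding-like decoys pass both geometric
    filters and are left for the coding-potential consensus to reject.
    """
    rng = design.rng(0)
    truth = GroundTruth()

    known: list[TranscriptModel] = []
    # slots: (chrom, gap_start, gap_end, left_gene_id, left_is_coding)
    slots: list[tuple[str, int, int, str, bool]] = []
    cursors = {c: _CHROM_MARGIN for c in _CHROMS}
    specs = [("coding", f"G{i:04d}") for i in range(design.n_known_genes)]
    specs += [("known_noncoding", f"NC{i:03d}") for i in range(design.n_known_noncoding)]
    for i, (biotype, gid) in enumerate(specs):
        chrom = _CHROMS[i % len(_CHROMS)]
        exons = _known_exons(rng, cursors[chrom], biotype == "coding")
        strand = "+" if rng.random() < 0.5 else "-"
        known.append(
            TranscriptModel(gid, chrom, strand, exons, biotype, "syndata", gid)
        )
        end = exons[-1][1]
        slots.append((chrom, end, end + _INTERGENIC_GAP, gid, biotype == "coding"))
        cursors[chrom] = end + _INTERGENIC_GAP
    if design.chrom_length is not None and max(cursors.values()) > design.chrom_length:
        raise SizingError(
            f"features need {max(cursors.values())} bp but chrom_length is "
            f"{design.chrom_length}"
        )

    n_ms = design.n_ms_total
    n_cis = design.n_cis_pairs
    n_cls1 = min(design.n_class_transcripts, design.n_novel_lincrna - n_ms - n_cis)
    roles = (
        ["true"] * design.n_novel_lincrna
        + ["coding_decoy"] * design.n_decoy_coding
        + ["near_decoy"] * design.n_decoy_near
        + ["short_decoy"] * design.n_decoy_short
    )
    # cis lincRNAs and near-decoys need a coding gene next door; reserve the
    # first coding-adjacent slots for them, everything else takes the rest
    coding_slots = [s for s in slots if s[4]]
    n_reserved = n_cis + design.n_decoy_near
    if n_reserved > len(coding_slots) or len(roles) > len(slots):
        raise SizingError("not enough intergenic slots for the requested features")
    reserved = coding_slots[:n_reserved]
    reserved_iter = iter(reserved)
    general_iter = iter(s for s in slots if s not in reserved)
    novel: list[TranscriptModel] = []
    true_idx = 0
    for j, role in enumerate(roles):
        tid = f"TCONS_{j + 1:05d}"
        is_cis_true = role == "true" and n_ms <= true_idx < n_ms + n_cis
        if is_cis_true or role == "near_decoy":
            slot = next(reserved_iter)
        else:
            slot = next(general_iter)
        chrom, gap_start, gap_end, left_gene, _ = slot

        if role == "true":
            single = rng.random() < 0.96
            if single:
                mature = int(np.clip(rng.lognormal(np.log(1673.0), 0.35), 250, 4000))
                n_ex = 1
            else:
                mature = int(np.clip(rng.lognormal(np.log(2500.0), 0.30), 600, 5000))
                n_ex = int(rng.integers(2, 5))
        elif role == "coding_decoy":
            mature = int(rng.integers(600, 1801))
            n_ex = 1
        elif role == "near_decoy":
            mature = int(rng.integers(300, 1501))
            n_ex = 1
        else:  # short_decoy
            mature = int(rng.integers(100, 200))
            n_ex = 1

        if role == "near_decoy":
            start = gap_start + int(rng.integers(200, 1900))
        elif is_cis_true:
            start = gap_start + int(rng.integers(5000, 40_000))
        else:
            start = gap_start + (gap_end - gap_start) // 2 - mature // 2
        exons = _split_exons(rng, start, mature, n_ex)
        if exons[-1][1] > gap_end - 2000 and role != "near_decoy":
            exons = _split_exons(rng, gap_start + 2500, mature, 1)
        strand = "+" if rng.random() < 0.5 else "-"
        novel.append(
            TranscriptModel(tid, chrom, strand, exons, "candidate", "syndata", tid)
        )

        if role == "true":
            truth.novel_lincrna_ids.append(tid)
            if true_idx < n_ms:
                subtype = TUMOR_GROUPS[true_idx // design.ms_lincrna_per_subtype]
                truth.ms_lincrna_map.setdefault(subtype, []).append(tid)
            elif is_cis_true:
                truth.cis_pairs.append((tid, left_gene, design.cis_latent_r))
            elif true_idx < n_ms + n_cis + n_cls1:
                truth.planted_class[tid] = "I"
            true_idx += 1
        elif role == "coding_decoy":
            truth.decoy_coding_ids.append(tid)
        elif role == "near_decoy":
            truth.decoy_near_ids.append(tid)
        else:
            truth.decoy_short_ids.append(tid)

    # planted expression classes on known transcripts
    coding_ids = [t.id for t in known if t.biotype == "coding"]
    nc_ids = [t.id for t in known if t.biotype == "known_noncoding"]
    cis_partner_ids = {g for _, g, _ in truth.cis_pairs}
    free_coding = [g for g in coding_ids if g not in cis_partner_ids]
    n_cls = design.n_class_transcripts
    for gid in free_coding[:n_cls]:
        truth.planted_class[gid] = "II"
    for gid in nc_ids[: min(n_cls, len(nc_ids))]:
        truth.planted_class[gid] = "III"
    # coding-coding coexpressed pairs (for the PPI conjunction rule)
    pool = free_coding[n_cls:]
    for i in range(design.n_coding_coexpressed_pairs):
        if 2 * i + 1 >= len(pool):
            break
        with_ppi = i % 10 < 7  # 70% of planted pairs get a PPI edge
        truth.coding_coexpressed_pairs.append((pool[2 * i], pool[2 * i + 1], with_ppi))
    # fully PPI-connected coexpression modules for the module detector
    mod_pool = pool[2 * design.n_coding_coexpressed_pairs :]
    msize = design.coexpression_module_size
    for i in range(design.n_coexpression_modules):
        members = mod_pool[i * msize : (i + 1) * msize]
        if len(members) == msize:
            truth.coexpressed_modules.append(list(members))
    used_nc = set(nc_ids[: min(n_cls, len(nc_ids))])
    truth.silent_ids = [g for g in nc_ids if g not in used_nc][: design.n_silent]

    return AnnotationCatalog(known), AnnotationCatalog(novel), truth


# ---------------------------------------------------------------------------
# sequences

_BASES = "ACGT"
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
]
# GC3-biased codon usage: third-position G/C codons are favoured, giving the
# 3-periodic composition signal that the position/hexamer scorers measure.
_CODON_W = np.array([4.0 if c[2] in "GC" else 1.0 for c in _SENSE_CODONS])
_CODON_P = _CODON_W / _CODON_W.sum()


def _bg_transition(prev2: str) -> np.ndarray:
    """Order-2 background transition probabilities with CpG depletion."""
    q = np.array([0.30, 0.20, 0.20, 0.30])
    if prev2[1] == "C":
        q = q.copy()
        q[2] *= 0.25  # suppress CpG dinucleotides
    return q / q.sum()


_BG_TABLE = {
    a + b: _bg_transition(a + b) for a in _BASES for b in _BASES
}


def _noncoding_sequence(length: int, rng: np.random.Generator) -> str:
    out = list(rng.choice(list(_BASES), size=2, p=[0.3, 0.2, 0.2, 0.3]))
    for _ in range(length - 2):
        probs = _BG_TABLE[out[-2] + out[-1]]
        out.append(_BASES[rng.choice(4, p=probs)])
    seq = "".join(out[:length])
    # disrupt any long ORF so noncoding sequences never look coding
    while True:
        orf_len, _, _, start = longest_orf(seq)
        if orf_len < _ORF_CAP:
            return seq
        mid = start + 3 * ((orf_len // 3) // 2)
        seq = seq[:mid] + "TAA" + seq[mid + 3 :]


def _coding_sequence(length: int, rng: np.random.Generator) -> str:
    """Codon-biased sequence with an ORF covering >= 60% of the length."""
    cov = float(rng.uniform(0.65, 0.90))
    n_codons = max(int(np.ceil(length * cov / 3.0)), 21)
    n_codons = min(n_codons, length // 3)
    orf_nt = 3 * n_codons
    utr5 = int(rng.integers(0, length - orf_nt + 1))
    body = "".join(
        _SENSE_CODONS[i] for i in rng.choice(len(_SENSE_CODONS), n_codons - 2, p=_CODON_P)
    )
    orf = "ATG" + body + str(rng.choice(list(STOP_CODONS)))
    left = _noncoding_sequence(utr5, rng) if utr5 else ""
    right_len = length - utr5 - orf_nt
    right = _noncoding_sequence(right_len, rng) if right_len else ""
    return left + orf + right


def generate_sequences(
    known: AnnotationCatalog,
    novel: AnnotationCatalog,
    truth: GroundTruth,
    design: SimulationDesign,
) -> dict[str, str]:
    """Mature sequences per transcript: codon-biased for coding biotypes and
    coding-like decoys, background (ORF-capped) for everything else."""
    rng = design.rng(1)
    coding_like = set(truth.decoy_coding_ids)
    seqs: dict[str, str] = {}
    for t in list(known) + list(novel):
        length = t.mature_length
        if t.biotype == "coding" or t.id in coding_like:
            seqs[t.id] = _coding_sequence(length, rng)
        else:
            seqs[t.id] = _noncoding_sequence(length, rng)
    return seqs


def generate_training_sequences(
    design: SimulationDesign, n_per_class: int = 500,
    length_range: tuple[int, int] = (300, 3000),
) -> tuple[list[str], list[int]]:
    """Labelled training corpus for the coding-potential scorers (1=coding)."""
    rng = design.rng(7)
    seqs: list[str] = []
    labels: list[int] = []
    for _ in range(n_per_class):
        seqs.append(_coding_sequence(int(rng.integers(*length_range)), rng))
        labels.append(1)
    for _ in range(n_per_class):
        seqs.append(_noncoding_sequence(int(rng.integers(*length_range)), rng))
        labels.append(0)
    return seqs, labels


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=tid, description="") for tid, s in seqs.items()]
    seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# expression


def _latent_loading(r_target: float, sd: float) -> float:
    """Loading ``a`` of the shared factor so that two transcripts with log2
    values mu + a*z + Normal(0, sd) have Pearson r ~= ``r_target`` on the
    FPKM (2**x) scale, where the pipeline computes its correlations.

    Uses the lognormal correlation identity
    corr(e^X, e^Y) = (exp(rho*s^2) - 1) / (exp(s^2) - 1)
    with s^2 the per-variable log-variance in natural-log units and
    rho = a^2/(a^2 + sd^2) the log-scale correlation.
    """
    if r_target <= 0 or sd <= 0:
        return 0.0
    from scipy.optimize import brentq

    ln2sq = np.log(2.0) ** 2

    def fpkm_corr(a: float) -> float:
        v = a * a + sd * sd
        s2 = v * ln2sq
        rho = a * a / v
        return (np.exp(rho * s2) - 1.0) / (np.exp(s2) - 1.0)

    hi = 1.0
    while fpkm_corr(hi) < r_target and hi < 32.0:
        hi *= 2.0
    return float(brentq(lambda a: fpkm_corr(a) - r_target, 1e-9, hi))


def _baselines(
    design: SimulationDesign, known: AnnotationCatalog, novel: AnnotationCatalog,
    truth: GroundTruth,
) -> pd.Series:
    """Per-transcript baseline log2 FPKM, shared across cohorts."""
    rng = design.rng(2)
    silent = set(truth.silent_ids)
    base = {}
    for t in list(known) + list(novel):
        if t.id in silent:
            base[t.id] = -12.0
        elif t.biotype == "coding":
            base[t.id] = float(rng.normal(3.5, 1.0))
        elif t.biotype == "known_noncoding":
            base[t.id] = float(rng.normal(1.5, 0.8))
        else:
            base[t.id] = float(rng.normal(1.0, 0.7))
    return pd.Series(base)


def generate_expression(
    design: SimulationDesign,
    truth: GroundTruth,
    known: AnnotationCatalog,
    novel: AnnotationCatalog,
    groups: Sequence[tuple[str, int]] | None = None,
    cohort: str = "discovery",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM matrix and sample metadata with all planted effects.

    Baseline log2 FPKM is Normal(mu_t, noise_sd_log2) per sample.
    MS-lincRNAs gain ``effect_log2fc`` in their subtype only; Class I/II
    transcripts are shifted down/up in every tumor sample and Class III up
    in luminal samples; each planted cis (and coding-coding) pair shares a
    latent factor scaled to an expected Pearson r of ``cis_latent_r``.
    """
    if groups is None:
        groups = [(g, design.samples_per_group) for g in design.groups]
    rng = design.rng(3 if cohort == "discovery" else 4)
    sample_groups: list[str] = []
    for g, n in groups:
        sample_groups += [g] * n
    n_s = len(sample_groups)
    prefix = "S" if cohort == "discovery" else "V"
    sample_ids = [f"{prefix}{i:03d}_{g}" for i, g in enumerate(sample_groups)]
    meta = pd.DataFrame({"group": sample_groups}, index=sample_ids)
    is_tumor = np.isin(sample_groups, TUMOR_GROUPS)
    is_luminal = np.isin(sample_groups, LUMINAL_GROUPS)

    base = _baselines(design, known, novel, truth)
    ids = list(base.index)
    sd = design.noise_sd_log2
    values = base.to_numpy()[:, None] + rng.normal(0.0, sd, size=(len(ids), n_s))
    row = {tid: i for i, tid in enumerate(ids)}

    eff = design.effect_log2fc
    for subtype, members in truth.ms_lincrna_map.items():
        mask = np.asarray(sample_groups) == subtype
        for tid in members:
            values[row[tid], mask] += eff
    for tid, cls in truth.planted_class.items():
        if cls == "I":
            values[row[tid], is_tumor] -= eff
        elif cls == "II":
            values[row[tid], is_tumor] += eff
        elif cls == "III":
            values[row[tid], is_luminal] += eff
    a = _latent_loading(design.cis_latent_r, sd)
    for linc, gene, _ in truth.cis_pairs:
        z = rng.normal(0.0, 1.0, n_s)
        values[row[linc]] += a * z
        values[row[gene]] += a * z
    for g1, g2, _ in truth.coding_coexpressed_pairs:
        z = rng.normal(0.0, 1.0, n_s)
        values[row[g1]] += a * z
        values[row[g2]] += a * z
    for members in truth.coexpressed_modules:
        z = rng.normal(0.0, 1.0, n_s)
        for gid in members:
            values[row[gid]] += a * z

    fpkm = pd.DataFrame(2.0 ** values, index=ids, columns=sample_ids)
    return fpkm, meta


# ---------------------------------------------------------------------------
# methylation


def generate_methylation(
    design: SimulationDesign,
    truth: GroundTruth,
    known: AnnotationCatalog,
    novel: AnnotationCatalog,
    fpkm: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Beta matrix and CpG coordinates (BED-style, 0-based half-open).

    Each regulated transcript gets one CpG 500-2000 bp upstream of its TSS
    whose beta is a logistic transform of (minus) the standardised
    expression plus noise; null CpGs in the window are independent noise;
    decoy CpGs are placed outside the window.
    """
    rng = design.rng(5)
    n_s = fpkm.shape[1]
    catalog = {t.id: t for t in list(known) + list(novel)}

    n_reg_novel = int(round(design.meth_regulated_fraction * design.n_novel_lincrna))
    coding_ids = [t.id for t in known if t.biotype == "coding"]
    n_reg_coding = int(round(design.meth_regulated_fraction * 50))
    regulated = list(
        rng.choice(truth.novel_lincrna_ids, size=n_reg_novel, replace=False)
    ) + list(rng.choice(coding_ids, size=n_reg_coding, replace=False))

    remaining = [
        tid for tid in catalog
        if tid not in set(regulated) and tid not in set(truth.silent_ids)
    ]
    nulls = list(rng.choice(remaining, size=min(100, len(remaining)), replace=False))
    decoy_hosts = [tid for tid in remaining if tid not in set(nulls)][:20]

    rows, bed = {}, []
    counter = 0

    def place(tid: str, lo: int, hi: int) -> str:
        nonlocal counter
        t = catalog[tid]
        d = int(rng.integers(lo, hi + 1))
        pos = t.tss - d if t.strand != "-" else t.tss + d
        cg = f"cg{counter:05d}"
        counter += 1
        bed.append({"chrom": t.chrom, "start": max(pos, 0), "end": max(pos, 0) + 1, "id": cg})
        return cg

    b = design.meth_slope
    for tid in regulated:
        cg = place(tid, 500, 2000)
        sign = "-" if rng.random() < 0.8 else "+"
        expr = np.log2(fpkm.loc[tid].to_numpy() + 1.0)
        z = (expr - expr.mean()) / (expr.std() or 1.0)
        slope = -b if sign == "-" else b
        rows[cg] = expit(rng.normal(0.0, 0.7) + slope * z + rng.normal(0.0, 0.5, n_s))
        truth.meth_regulated.append((tid, cg, sign))
    for tid in nulls:
        cg = place(tid, 500, 2000)
        rows[cg] = expit(rng.normal(0.0, 1.0, n_s))
    for tid in decoy_hosts:
        cg = place(tid, 2500, 5000)
        rows[cg] = expit(rng.normal(0.0, 1.0, n_s))

    beta = pd.DataFrame.from_dict(rows, orient="index", columns=fpkm.columns)
    return beta, pd.DataFrame(bed, columns=["chrom", "start", "end", "id"]).set_index("id")


# ---------------------------------------------------------------------------
# survival & PPI


def generate_survival(
    design: SimulationDesign,
    labels: pd.Series,
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Exponential event times with cluster-specific hazards and independent
    uniform censoring over ``censor_horizon`` (infinite horizon = none)."""
    rng = design.rng(6)
    clusters = sorted(pd.unique(labels))
    lo, hi = design.hazard_ratio_range
    ratios = np.geomspace(lo, hi, num=len(clusters)) if len(clusters) > 1 else np.array([lo])
    lam0 = np.log(2.0) / design.baseline_median_survival
    hazards = {c: float(lam0 * r) for c, r in zip(clusters, ratios)}
    if truth is not None:
        truth.cluster_hazards = {str(c): h for c, h in hazards.items()}
    t_event = np.array([rng.exponential(1.0 / hazards[c]) for c in labels])
    if np.isinf(design.censor_horizon):
        t_cens = np.full(len(labels), np.inf)
    else:
        t_cens = rng.uniform(0.0, design.censor_horizon, size=len(labels))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": time, "event": event}, index=labels.index)


def generate_ppi(
    known: AnnotationCatalog,
    design: SimulationDesign,
    truth: GroundTruth,
    n_random: int = 200,
) -> pd.DataFrame:
    """Undirected simple PPI edge list over coding gene ids.

    Planted coexpressed coding pairs flagged ``ppi=True`` are guaranteed an
    edge; planted pairs flagged ``False`` are guaranteed absent; the rest
    are random background edges (no self-loops, no duplicates)."""
    rng = design.rng(8)
    coding_ids = [t.id for t in known if t.biotype == "coding"]
    edges: set[frozenset] = set()
    forbidden = {
        frozenset((a, b)) for a, b, ppi in truth.coding_coexpressed_pairs if not ppi
    }
    for a, b, ppi in truth.coding_coexpressed_pairs:
        if ppi:
            edges.add(frozenset((a, b)))
    for members in truth.coexpressed_modules:
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                edges.add(frozenset((a, b)))
    attempts = 0
    while len(edges) < n_random and attempts < 50 * n_random:
        attempts += 1
        a, b = rng.choice(coding_ids, size=2, replace=False)
        e = frozenset((a, b))
        if e not in forbidden:
            edges.add(e)
    rows = [sorted(e) for e in edges]
    rows.sort()
    return pd.DataFrame(rows, columns=["id1", "id2"])


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SimulatedStudy:
    design: SimulationDesign
    truth: GroundTruth
    known: AnnotationCatalog
    novel: AnnotationCatalog
    sequences: dict[str, str]
    fpkm: pd.DataFrame
    meta: pd.DataFrame
    beta: pd.DataFrame
    cpg: pd.DataFrame
    ppi: pd.DataFrame

    @property
    def ppi_set(self) -> set[frozenset]:
        return {frozenset((r.id1, r.id2)) for r in self.ppi.itertuples(index=False)}


def simulate(design: SimulationDesign, outdir: str | Path | None = None) -> SimulatedStudy:
    """Run every generator; optionally write all standard-format files."""
    known, novel, truth = generate_annotation(design)
    seqs = generate_sequences(known, novel, truth, design)
    fpkm, meta = generate_expression(design, truth, known, novel)
    beta, cpg = generate_methylation(design, truth, known, novel, fpkm)
    ppi = generate_ppi(known, design, truth)
    study = SimulatedStudy(design, truth, known, novel, seqs, fpkm, meta, beta, cpg, ppi)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gtf(known, outdir / "known.gtf")
        write_gtf(novel, outdir / "novel_candidates.gtf")
        write_fasta(seqs, outdir / "transcripts.fa")
        fpkm.to_csv(outdir / "fpkm.tsv", sep="\t")
        meta.to_csv(outdir / "samples.tsv", sep="\t")
        beta.to_csv(outdir / "meth_beta.tsv", sep="\t")
        cpg.reset_index()[["chrom", "start", "end", "id"]].to_csv(
            outdir / "cpg.bed", sep="\t", header=False, index=False
        )
        ppi.to_csv(outdir / "ppi.tsv", sep="\t", index=False)
        truth.to_json(outdir / "truth.json")
    return study
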