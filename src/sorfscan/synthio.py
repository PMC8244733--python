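"""Synthetic multi-tissue Ribo-seq/RNA-seq/MS data with planted ground truth.

The generator emulates the study design the analysis assumes: six tissues
with two replicates each, transcripts carrying a canonical CDS plus planted
sORFs of all seven positional classes, 3-nt periodic P-site signal on
translated ORFs (frame-multinomial allocation inside independent per-codon
Poisson counts), tissue-specific translation for a subset of sORFs, and an
MS detection probability that increases with peptide length and abundance.

P-site tracks are emitted directly (position -> count) rather than as reads;
RNA counts are fragments per transcript. Identical config + seed gives
bit-identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from . import io as sio
from .models import (
    SEVEN_CLASSES,
    START_CODON,
    STOP_CODONS,
    ConfigurationError,
    GeometryError,
    OrfRecord,
    TranscriptModel,
)
from .msval import tryptic_digest

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "SimTruth", "Simulation", "generate_genome",
           "simulate_tracks", "simulate_ms_table", "simulate", "write_outputs"]

TISSUE_NAMES = ("seedling", "root", "stem", "leaf", "ear", "tassel")
_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]
_STOPS = sorted(STOP_CODONS)


def _default_class_counts() -> dict[str, int]:
    return {c: 10 for c in SEVEN_CLASSES}


def _default_peptide_aa() -> dict[str, tuple[int, int]]:
    # Reproduces the observed class length ordering: annotated sORFs longest,
    # novel and internal sORFs shortest.
    return {
        "annotated": (50, 100),
        "uORF": (10, 40),
        "dORF": (10, 40),
        "Overlap_uORF": (15, 45),
        "Overlap_dORF": (15, 45),
        "Internal": (5, 20),
        "novel": (3, 12),
    }


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic dataset.

    ``periodicity_strength`` is the expected share of a translated ORF's
    P-sites landing in frame 0 (1/3 = no periodicity). ``mean_coverage`` is
    the expected P-site count per codon at unit expression. The MS detection
    model is logistic in log2(abundance+1) and peptide length.
    """

    seed: int = 0
    n_tissues: int = 6
    n_replicates: int = 2
    n_coding_transcripts: int = 80
    n_noncoding_transcripts: int = 15
    planted_class_counts: dict = field(default_factory=_default_class_counts)
    periodicity_strength: float = 0.9
    mean_coverage: float = 30.0
    tissue_specific_fraction: float = 0.3
    detect_beta0: float = -4.0
    detect_beta_abund: float = 0.3
    detect_beta_len: float = 0.04
    missing_assay_samples: list = field(default_factory=list)
    # geometry (nt); UTR lengths are sampled uniformly from these ranges
    utr5_range: tuple = (150, 400)
    utr3_range: tuple = (150, 400)
    morf_aa_range: tuple = (120, 280)
    noncoding_len_range: tuple = (400, 800)
    class_peptide_aa: dict = field(default_factory=_default_peptide_aa)
    n_chromosomes: int = 2
    telomere_bias: float = 0.0
    # expression model
    expr_sigma_tissue: float = 0.8
    expr_sigma_rep: float = 0.1
    rna_depth: float = 50.0  # expected fragments per kb at unit expression
    background_rate: float = 0.0  # P-sites per nt on untranslated positions
    sorf_te_boost: float = 2.0
    # MS model
    ms_missed_cleavages: int = 2
    ms_min_len: int = 7
    ms_max_len: int = 50
    ms_max_peptides: int = 3
    decoy_rate: float = 0.0

    def __post_init__(self) -> None:
        unknown = set(self.planted_class_counts) - set(SEVEN_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown ORF classes {sorted(unknown)}")
        if not 1 / 3 < self.periodicity_strength <= 1:
            raise ConfigurationError("periodicity_strength must be in (1/3, 1]")
        if self.n_tissues * self.n_replicates < 2:
            raise ConfigurationError("need at least two samples")

    @property
    def tissues(self) -> list[str]:
        if self.n_tissues <= len(TISSUE_NAMES):
            return list(TISSUE_NAMES[: self.n_tissues])
        return [f"tissue{i + 1}" for i in range(self.n_tissues)]

    @property
    def samples(self) -> list[str]:
        return [f"{t}{r + 1}" for t in self.tissues for r in range(self.n_replicates)]

    def tissue_of(self, sample: str) -> str:
        for t in self.tissues:
            if sample.startswith(t):
                return t
        raise KeyError(sample)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("utr5_range", "utr3_range", "morf_aa_range", "noncoding_len_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "class_peptide_aa" in raw:
            raw["class_peptide_aa"] = {
                k: tuple(v) for k, v in raw["class_peptide_aa"].items()
            }
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SimTruth:
    """Planted ground truth consumed by recovery and validation tests."""

    translated_orf_ids: set = field(default_factory=set)
    ms_detected_orf_ids: set = field(default_factory=set)
    tissue_of_specific_orfs: dict = field(default_factory=dict)
    parent_of_orf: dict = field(default_factory=dict)
    class_of_orf: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "translated_orf_ids": sorted(self.translated_orf_ids),
                    "ms_detected_orf_ids": sorted(self.ms_detected_orf_ids),
                    "tissue_of_specific_orfs": self.tissue_of_specific_orfs,
                    "parent_of_orf": self.parent_of_orf,
                    "class_of_orf": self.class_of_orf,
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            translated_orf_ids=set(raw["translated_orf_ids"]),
            ms_detected_orf_ids=set(raw["ms_detected_orf_ids"]),
            tissue_of_specific_orfs=raw["tissue_of_specific_orfs"],
            parent_of_orf=raw["parent_of_orf"],
            class_of_orf=raw["class_of_orf"],
        )


@dataclass
class Simulation:
    config: SimConfig
    genome: dict
    models: list
    planted: list  # OrfRecord with orf_class set
    truth: SimTruth


# ---------------------------------------------------------------------------
# sequence helpers


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(_BASES[rng.integers(0, 4, size=n)])


def _random_coding(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + stop codon (n_codons counts the aa)."""
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 1)
    body = "".join(_NONSTOP_CODONS[i] for i in idx)
    return START_CODON + body + _STOPS[rng.integers(0, 3)]


def _plant(seq: list[str], start: int, end: int, rng: np.random.Generator,
           protected: frozenset[int] = frozenset()) -> None:
    """Overwrite [start, end) with a candidate ORF, sparing protected bases."""
    for i, ch in enumerate(START_CODON):
        if start + i not in protected:
            seq[start + i] = ch
    stop = _STOPS[rng.integers(0, 3)]
    for i, ch in enumerate(stop):
        if end - 3 + i not in protected:
            seq[end - 3 + i] = ch
    for p in range(start + 3, end - 3):
        if p not in protected:
            seq[p] = str(_BASES[rng.integers(0, 4)])


def _orf_ok(seq: Sequence[str], start: int, end: int) -> bool:
    """ORF well-formed and maximal for its stop (no 5' in-frame extension)."""
    if "".join(seq[start : start + 3]) != START_CODON:
        return False
    if "".join(seq[end - 3 : end]) not in STOP_CODONS:
        return False
    for p in range(start + 3, end - 3, 3):
        if "".join(seq[p : p + 3]) in STOP_CODONS:
            return False
    p = start - 3
    while p >= 0:
        codon = "".join(seq[p : p + 3])
        if codon in STOP_CODONS:
            break
        if codon == START_CODON:
            return False
        p -= 3
    return True


def _cds_ok(seq: Sequence[str], cs: int, ce: int) -> bool:
    if "".join(seq[cs : cs + 3]) != START_CODON:
        return False
    if "".join(seq[ce - 3 : ce]) not in STOP_CODONS:
        return False
    for p in range(cs + 3, ce - 3, 3):
        if "".join(seq[p : p + 3]) in STOP_CODONS:
            return False
    return True


# ---------------------------------------------------------------------------
# transcript construction


def _build_transcript(rng: np.random.Generator, tid: str, planted_class: Optional[str],
                      cfg: SimConfig) -> tuple[list[str], Optional[tuple[int, int]],
                                               Optional[tuple[int, int]]]:
    """Return (sequence, cds interval, planted ORF interval), all transcript
    coordinates; raises :class:`GeometryError` when the class cannot fit."""
    lo5, hi5 = cfg.utr5_range
    lo3, hi3 = cfg.utr3_range

    if planted_class == "novel":
        length = int(rng.integers(*cfg.noncoding_len_range))
        pep = int(rng.integers(*cfg.class_peptide_aa["novel"]))
        orf_len = 3 * pep + 3
        if length < orf_len + 12:
            raise GeometryError(f"{tid}: non-coding transcript too short for novel ORF")
        for _ in range(300):
            seq = _random_seq(rng, length)
            s = int(rng.integers(6, length - orf_len - 3))
            s -= s % 3 - int(rng.integers(0, 3)) if False else 0
            _plant(seq, s, s + orf_len, rng)
            if _orf_ok(seq, s, s + orf_len):
                return seq, None, (s, s + orf_len)
        raise GeometryError(f"{tid}: could not plant novel ORF")

    if planted_class == "annotated":
        pep = int(rng.integers(*cfg.class_peptide_aa["annotated"]))
    else:
        pep = int(rng.integers(*cfg.morf_aa_range))
    cds_len = 3 * pep + 3

    for _ in range(300):
        utr5 = int(rng.integers(lo5, hi5 + 1))
        utr3 = int(rng.integers(lo3, hi3 + 1))
        cs, ce = utr5, utr5 + cds_len
        seq = _random_seq(rng, utr5) + list(_random_coding(rng, pep)) + _random_seq(rng, utr3)
        length = len(seq)

        if planted_class is None:
            if _cds_ok(seq, cs, ce):
                return seq, (cs, ce), None
            continue

        if planted_class == "annotated":
            if _cds_ok(seq, cs, ce) and _orf_ok(seq, cs, ce):
                return seq, (cs, ce), (cs, ce)
            continue

        L = int(rng.integers(*cfg.class_peptide_aa[planted_class]))
        orf_len = 3 * L + 3
        protected = frozenset(range(cs, cs + 3)) | frozenset(range(ce - 3, ce))

        if planted_class == "uORF":
            if hi5 < orf_len + 6:
                raise GeometryError(f"{tid}: 5'UTR too short for uORF of {L} aa")
            if utr5 < orf_len + 6:
                continue
            s = int(rng.integers(3, utr5 - orf_len - 2))
            e = s + orf_len
        elif planted_class == "dORF":
            if hi3 < orf_len + 6:
                raise GeometryError(f"{tid}: 3'UTR too short for dORF of {L} aa")
            if utr3 < orf_len + 6:
                continue
            s = ce + int(rng.integers(3, utr3 - orf_len - 2))
            e = s + orf_len
        elif planted_class == "Overlap_uORF":
            k = int(rng.choice([7, 8, 10, 11, 13, 14, 16, 17, 19, 20]))
            s = cs + k - orf_len
            e = cs + k
            if hi5 < orf_len - k + 6:
                raise GeometryError(f"{tid}: 5'UTR too short for Overlap_uORF of {L} aa")
            if s < 3:
                continue
        elif planted_class == "Overlap_dORF":
            k = int(rng.choice([7, 8, 10, 11, 13, 14, 16, 17, 19, 20]))
            s = ce - k
            e = s + orf_len
            if hi3 < orf_len - k + 6:
                raise GeometryError(f"{tid}: 3'UTR too short for Overlap_dORF of {L} aa")
            if e > length - 3 or s < cs + 3:
                continue
        elif planted_class == "Internal":
            if cds_len < orf_len + 12:
                continue
            o = int(rng.integers(3, cds_len - orf_len - 6))
            if o % 3 == 0:
                o += 1
            s = cs + o
            e = s + orf_len
        else:  # pragma: no cover
            raise ConfigurationError(f"unknown class {planted_class}")

        _plant(seq, s, e, rng, protected)
        if not _orf_ok(seq, s, e):
            continue
        if not _cds_ok(seq, cs, ce):
            continue
        return seq, (cs, ce), (s, e)

    raise GeometryError(f"{tid}: could not satisfy geometry for {planted_class}")


def generate_genome(config: SimConfig) -> Simulation:
    """Build the genome FASTA content, transcript models, and planted truth.

    Every planted sORF starts with ATG, ends at its first in-frame stop, is
    maximal for that stop (so the caller's longest-per-stop collapse recovers
    its exact coordinates), and each requested class is present.
    """
    rng = np.random.default_rng([config.seed, 0])
    counts = dict(config.planted_class_counts)
    coding_classes = ["annotated", "uORF", "dORF", "Overlap_uORF", "Overlap_dORF", "Internal"]
    n_coding_hosts = sum(counts.get(c, 0) for c in coding_classes)
    n_novel = counts.get("novel", 0)
    if n_coding_hosts > config.n_coding_transcripts:
        raise ConfigurationError(
            f"{n_coding_hosts} coding hosts needed but only "
            f"{config.n_coding_transcripts} coding transcripts configured"
        )
    if n_novel > config.n_noncoding_transcripts:
        raise ConfigurationError("not enough non-coding transcripts for novel ORFs")

    roles: list[Optional[str]] = []
    for c in coding_classes:
        roles += [c] * counts.get(c, 0)
    roles += [None] * (config.n_coding_transcripts - n_coding_hosts)
    roles += ["novel"] * n_novel
    roles += ["nc"] * (config.n_noncoding_transcripts - n_novel)

    models: list[TranscriptModel] = []
    planted: list[OrfRecord] = []
    truth = SimTruth()
    built: list[tuple[str, str, list[str], Optional[tuple], Optional[tuple], str]] = []
    for i, role in enumerate(roles):
        tid = f"tx{i + 1:04d}"
        gid = f"gene{i + 1:04d}"
        planted_class = None if role in (None, "nc") else role
        seq, cds, orf_iv = _build_transcript(rng, tid, planted_class, config)
        biotype = "protein_coding" if cds is not None else "non_coding"
        built.append((tid, gid, seq, cds, orf_iv, biotype))
        if orf_iv is not None:
            s, e = orf_iv
            orf_id = f"{tid}:{s}-{e}"
            pep = str(Seq("".join(seq[s : e - 3])).translate())
            planted.append(
                OrfRecord(orf_id=orf_id, transcript_id=tid, start=s, end=e,
                          peptide=pep, orf_class=role)
            )
            truth.translated_orf_ids.add(orf_id)
            truth.parent_of_orf[orf_id] = gid
            truth.class_of_orf[orf_id] = role

    # tissue-specific subset of the planted sORFs
    n_specific = int(round(config.tissue_specific_fraction * len(planted)))
    if n_specific:
        chosen = rng.choice(len(planted), size=n_specific, replace=False)
        for j in sorted(chosen):
            tissue = config.tissues[int(rng.integers(0, config.n_tissues))]
            truth.tissue_of_specific_orfs[planted[j].orf_id] = tissue

    # lay the transcripts out on chromosomes
    genome: dict[str, str] = {}
    per_chrom: dict[str, list[int]] = {f"chr{c + 1}": [] for c in range(config.n_chromosomes)}
    for i in range(len(built)):
        per_chrom[f"chr{i % config.n_chromosomes + 1}"].append(i)
    for chrom, idxs in per_chrom.items():
        total = sum(len(built[i][2]) for i in idxs)
        chrom_len = max(3 * total, 1000)
        slack = chrom_len - total
        if config.telomere_bias > 0:
            b = max(0.05, 1.0 - config.telomere_bias)
            rel = np.sort(rng.beta(b, b, size=len(idxs)))
        else:
            rel = np.sort(rng.random(size=len(idxs)))
        chrom_seq = _random_seq(rng, chrom_len)
        cursor = 0
        for u, i in zip(rel, idxs):
            tid, gid, seq, cds, orf_iv, biotype = built[i]
            gstart = min(max(cursor, int(u * slack)), chrom_len - len(seq) - (0 if i == idxs[-1] else 1))
            gstart = max(gstart, cursor)
            gend = gstart + len(seq)
            strand = "+" if rng.random() < 0.5 else "-"
            tx_seq = "".join(seq)
            segment = tx_seq if strand == "+" else str(Seq(tx_seq).reverse_complement())
            chrom_seq[gstart:gend] = list(segment)
            cursor = gend
            models.append(
                TranscriptModel(
                    transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand,
                    exons=((gstart, gend),), sequence=tx_seq, cds=cds, biotype=biotype,
                )
            )
        genome[chrom] = "".join(chrom_seq)

    return Simulation(config=config, genome=genome, models=models,
                      planted=planted, truth=truth)


# ---------------------------------------------------------------------------
# expression tracks


def _expression(rng: np.random.Generator, cfg: SimConfig, n_tx: int) -> np.ndarray:
    """(transcript x sample) expression multipliers; replicates share the
    tissue mean up to lognormal replicate noise."""
    tissue = rng.lognormal(0.0, cfg.expr_sigma_tissue, size=(n_tx, cfg.n_tissues))
    reps = rng.lognormal(0.0, cfg.expr_sigma_rep,
                         size=(n_tx, cfg.n_tissues, cfg.n_replicates))
    return (tissue[:, :, None] * reps).reshape(n_tx, -1)


def simulate_tracks(sim: Simulation, config: Optional[SimConfig] = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample P-site tracks and RNA fragment counts.

    Translated ORFs receive independent Poisson counts per codon, allocated
    to frames with probabilities ``(ps, (1-ps)/2, (1-ps)/2)``; untranslated
    positions receive frame-uniform background. Tissue-specific ORFs have
    zero expected P-site signal outside their tissue. Samples listed in
    ``missing_assay_samples`` omit that assay.
    """
    cfg = config or sim.config
    rng = np.random.default_rng([cfg.seed, 1])
    samples = cfg.samples
    tx_index = {m.transcript_id: i for i, m in enumerate(sim.models)}
    expr = _expression(rng, cfg, len(sim.models))
    ps = cfg.periodicity_strength
    frame_p = np.array([ps, (1 - ps) / 2, (1 - ps) / 2])
    missing = {tuple(x) for x in cfg.missing_assay_samples}

    units: list[tuple[str, int, int, float, Optional[str]]] = []
    for orf in sim.planted:
        units.append((orf.transcript_id, orf.start, orf.end, cfg.sorf_te_boost,
                      sim.truth.tissue_of_specific_orfs.get(orf.orf_id)))
    planted_tids = {orf.transcript_id for orf in sim.planted
                    if orf.orf_class == "annotated"}
    for m in sim.models:
        if m.cds is not None and m.transcript_id not in planted_tids:
            units.append((m.transcript_id, m.cds[0], m.cds[1], 1.0, None))

    psite_rows: list[tuple[str, int, int, str]] = []
    rna_rows: list[tuple[str, int, str]] = []
    for si, sample in enumerate(samples):
        tissue = cfg.tissue_of(sample)
        if (sample, "ribo") not in missing:
            acc: dict[str, dict[int, int]] = {}
            for tid, s, e, boost, spec_tissue in units:
                if spec_tissue is not None and spec_tissue != tissue:
                    continue
                lam = cfg.mean_coverage * expr[tx_index[tid], si] * boost
                n_codons = (e - s) // 3
                totals = rng.poisson(lam, size=n_codons)
                track = acc.setdefault(tid, {})
                for j, tot in enumerate(totals):
                    if tot == 0:
                        continue
                    f = rng.multinomial(tot, frame_p)
                    base = s + 3 * j
                    for k in range(3):
                        if f[k]:
                            track[base + k] = track.get(base + k, 0) + int(f[k])
            if cfg.background_rate > 0:
                for m in sim.models:
                    lam = cfg.background_rate * expr[tx_index[m.transcript_id], si]
                    n_bg = rng.poisson(lam * m.length)
                    if n_bg:
                        track = acc.setdefault(m.transcript_id, {})
                        for p in rng.integers(0, m.length, size=n_bg):
                            track[int(p)] = track.get(int(p), 0) + 1
            for tid in sorted(acc):
                for pos in sorted(acc[tid]):
                    psite_rows.append((tid, pos, acc[tid][pos], sample))
        if (sample, "rna") not in missing:
            for m in sim.models:
                lam = cfg.rna_depth * expr[tx_index[m.transcript_id], si] * m.length / 1000.0
                rna_rows.append((m.transcript_id, int(rng.poisson(lam)), sample))

    psites = pd.DataFrame(psite_rows, columns=sio.PSITE_COLUMNS)
    rna = pd.DataFrame(rna_rows, columns=sio.RNA_COLUMNS)
    return psites, rna


# ---------------------------------------------------------------------------
# MS peptide table


def _logistic(x: float) -> float:
    from scipy.special import expit

    return float(expit(x))


def simulate_ms_table(
    orfs: Sequence[OrfRecord],
    ribo_abundance: Mapping[str, float],
    config: SimConfig,
    seed: Optional[int] = None,
    samples: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, set]:
    """Draw an MS-style peptide table for the translated ORFs.

    Each ORF is detected with probability
    ``logistic(b0 + b_abund * log2(abundance + 1) + b_len * peptide_length)``;
    detected ORFs contribute 1..``ms_max_peptides`` fully tryptic peptides
    from their digest (reportable length range ``[ms_min_len, ms_max_len]``).
    An ORF whose digest yields no reportable peptide is never detected.
    """
    rng = np.random.default_rng([config.seed, 2] if seed is None else seed)
    samples = list(samples or config.samples)
    rows: list[tuple[str, str]] = []
    detected: set[str] = set()
    for orf in orfs:
        ab = float(ribo_abundance.get(orf.orf_id, 0.0))
        if ab < 0:
            raise ConfigurationError(f"negative abundance for {orf.orf_id}")
        x = (config.detect_beta0
             + config.detect_beta_abund * math.log2(ab + 1)
             + config.detect_beta_len * orf.peptide_length)
        if rng.random() >= _logistic(x):
            continue
        frags = sorted(set(tryptic_digest(
            orf.peptide, missed_cleavages=config.ms_missed_cleavages,
            min_len=config.ms_min_len, max_len=config.ms_max_len,
        )))
        if not frags:
            logger.info("ORF %s has no reportable tryptic peptide", orf.orf_id)
            continue
        detected.add(orf.orf_id)
        n_pep = int(rng.integers(1, min(config.ms_max_peptides, len(frags)) + 1))
        chosen = rng.choice(len(frags), size=n_pep, replace=False)
        for ci in sorted(chosen):
            n_samp = 1 + int(rng.binomial(len(samples) - 1, 0.5))
            for sj in sorted(rng.choice(len(samples), size=n_samp, replace=False)):
                rows.append((frags[int(ci)], samples[int(sj)]))
    if config.decoy_rate > 0:
        n_decoy = rng.poisson(config.decoy_rate * len(orfs))
        aa = np.array(list("ACDEFGHILMNPQSTVWY"))
        for _ in range(n_decoy):
            n = int(rng.integers(config.ms_min_len, config.ms_max_len + 1))
            pep = "".join(aa[rng.integers(0, len(aa), size=n - 1)]) + ("K" if rng.random() < 0.5 else "R")
            rows.append((pep, samples[int(rng.integers(0, len(samples)))]))
    table = pd.DataFrame(rows, columns=sio.PEPTIDE_COLUMNS)
    return table, detected


def detection_bias_experiment(
    config: Optional[SimConfig] = None, n_orfs: int = 600, seed: int = 0
) -> dict:
    """MS detection-bias study: verified vs unverified length/abundance.

    Simulates ``n_orfs`` peptides with independent length (5-80 aa, uniform)
    and translatome abundance (lognormal around 50) variation, draws MS
    detection under the logistic model, and returns the rank-sum contrasts of
    the detected against the undetected set. Reproduces the expected
    direction: detected peptides are longer and more abundant.
    """
    from .msval import ValidationRecord, verified_vs_unverified_contrast

    cfg = config or SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    orfs, abundance = [], {}
    for i in range(n_orfs):
        length = int(rng.integers(5, 81))
        pep = "M" + "".join(aa[rng.integers(0, 20, size=length - 1)])
        orfs.append(OrfRecord(orf_id=f"o{i}", transcript_id=f"t{i}",
                              start=0, end=3 * length + 3, peptide=pep))
        abundance[f"o{i}"] = float(rng.lognormal(math.log(50), 1.0))
    _, detected = simulate_ms_table(orfs, abundance, cfg, seed=seed + 1)
    records = [ValidationRecord(orf_id=o.orf_id, upn=int(o.orf_id in detected),
                                verified=o.orf_id in detected) for o in orfs]
    lengths = {o.orf_id: o.peptide_length for o in orfs}
    return verified_vs_unverified_contrast(records, abundance, lengths)


# ---------------------------------------------------------------------------
# one-call convenience + writers


def orf_psite_totals(planted: Sequence[OrfRecord], psites: pd.DataFrame) -> dict[str, float]:
    """Mean per-sample P-site count inside each planted ORF interval."""
    n_samples = max(psites["sample"].nunique(), 1)
    totals: dict[str, float] = {}
    by_tid = dict(tuple(psites.groupby("transcript_id")))
    for orf in planted:
        grp = by_tid.get(orf.transcript_id)
        if grp is None:
            totals[orf.orf_id] = 0.0
            continue
        mask = (grp["position0based"] >= orf.start) & (grp["position0based"] < orf.end)
        totals[orf.orf_id] = float(grp.loc[mask, "count"].sum()) / n_samples
    return totals


def simulate(config: SimConfig) -> tuple[Simulation, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full generation pass: genome + tracks + MS table (truth updated)."""
    sim = generate_genome(config)
    psites, rna = simulate_tracks(sim)
    abundance = orf_psite_totals(sim.planted, psites)
    peptides, detected = simulate_ms_table(sim.planted, abundance, config)
    sim.truth.ms_detected_orf_ids = detected & sim.truth.translated_orf_ids
    return sim, psites, rna, peptides


def write_outputs(sim: Simulation, psites: pd.DataFrame, rna: pd.DataFrame,
                  peptides: pd.DataFrame, outdir) -> dict[str, str]:
    """Write FASTA/GTF/TSV/JSON outputs; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "gtf": os.path.join(outdir, "annotation.gtf"),
        "psites": os.path.join(outdir, "psites.tsv"),
        "rna": os.path.join(outdir, "rna_counts.tsv"),
        "peptides": os.path.join(outdir, "peptides.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
        "config": os.path.join(outdir, "sim_config.yaml"),
    }
    sio.write_fasta(sim.genome, paths["genome"])
    lines: list[str] = []
    for m in sim.models:
        lines.extend(sio.transcript_gtf_lines(m))
    sio.write_gtf(lines, paths["gtf"])
    sio.write_psites(psites, paths["psites"])
    sio.write_rna_counts(rna, paths["rna"])
    sio.write_peptides(peptides, paths["peptides"])
    sim.truth.to_json(paths["truth"])
    sim.config.to_yaml(paths["config"])
    return paths
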