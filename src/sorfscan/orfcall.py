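"""ORF enumeration, periodicity-based translation calling, and classification.

The translation call rests on the three-nucleotide periodicity of ribosome
P-sites: an elongating ribosome steps one codon at a time, so genuine
translation concentrates P-site counts in frame 0 of the ORF. Per codon we
take the difference ``f0 - max(f1, f2)`` and apply a one-sided Wilcoxon
signed-rank test (zero differences dropped), with Benjamini-Hochberg
correction across ORFs within each sample.

Called ORFs are then placed into seven positional classes relative to the
transcript's annotated CDS: annotated, uORF, dORF, Overlap_uORF,
Overlap_dORF, Internal, and novel (non-coding host transcript).
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import io as sio
from .models import (
    INFRAME_NESTED,
    SEVEN_CLASSES,
    START_CODON,
    STOP_CODONS,
    GeometryError,
    OrfRecord,
    PeriodicityResult,
    TranscriptModel,
)

__all__ = [
    "enumerate_candidate_orfs",
    "test_periodicity",
    "call_sample",
    "merge_calls_across_samples",
    "classify_interval",
    "classify_orf",
    "filter_sorfs",
    "merge_with_reference",
    "call_sorfs",
]

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_AA = 2
DEFAULT_MAX_AA = 100
#: Minimum evidence to test an ORF at all: prevents 2-aa ORFs from being
#: called on a single read.
DEFAULT_MIN_CODONS = 5
DEFAULT_MIN_INFRAME = 10


# ---------------------------------------------------------------------------
# Candidate enumeration


def enumerate_candidate_orfs(
    transcript: TranscriptModel,
    min_aa: int = DEFAULT_MIN_AA,
    max_aa: int = DEFAULT_MAX_AA,
    longest_per_stop: bool = True,
) -> list[OrfRecord]:
    """All AUG...in-frame-stop ORFs wholly inside the transcript.

    By default ORFs sharing a stop codon are collapsed to the longest
    (5'-most AUG). Positions with non-ACGT characters are masked: ORFs
    spanning them are dropped with a warning. The collapse happens before the
    ``[min_aa, max_aa]`` peptide-length filter.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = transcript.sequence.upper()
    n = len(seq)
    masked = [i for i, ch in enumerate(seq) if ch not in "ACGT"]
    masked_arr = np.asarray(masked, dtype=int)

    candidates: list[tuple[int, int]] = []
    for frame in range(3):
        starts, stops = [], []
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon == START_CODON:
                starts.append(i)
            elif codon in STOP_CODONS:
                stops.append(i)
        for i in starts:
            k = bisect_left(stops, i + 3)
            if k < len(stops):
                candidates.append((i, stops[k] + 3))

    if longest_per_stop:
        by_stop: dict[int, int] = {}
        for s, e in candidates:
            if e not in by_stop or s < by_stop[e]:
                by_stop[e] = s
        candidates = [(s, e) for e, s in by_stop.items()]

    records = []
    for s, e in sorted(candidates):
        if masked_arr.size and np.any((masked_arr >= s) & (masked_arr < e)):
            warnings.warn(
                f"ORF [{s}, {e}) on {transcript.transcript_id} spans masked "
                "bases; dropped"
            )
            continue
        pep_len = (e - s - 3) // 3
        if not min_aa <= pep_len <= max_aa:
            continue
        peptide = str(Seq(seq[s : e - 3]).translate())
        records.append(
            OrfRecord(
                orf_id=f"{transcript.transcript_id}:{s}-{e}",
                transcript_id=transcript.transcript_id,
                start=s,
                end=e,
                peptide=peptide,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Periodicity test


def codon_frame_counts(
    track: Mapping[int, float] | np.ndarray, start: int, end: int
) -> np.ndarray:
    """Per-codon (f0, f1, f2) P-site counts over ``[start, end)``.

    ``track`` is either a position->count mapping or a dense per-position
    count array covering the interval.
    """
    if isinstance(track, np.ndarray):
        if track.size < end:
            track = np.pad(track, (0, end - track.size))
        return track[start:end].reshape(-1, 3)
    n_codons = (end - start) // 3
    out = np.zeros((n_codons, 3))
    for j in range(n_codons):
        base = start + 3 * j
        for f in range(3):
            out[j, f] = track.get(base + f, 0)
    return out


def test_periodicity(
    orf: OrfRecord,
    track: Mapping[int, float],
    sample: str = "",
    alpha: float = DEFAULT_ALPHA,
    min_codons: int = DEFAULT_MIN_CODONS,
    min_inframe_count: float = DEFAULT_MIN_INFRAME,
) -> PeriodicityResult:
    """One-sided paired test of frame-0 counts against the off-frame maximum.

    Returns a raw (unadjusted) result; insufficient coverage yields
    ``called=False`` with ``reason='insufficient coverage'`` rather than an
    exception. ``alpha`` only enters through the later BH adjustment.
    """
    counts = codon_frame_counts(track, orf.start, orf.end)
    informative = counts.sum(axis=1) > 0
    n_inf = int(informative.sum())
    inframe_total = counts[:, 0].sum()
    if n_inf < min_codons or inframe_total < min_inframe_count:
        return PeriodicityResult(
            orf_id=orf.orf_id,
            sample=sample,
            n_informative_codons=n_inf,
            statistic=0.0,
            p_value=1.0,
            called=False,
            reason="insufficient coverage",
        )
    diffs = counts[informative, 0] - counts[informative, 1:].max(axis=1)
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        stat, p = 0.0, 1.0
    else:
        # exact null only for small untied samples; otherwise the normal
        # approximation with continuity correction
        untied = np.unique(np.abs(nonzero)).size == nonzero.size
        method = "exact" if (untied and nonzero.size <= 25) else "approx"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = stats.wilcoxon(
                nonzero, alternative="greater", zero_method="wilcox",
                correction=True, method=method,
            )
    return PeriodicityResult(
        orf_id=orf.orf_id,
        sample=sample,
        n_informative_codons=n_inf,
        statistic=float(stat),
        p_value=float(p),
    )


def adjust_calls(
    results: Sequence[PeriodicityResult], alpha: float = DEFAULT_ALPHA
) -> list[PeriodicityResult]:
    """Benjamini-Hochberg adjustment within one sample; sets ``called``."""
    testable = [r for r in results if r.reason is None]
    if testable:
        _, adj, _, _ = multipletests(
            [r.p_value for r in testable], alpha=alpha, method="fdr_bh"
        )
        for r, q in zip(testable, adj):
            r.adjusted_p = float(max(q, r.p_value))
            r.called = bool(r.adjusted_p < alpha)
    return list(results)


def call_sample(
    orfs: Sequence[OrfRecord],
    track_by_transcript: Mapping[str, Mapping[int, float]],
    sample: str,
    alpha: float = DEFAULT_ALPHA,
    min_codons: int = DEFAULT_MIN_CODONS,
    min_inframe_count: float = DEFAULT_MIN_INFRAME,
) -> list[PeriodicityResult]:
    """Raw periodicity tests + BH correction for every candidate in a sample."""
    results = []
    for orf in orfs:
        track = track_by_transcript.get(orf.transcript_id)
        if track is None:
            results.append(
                PeriodicityResult(
                    orf_id=orf.orf_id, sample=sample, n_informative_codons=0,
                    statistic=0.0, p_value=1.0, called=False,
                    reason="insufficient coverage",
                )
            )
            continue
        results.append(
            test_periodicity(
                orf, track, sample=sample, alpha=alpha,
                min_codons=min_codons, min_inframe_count=min_inframe_count,
            )
        )
    return adjust_calls(results, alpha=alpha)


def merge_calls_across_samples(
    results: Iterable[PeriodicityResult], orfs_by_id: Mapping[str, OrfRecord]
) -> list[OrfRecord]:
    """Union rule: an ORF is retained if called in at least one sample.

    Identical ``(transcript, start, end)`` coordinates are deduplicated; the
    supporting-sample list and minimum adjusted p are recorded.
    """
    support: dict[tuple[str, int, int], dict] = {}
    for res in results:
        if not res.called:
            continue
        orf = orfs_by_id[res.orf_id]
        key = (orf.transcript_id, orf.start, orf.end)
        entry = support.setdefault(key, {"orf": orf, "samples": set(), "p": np.inf})
        entry["samples"].add(res.sample)
        entry["p"] = min(entry["p"], res.adjusted_p)
    merged = []
    for key in sorted(support):
        entry = support[key]
        orf = entry["orf"]
        merged.append(
            OrfRecord(
                orf_id=orf.orf_id,
                transcript_id=orf.transcript_id,
                start=orf.start,
                end=orf.end,
                peptide=orf.peptide,
                orf_class=orf.orf_class,
                samples=tuple(sorted(entry["samples"])),
                min_adjusted_p=float(entry["p"]),
            )
        )
    return merged


# ---------------------------------------------------------------------------
# Classification


def classify_interval(start: int, end: int, cds: tuple[int, int] | None) -> str:
    """Classify an ORF interval against a CDS interval (transcript coords).

    Decision order: no CDS -> ``novel``; boundaries equal to the CDS ->
    ``annotated``; entirely upstream/downstream -> ``uORF``/``dORF``;
    straddling the CDS 5' boundary -> ``Overlap_uORF`` (an ORF spanning the
    whole CDS falls here: the upstream start takes precedence); straddling the
    3' boundary -> ``Overlap_dORF``; fully inside in a shifted frame ->
    ``Internal``. A same-frame nested ORF gets the ``inframe_nested`` label,
    which is excluded from the seven-class output.
    """
    if cds is None:
        return "novel"
    cs, ce = cds
    s, e = start, end
    if (s, e) == (cs, ce):
        return "annotated"
    if e <= cs:
        return "uORF"
    if s >= ce:
        return "dORF"
    if s < cs < e:
        return "Overlap_uORF"
    if cs <= s < ce < e:
        return "Overlap_dORF"
    # remaining: fully inside the CDS
    if (s - cs) % 3 != 0:
        return "Internal"
    return INFRAME_NESTED


def classify_orf(orf: OrfRecord, transcript: TranscriptModel) -> str:
    """Seven-class positional label for an ORF on its own transcript (see
    :func:`classify_interval`)."""
    return classify_interval(orf.start, orf.end, transcript.cds)


def filter_sorfs(orfs: Iterable[OrfRecord]) -> list[OrfRecord]:
    """Keep sORFs: CDS 6-300 nt excluding the stop codon (peptide 2-100 aa),
    with one of the seven class labels."""
    kept = []
    for orf in orfs:
        if not 6 <= orf.cds_len_nt <= 300:
            continue
        if orf.orf_class is not None and orf.orf_class not in SEVEN_CLASSES:
            continue
        kept.append(orf)
    return kept


# ---------------------------------------------------------------------------
# Annotation merge


def merge_with_reference(
    sorfs: Sequence[OrfRecord],
    reference_gtf: str,
    models: Mapping[str, TranscriptModel],
    out_path: str,
    chrom_lengths: Mapping[str, int] | None = None,
) -> None:
    """Append one transcript/exon/CDS record group per sORF to the reference.

    sORF ids are stable (derived from host transcript and coordinates); the
    output round-trips through :func:`sorfscan.io.transcripts_from_gtf`.
    """
    with open(reference_gtf) as fh:
        ref_lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    new_lines = []
    for orf in sorted(sorfs, key=lambda o: o.orf_id):
        host = models[orf.transcript_id]
        blocks = host.to_genomic(orf.start, orf.end)
        if chrom_lengths is not None:
            limit = chrom_lengths[host.chrom]
            for gs, ge in blocks:
                if gs < 0 or ge > limit:
                    raise GeometryError(
                        f"sORF {orf.orf_id} projects outside {host.chrom}"
                    )
        tid = f"sORF_{orf.transcript_id}_{orf.start}_{orf.end}"
        sub = TranscriptModel(
            transcript_id=tid,
            gene_id=host.gene_id,
            chrom=host.chrom,
            strand=host.strand,
            exons=tuple(blocks if host.strand == "+" else blocks[::-1]),
            sequence="",
            cds=(0, orf.end - orf.start),
            biotype="sORF",
        )
        new_lines.extend(sio.transcript_gtf_lines(sub))
    sio.write_gtf(ref_lines + new_lines, out_path)


# ---------------------------------------------------------------------------
# End-to-end calling


def call_sorfs(
    models: Sequence[TranscriptModel],
    psites: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_aa: int = DEFAULT_MIN_AA,
    max_aa: int = DEFAULT_MAX_AA,
    min_codons: int = DEFAULT_MIN_CODONS,
    min_inframe_count: float = DEFAULT_MIN_INFRAME,
) -> tuple[list[OrfRecord], list[PeriodicityResult]]:
    """Enumerate, test per sample, BH-correct, merge, classify, and filter.

    Returns the called, classified sORF set and every per-sample periodicity
    result.
    """
    by_tid = {m.transcript_id: m for m in models}
    candidates: list[OrfRecord] = []
    for m in models:
        candidates.extend(enumerate_candidate_orfs(m, min_aa=min_aa, max_aa=max_aa))
    orfs_by_id = {o.orf_id: o for o in candidates}

    lengths = {m.transcript_id: m.length for m in models}
    tracks: dict[str, dict[str, np.ndarray]] = defaultdict(dict)
    for (sample, tid), grp in psites.groupby(["sample", "transcript_id"]):
        arr = np.zeros(lengths.get(tid, int(grp["position0based"].max()) + 1))
        np.add.at(arr, grp["position0based"].to_numpy(int), grp["count"].to_numpy(float))
        tracks[sample][tid] = arr

    all_results: list[PeriodicityResult] = []
    for sample in sorted(tracks):
        all_results.extend(
            call_sample(
                candidates,
                tracks[sample],
                sample,
                alpha=alpha,
                min_codons=min_codons,
                min_inframe_count=min_inframe_count,
            )
        )

    merged = merge_calls_across_samples(all_results, orfs_by_id)
    classified = [
        orf.with_class(classify_orf(orf, by_tid[orf.transcript_id])) for orf in merged
    ]
    return filter_sorfs(classified), all_results
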