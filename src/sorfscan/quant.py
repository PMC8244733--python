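"""Abundance (RPKM/FPKM), translation efficiency, and expression entropy.

RPKM = reads * 1e9 / (total mapped reads * feature length in nt); FPKM is
identical with fragments substituted for reads. TE is the ratio of
ribosome-footprint RPKM to mRNA FPKM for the same feature, computed only
where both assays pass the expression floor (default 0.5). Tissue
specificity is summarised as the Shannon entropy of the expression
distribution across columns: low entropy = expression concentrated in few
tissues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import OrfRecord, UndefinedValueError

__all__ = [
    "AbundanceMatrix",
    "compute_rpkm",
    "abundance_from_counts",
    "rna_abundance",
    "ribo_orf_counts",
    "compute_te",
    "shannon_entropy",
    "entropy_table",
    "contrast_entropy",
]

DEFAULT_MIN_EXPR = 0.5


@dataclass
class AbundanceMatrix:
    """Feature x sample normalized abundance for one assay.

    ``values`` is features x samples; ``lengths`` holds the feature length in
    nt (exon length for transcripts, CDS length including the stop for
    sORFs); ``totals`` the per-sample mapped reads/fragments.
    """

    assay: str  # "rna" | "ribo"
    unit: str  # "FPKM" | "RPKM"
    values: pd.DataFrame
    lengths: pd.Series
    totals: pd.Series

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundance values must be nonnegative")


def compute_rpkm(count: float, length: int, total: float) -> float:
    """Reads (or fragments) per kilobase per million mapped."""
    if length <= 0 or total <= 0:
        raise UndefinedValueError(
            f"RPKM undefined for length={length}, total={total}"
        )
    return count * 1e9 / (total * length)


def abundance_from_counts(
    counts: pd.DataFrame,
    lengths: Mapping[str, int],
    assay: str,
    unit: Optional[str] = None,
    totals: Optional[Mapping[str, float]] = None,
) -> AbundanceMatrix:
    """Normalize a feature x sample count table.

    ``totals`` defaults to the per-sample column sums (all mapped counts in
    the table); pass library totals explicitly when the table is a subset.
    """
    unit = unit or ("FPKM" if assay == "rna" else "RPKM")
    tot = pd.Series(totals) if totals is not None else counts.sum(axis=0)
    lens = pd.Series({f: lengths[f] for f in counts.index}, dtype=float)
    if (lens <= 0).any():
        bad = lens.index[lens <= 0][0]
        raise UndefinedValueError(f"feature {bad} has nonpositive length")
    if (tot <= 0).any():
        bad = tot.index[tot <= 0][0]
        raise UndefinedValueError(f"sample {bad} has zero mapped total")
    values = counts.mul(1e9).div(tot, axis=1).div(lens, axis=0)
    return AbundanceMatrix(assay=assay, unit=unit, values=values,
                           lengths=lens, totals=tot.astype(float))


def rna_abundance(rna_counts: pd.DataFrame, lengths: Mapping[str, int]) -> AbundanceMatrix:
    """FPKM matrix from the long-format RNA fragment table."""
    wide = (rna_counts.pivot_table(index="transcript_id", columns="sample",
                                   values="fragments", aggfunc="sum", fill_value=0)
            .astype(float))
    wide.columns.name = None
    return abundance_from_counts(wide, lengths, assay="rna", unit="FPKM")


def ribo_orf_counts(
    psites: pd.DataFrame, orfs: Sequence[OrfRecord], samples: Sequence[str]
) -> pd.DataFrame:
    """Per-ORF x sample P-site counts (all positions inside [start, end))."""
    out = pd.DataFrame(0.0, index=[o.orf_id for o in orfs], columns=list(samples))
    groups = dict(tuple(psites.groupby(["transcript_id", "sample"])))
    for orf in orfs:
        for sample in samples:
            grp = groups.get((orf.transcript_id, sample))
            if grp is None:
                continue
            mask = (grp["position0based"] >= orf.start) & (grp["position0based"] < orf.end)
            out.loc[orf.orf_id, sample] = float(grp.loc[mask, "count"].sum())
    return out


def compute_te(
    ribo: AbundanceMatrix,
    rna: AbundanceMatrix,
    min_expr: float = DEFAULT_MIN_EXPR,
) -> pd.DataFrame:
    """TE = ribo RPKM / rna FPKM where both pass the expression floor.

    Features/samples failing the floor, or samples missing one assay
    entirely, produce no record.
    """
    features = ribo.values.index.intersection(rna.values.index)
    samples = ribo.values.columns.intersection(rna.values.columns)
    rows = []
    for f in features:
        for s in samples:
            rv, mv = ribo.values.at[f, s], rna.values.at[f, s]
            if rv >= min_expr and mv >= min_expr:
                rows.append((f, s, rv / mv))
    return pd.DataFrame(rows, columns=["feature", "sample", "te"])


def shannon_entropy(values: Sequence[float]) -> float:
    """Entropy (bits) of the normalized expression vector.

    Zero-expression columns contribute nothing; an all-zero vector is
    undefined and returns NaN.
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("expression values must be nonnegative")
    total = v.sum()
    if total == 0:
        return float("nan")
    return float(stats.entropy(v / total, base=2))


def entropy_table(
    values: pd.DataFrame,
    collapse_replicates: bool = False,
    sample_to_tissue: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Per-feature entropy across columns.

    By default entropy is taken across all samples; with
    ``collapse_replicates`` columns are first averaged within tissue
    (requires ``sample_to_tissue``).
    """
    mat = values
    if collapse_replicates:
        if sample_to_tissue is None:
            raise ValueError("collapse_replicates requires sample_to_tissue")
        mat = values.T.groupby(lambda c: sample_to_tissue[c]).mean().T
    n = mat.shape[1]
    se = mat.apply(lambda row: shannon_entropy(row.to_numpy()), axis=1)
    return pd.DataFrame({"feature": mat.index, "se": se.to_numpy(),
                         "n_columns": n}).reset_index(drop=True)


def contrast_entropy(
    sorf_entropies: Sequence[float], canonical_entropies: Sequence[float]
) -> dict:
    """Rank-sum contrast of sORF vs canonical entropy (NaN entries dropped).

    Lower median entropy in the sORF group indicates higher tissue
    specificity.
    """
    from .downstream import rank_sum_test

    a = np.asarray(sorf_entropies, dtype=float)
    b = np.asarray(canonical_entropies, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two defined entropies")
    u, p = rank_sum_test(a, b, alternative="two-sided")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    direction = "sorf_more_specific" if med_a < med_b else (
        "canonical_more_specific" if med_b < med_a else "none")
    return {"u": u, "p": p, "median_sorf": med_a, "median_canonical": med_b,
            "direction": direction}
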