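"""Comparative statistics and summaries over called sORFs and sPeptides.

Covers the start/stop sequence-context matrices with per-position
chi-square contrasts, chromosome-scale bin densities, Mann-Whitney U
rank-sum contrasts, hierarchical clustering of samples and of feature
profiles, permutation-tested parent-gene correlation, and proportion
tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FreqMatrix",
    "ClusterResult",
    "extract_context",
    "position_frequency_matrix",
    "compare_position_frequencies",
    "genomic_bin_density",
    "rank_sum_test",
    "cluster_samples",
    "cluster_features_into_groups",
    "correlate_with_parent",
    "summarize_proportions",
]

#: Window layout: 5 nt upstream, the codon, 5 nt downstream.
CONTEXT_COLUMNS = ["-5", "-4", "-3", "-2", "-1", "c1", "c2", "c3",
                   "+1", "+2", "+3", "+4", "+5"]
_BASES = ["A", "C", "G", "T"]


@dataclass
class FreqMatrix:
    """Per-position base frequencies around a start or stop codon."""

    site: str  # "start" | "stop"
    freqs: pd.DataFrame  # rows A/C/G/T, 13 window columns
    counts: pd.DataFrame
    n_sequences: int


@dataclass
class ClusterResult:
    """Agglomerative clustering outcome (deterministic)."""

    linkage: np.ndarray
    labels: list[str]
    groups: dict[str, int]
    dropped: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# sequence context


def extract_context(sequence: str, codon_start: int, flank: int = 5) -> str:
    """The 13-nt window around a codon; out-of-transcript positions masked
    with ``N``."""
    out = []
    for p in range(codon_start - flank, codon_start + 3 + flank):
        out.append(sequence[p] if 0 <= p < len(sequence) else "N")
    return "".join(out)


def position_frequency_matrix(windows: Sequence[str], site: str = "start") -> FreqMatrix:
    """Relative base frequencies per window position.

    ``N`` (masked) characters are excluded from a position's denominator;
    each column's frequencies sum to 1 over the observed sequences.
    """
    if not windows:
        raise ValueError("empty input")
    width = len(CONTEXT_COLUMNS)
    counts = pd.DataFrame(0, index=_BASES, columns=CONTEXT_COLUMNS)
    for w in windows:
        if len(w) != width:
            raise ValueError(f"window {w!r} is not {width} nt")
        for j, ch in enumerate(w.upper()):
            if ch in _BASES:
                counts.iloc[_BASES.index(ch), j] += 1
    col_totals = counts.sum(axis=0)
    freqs = counts.div(col_totals.replace(0, np.nan), axis=1)
    return FreqMatrix(site=site, freqs=freqs, counts=counts, n_sequences=len(windows))


def compare_position_frequencies(set1: FreqMatrix, set2: FreqMatrix) -> pd.DataFrame:
    """Per-position chi-square on the 4x2 base-count table, BH-adjusted."""
    rows = []
    for col in CONTEXT_COLUMNS:
        table = np.column_stack([set1.counts[col].to_numpy(),
                                 set2.counts[col].to_numpy()])
        table = table[table.sum(axis=1) > 0]
        if table.shape[0] < 2 or (table.sum(axis=0) == 0).any():
            rows.append((col, np.nan, 1.0))
            continue
        if np.array_equal(table[:, 0] * table[:, 1].sum(),
                          table[:, 1] * table[:, 0].sum()):
            rows.append((col, 0.0, 1.0))
            continue
        chi2, p, _, _ = stats.chi2_contingency(table)
        rows.append((col, float(chi2), float(p)))
    df = pd.DataFrame(rows, columns=["position", "chi2", "p"])
    _, adj, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
    df["p_adj"] = adj
    return df


# ---------------------------------------------------------------------------
# genomic density


def genomic_bin_density(
    positions: Mapping[str, Sequence[int]],
    chrom_lengths: Mapping[str, int],
    bin_size: int,
) -> pd.DataFrame:
    """Counts of ORF starts per fixed-width genomic bin (trailing partial bin
    included)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        pos = np.asarray(positions.get(chrom, []), dtype=int)
        if pos.size and (pos.min() < 0 or pos.max() >= length):
            raise ValueError(f"position outside {chrom} (length {length})")
        n_bins = int(np.ceil(length / bin_size)) or 1
        counts, _ = np.histogram(pos, bins=n_bins, range=(0, n_bins * bin_size))
        for b, c in enumerate(counts):
            rows.append((chrom, b * bin_size, min((b + 1) * bin_size, length), int(c)))
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end", "count"])


# ---------------------------------------------------------------------------
# rank-sum


def rank_sum_test(
    group_a: Sequence[float], group_b: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U: exact p for small untied samples, otherwise the normal
    approximation with tie and continuity corrections."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# clustering


def _prepare(matrix: pd.DataFrame, log_transform: bool, standardize: bool
             ) -> tuple[pd.DataFrame, list[str]]:
    x = matrix.astype(float)
    if log_transform:
        x = np.log2(x + 1.0)
    sd = x.std(axis=1, ddof=0)
    dropped = list(x.index[sd == 0])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s)")
        x = x.loc[sd > 0]
        sd = sd[sd > 0]
    if standardize:
        x = x.sub(x.mean(axis=1), axis=0).div(sd, axis=0)
    return x, dropped


def cluster_samples(
    matrix: pd.DataFrame,
    k: int,
    log_transform: bool = True,
    standardize: bool = True,
) -> ClusterResult:
    """Complete-linkage Euclidean clustering of the sample columns on
    row-standardized log2(FPKM+1); cut into ``k`` groups."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    if matrix.shape[1] < k:
        raise ValueError(f"cannot cut {matrix.shape[1]} columns into {k} groups")
    x, dropped = _prepare(matrix, log_transform, standardize)
    if x.empty:
        raise ValueError("no informative features left")
    z = hierarchy.linkage(x.to_numpy().T, method="complete", metric="euclidean")
    assign = hierarchy.fcluster(z, t=k, criterion="maxclust")
    labels = list(matrix.columns)
    return ClusterResult(linkage=z, labels=labels,
                         groups=dict(zip(labels, map(int, assign))), dropped=dropped)


def cluster_features_into_groups(
    matrix: pd.DataFrame,
    k: int = 3,
    log_transform: bool = True,
    standardize: bool = True,
) -> tuple[ClusterResult, pd.DataFrame]:
    """Cluster feature expression profiles into ``k`` groups; also returns
    each group's mean profile."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    x, dropped = _prepare(matrix, log_transform, standardize)
    if x.shape[0] < k:
        raise ValueError(f"cannot cut {x.shape[0]} features into {k} groups")
    z = hierarchy.linkage(x.to_numpy(), method="complete", metric="euclidean")
    assign = hierarchy.fcluster(z, t=k, criterion="maxclust")
    labels = list(x.index)
    groups = dict(zip(labels, map(int, assign)))
    means = x.groupby(pd.Series(groups)).mean()
    means.index.name = "group"
    return ClusterResult(linkage=z, labels=labels, groups=groups,
                         dropped=dropped), means


# ---------------------------------------------------------------------------
# parent-gene correlation


def correlate_with_parent(
    orf_profile: Sequence[float],
    parent_profile: Sequence[float],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Pearson correlation of translatome profiles with a permutation p-value
    ``(1 + #{|r_perm| >= |r|}) / (1 + n_permutations)``."""
    x = np.asarray(orf_profile, dtype=float)
    y = np.asarray(parent_profile, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("profiles must share length >= 3")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        rp = np.corrcoef(x, rng.permutation(y))[0, 1]
        if abs(rp) >= abs(r) - 1e-12:
            count += 1
    return r, (1 + count) / (1 + n_permutations)


# ---------------------------------------------------------------------------
# proportions


def summarize_proportions(
    class_counts: Mapping[str, int],
    decimals: int = 2,
    verified_count: Optional[int] = None,
) -> pd.DataFrame:
    """Percent of total per class (rounded); optionally an overall
    verified/total rate row."""
    counts = {k: int(v) for k, v in class_counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be nonnegative")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total must be positive")
    rows = [(cls, n, round(100.0 * n / total, decimals))
            for cls, n in counts.items()]
    if verified_count is not None:
        rows.append(("verified_overall", int(verified_count),
                     round(100.0 * verified_count / total, decimals)))
    return pd.DataFrame(rows, columns=["class", "count", "percent"])
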