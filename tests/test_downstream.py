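"""Context matrices, bin density, rank-sum, clustering, correlation,
proportions."""

import numpy as np
import pandas as pd
import pytest
from helpers_oracles import ranksum_enumeration
from scipy.cluster import hierarchy

from sorfscan import downstream


# ---------------------------------------------------------------------------
# sequence context


def test_frequency_matrix_identical_inputs():
    w = "AAAAA" + "ATG" + "GGGGG"
    fm = downstream.position_frequency_matrix([w, w], site="start")
    assert fm.freqs.at["A", "-1"] == 1.0
    assert fm.freqs.at["A", "c1"] == 1.0
    assert fm.freqs.at["G", "+5"] == 1.0
    sums = fm.freqs.sum(axis=0)
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_frequency_matrix_masks_short_windows():
    w = downstream.extract_context("ATGGGGGG", 0)  # no upstream sequence
    fm = downstream.position_frequency_matrix([w])
    assert np.isnan(fm.freqs.at["A", "-5"])
    assert fm.freqs.at["A", "c1"] == 1.0


def test_frequency_matrix_empty_errors():
    with pytest.raises(ValueError):
        downstream.position_frequency_matrix([])


def test_positional_chi_square_detects_divergent_position():
    base = "AAAAA" + "ATG" + "GGGGG"
    set1 = downstream.position_frequency_matrix([base] * 50)
    other = "AAGAA" + "ATG" + "GGGGG"  # G at position -3
    set2 = downstream.position_frequency_matrix([other] * 50)
    comp = downstream.compare_position_frequencies(set1, set2)
    row = comp.set_index("position")
    assert row.at["-3", "p_adj"] < 0.001
    assert row.at["-1", "p_adj"] > 0.9


def test_positional_chi_square_self_comparison_is_null():
    rng = np.random.default_rng(0)
    windows = ["".join(rng.choice(list("ACGT"), size=13)) for _ in range(80)]
    fm = downstream.position_frequency_matrix(windows)
    comp = downstream.compare_position_frequencies(fm, fm)
    assert (comp["p"] == 1.0).all()


# ---------------------------------------------------------------------------
# bin density


def test_bin_density_counts_partition_orfs():
    dens = downstream.genomic_bin_density({"chr1": [1, 2, 3]}, {"chr1": 10}, 5)
    assert dens["count"].tolist() == [3, 0]
    empty = downstream.genomic_bin_density({}, {"chr1": 10}, 5)
    assert empty["count"].tolist() == [0, 0]
    with pytest.raises(ValueError):
        downstream.genomic_bin_density({"chr1": [12]}, {"chr1": 10}, 5)


def test_bin_density_telomere_biased_simulation():
    """U-shaped transcript placement produces higher density near the
    chromosome ends than around the midpoint."""
    from sorfscan.synthio import SimConfig, generate_genome

    cfg = SimConfig(seed=13, n_coding_transcripts=60, n_noncoding_transcripts=0,
                    planted_class_counts={"uORF": 30, "dORF": 30},
                    n_chromosomes=1, telomere_bias=0.9)
    sim = generate_genome(cfg)
    by_tid = {m.transcript_id: m for m in sim.models}
    positions = {}
    for orf in sim.planted:
        m = by_tid[orf.transcript_id]
        positions.setdefault(m.chrom, []).append(m.to_genomic(orf.start, orf.end)[0][0])
    length = len(sim.genome["chr1"])
    dens = downstream.genomic_bin_density(positions, {"chr1": length}, length // 10)
    counts = dens["count"].to_numpy()
    assert counts[0] + counts[-1] > counts[len(counts) // 2 - 1] + counts[len(counts) // 2]


# ---------------------------------------------------------------------------
# rank-sum


def test_ranksum_exact_worked_example():
    u, p = downstream.rank_sum_test([1, 2], [3, 4], alternative="less")
    assert u == 0.0
    assert p == pytest.approx(1 / 6)


def test_ranksum_identical_groups_two_sided():
    vals = [1.0, 2.0, 3.0]
    _, p = downstream.rank_sum_test(vals, list(vals))
    assert p == pytest.approx(1.0)


def test_ranksum_extreme_separation_large_n():
    a = list(range(1, 51))
    b = list(range(51, 101))
    u, p = downstream.rank_sum_test(a, b, alternative="less")
    assert u == 0.0
    assert p < 1e-10


def test_ranksum_empty_group_errors():
    with pytest.raises(ValueError):
        downstream.rank_sum_test([], [1.0])


@pytest.mark.parametrize("alternative", ["less", "greater", "two-sided"])
def test_ranksum_matches_enumeration_oracle(alternative):
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(3, 11))
        na = int(rng.integers(1, n))
        pooled = rng.permutation(np.arange(1, n + 1)).astype(float)
        a, b = pooled[:na], pooled[na:]
        u, p = downstream.rank_sum_test(a, b, alternative=alternative)
        u_o, p_o = ranksum_enumeration(a, b, alternative=alternative)
        assert u == u_o
        assert p == pytest.approx(p_o, abs=1e-12)


def test_ranksum_normal_approximation_close_to_exact():
    """At nA = nB = 12 without ties the asymptotic p stays within 0.02 of the
    exact p across a sweep of configurations."""
    from scipy import stats

    rng = np.random.default_rng(3)
    for _ in range(25):
        pooled = rng.permutation(np.arange(1, 25)).astype(float)
        a, b = pooled[:12], pooled[12:]
        exact = stats.mannwhitneyu(a, b, method="exact").pvalue
        approx = stats.mannwhitneyu(a, b, method="asymptotic").pvalue
        assert abs(exact - approx) < 0.02


# ---------------------------------------------------------------------------
# clustering


def _expr_matrix(rng, n_features=40, tissues=6, reps=2, noise=0.05):
    cols = [f"t{t}r{r}" for t in range(tissues) for r in range(reps)]
    base = rng.lognormal(0, 1, size=(n_features, tissues))
    data = np.repeat(base, reps, axis=1) * rng.lognormal(0, noise,
                                                         size=(n_features, len(cols)))
    return pd.DataFrame(data, columns=cols,
                        index=[f"f{i}" for i in range(n_features)])


def test_identical_replicates_merge_first_at_height_zero():
    mat = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0],
                        "c": [9.0, 0.0, 4.0]})
    res = downstream.cluster_samples(mat, k=2)
    first = res.linkage[0]
    assert {int(first[0]), int(first[1])} == {0, 1}
    assert first[2] == 0.0
    assert res.groups["a"] == res.groups["b"] != res.groups["c"]


def test_cluster_samples_replicates_coassigned():
    rng = np.random.default_rng(0)
    mat = _expr_matrix(rng)
    res = downstream.cluster_samples(mat, k=6)
    for t in range(6):
        assert res.groups[f"t{t}r0"] == res.groups[f"t{t}r1"]


def test_cluster_samples_permutation_invariance():
    rng = np.random.default_rng(1)
    mat = _expr_matrix(rng, n_features=25)
    res = downstream.cluster_samples(mat, k=6)
    shuffled = mat[rng.permutation(mat.columns)]
    res2 = downstream.cluster_samples(shuffled, k=6)
    groups_a = {frozenset(s for s, g in res.groups.items() if g == gg)
                for gg in set(res.groups.values())}
    groups_b = {frozenset(s for s, g in res2.groups.items() if g == gg)
                for gg in set(res2.groups.values())}
    assert groups_a == groups_b


def test_cluster_samples_determinism():
    rng = np.random.default_rng(2)
    mat = _expr_matrix(rng)
    z1 = downstream.cluster_samples(mat, k=4).linkage
    z2 = downstream.cluster_samples(mat.copy(), k=4).linkage
    assert np.array_equal(z1, z2)


def test_cluster_samples_too_few_columns():
    mat = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
    with pytest.raises(ValueError):
        downstream.cluster_samples(mat, k=3)


def test_cluster_features_recovers_prototypes():
    rng = np.random.default_rng(7)
    prototypes = np.array([[10, 0, 0, 0], [0, 10, 0, 0], [0, 0, 10, 10.0]])
    rows, truth = [], []
    for i in range(30):
        proto = i % 3
        rows.append(prototypes[proto] + rng.normal(0, 0.1, size=4))
        truth.append(proto)
    mat = pd.DataFrame(np.abs(rows), columns=list("abcd"),
                       index=[f"f{i}" for i in range(30)])
    res, means = downstream.cluster_features_into_groups(mat, k=3,
                                                         log_transform=False)
    from sklearn.metrics import adjusted_rand_score

    labels = [res.groups[f"f{i}"] for i in range(30)]
    assert adjusted_rand_score(truth, labels) == 1.0
    assert means.shape[0] == 3


def test_cluster_features_k_one_single_group():
    rng = np.random.default_rng(8)
    mat = _expr_matrix(rng, n_features=10)
    res, _ = downstream.cluster_features_into_groups(mat, k=1)
    assert set(res.groups.values()) == {1}


def test_constant_features_dropped_with_warning():
    mat = pd.DataFrame({"a": [1.0, 3.0], "b": [1.0, 4.0], "c": [1.0, 5.0]},
                       index=["flat", "varying"])
    with pytest.warns(UserWarning, match="zero-variance"):
        res = downstream.cluster_samples(mat, k=2)
    assert res.dropped == ["flat"]


def test_linkage_heights_nondecreasing():
    rng = np.random.default_rng(9)
    mat = _expr_matrix(rng)
    z = downstream.cluster_samples(mat, k=2).linkage
    assert np.all(np.diff(z[:, 2]) >= -1e-12)
    assert hierarchy.is_valid_linkage(z)


# ---------------------------------------------------------------------------
# parent correlation


def test_correlation_identity_and_negation():
    x = [1.0, 4.0, 2.0, 8.0, 5.0]
    r, p = downstream.correlate_with_parent(x, x, n_permutations=200)
    assert r == pytest.approx(1.0)
    assert p < 0.05
    r_neg, _ = downstream.correlate_with_parent(x, [-v for v in x],
                                                n_permutations=200)
    assert r_neg == pytest.approx(-1.0)


def test_correlation_zero_variance_undefined():
    r, p = downstream.correlate_with_parent([1.0, 1.0, 1.0], [1.0, 2.0, 3.0],
                                            n_permutations=200)
    assert np.isnan(r) and np.isnan(p)


def test_correlation_null_p_roughly_uniform():
    rng = np.random.default_rng(11)
    ps = []
    for i in range(60):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        _, p = downstream.correlate_with_parent(x, y, n_permutations=400, seed=i)
        ps.append(p)
    from scipy import stats

    assert stats.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# proportions


@pytest.mark.parametrize(
    "count,total,expected",
    [(2907, 9388, 30.97), (2695, 9388, 28.71), (0, 9388, 0.00)],
)
def test_proportions_printed_arithmetic(count, total, expected):
    table = downstream.summarize_proportions({"x": count, "rest": total - count})
    assert table.set_index("class").at["x", "percent"] == expected


def test_proportions_sum_to_hundred():
    counts = {"a": 123, "b": 456, "c": 789, "d": 1}
    table = downstream.summarize_proportions(counts)
    assert table["percent"].sum() == pytest.approx(100.0, abs=0.05)


def test_proportions_one_decimal_variant_and_errors():
    table = downstream.summarize_proportions({"a": 300, "rest": 9088}, decimals=1)
    assert table.set_index("class").at["a", "percent"] == 3.2
    with pytest.raises(ValueError):
        downstream.summarize_proportions({"a": 0})
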