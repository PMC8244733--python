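"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: the rank-sum
oracle enumerates label assignments, the classifier oracle reasons over
position sets, and the projection oracle walks exons base by base.
"""

from itertools import combinations


def ranksum_enumeration(a, b, alternative="two-sided"):
    """Exact Mann-Whitney p by enumerating every split of the pooled values
    into groups of sizes |a| and |b| (assumes no ties)."""
    a, b = list(a), list(b)
    pooled = a + b
    na = len(a)

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = u_stat(a, b)
    mid = na * (len(pooled) - na) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(ga, gb)
        total += 1
        if alternative == "less":
            count += u <= u_obs
        elif alternative == "greater":
            count += u >= u_obs
        else:
            count += abs(u - mid) >= abs(u_obs - mid)
    return u_obs, count / total


def classify_by_position_sets(start, end, cds):
    """Seven-class label derived from explicit position-set relations."""
    if cds is None:
        return "novel"
    cs, ce = cds
    orf = set(range(start, end))
    cds_set = set(range(cs, ce))
    if orf == cds_set:
        return "annotated"
    overlap = bool(orf & cds_set)
    has_upstream = min(orf) < cs
    has_downstream = max(orf) >= ce
    if not overlap:
        return "uORF" if max(orf) < cs else "dORF"
    if has_upstream:
        return "Overlap_uORF"
    if has_downstream:
        return "Overlap_dORF"
    # nested inside the CDS
    if (min(orf) - cs) % 3 != 0:
        return "Internal"
    return "inframe_nested"


def project_base_by_base(exons_5to3, strand, start, end):
    """Genomic positions of transcript interval [start, end), one base at a
    time; returns a sorted list of genomic coordinates."""
    chain = []
    for gs, ge in exons_5to3:
        positions = range(gs, ge)
        if strand == "-":
            positions = reversed(positions)
        chain.extend(positions)
    return sorted(chain[start:end])
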