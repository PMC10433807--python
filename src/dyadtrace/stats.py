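"""Nonparametric group comparisons used throughout the pipeline.

Kruskal-Wallis with Dunn's post hoc test compares per-dyad transfer counts
across delivery modes or antibiotic-exposure groups; the chi-square test
compares identical/nonidentical strain-call counts across groups; the
Mann-Whitney U test contrasts within- vs between-dyad pairwise genome
distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps


@dataclass
class PairwiseDunn:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float


@dataclass
class GroupComparisonResult:
    groups: list[str]
    n: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]
    median: dict[str, float]
    h_statistic: float
    df: int
    p_omnibus: float
    pairwise: list[PairwiseDunn] = field(default_factory=list)


@dataclass
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    df: int
    p_value: float
    correction: str


@dataclass
class TwoSampleResult:
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int


def _tie_correction_term(all_values: np.ndarray) -> float:
    """Sum of (t^3 - t) over tied groups, used by Dunn's variance."""
    _, counts = np.unique(all_values, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t**3 - t))


def kruskal_dunn(
    values: np.ndarray | list[float],
    groups: np.ndarray | list[str],
    adjust: str = "bonferroni",
) -> GroupComparisonResult:
    """Kruskal-Wallis omnibus test followed by Dunn's pairwise comparisons.

    H uses tie-corrected ranks (scipy). Dunn z statistics use pooled mean
    ranks with the standard tie-corrected variance

        var = (N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j),
        T = sum(t^3 - t) over tied groups,

    and two-sided normal p-values; the default adjustment multiplies each
    raw p by the number of pairwise comparisons (Bonferroni), clipped at 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    samples = {g: values[groups == g] for g in labels}
    for g, v in samples.items():
        if len(v) == 0:
            raise ValueError(f"group {g!r} is empty")

    if np.all(values == values[0]):
        h, p_omni = 0.0, 1.0
    else:
        h, p_omni = sps.kruskal(*[samples[g] for g in labels])

    ranks = sps.rankdata(values)
    n_total = len(values)
    mean_rank = {g: float(ranks[groups == g].mean()) for g in labels}
    tie_term = _tie_correction_term(values)
    m = len(labels) * (len(labels) - 1) // 2
    pairwise = []
    for a, b in combinations(labels, 2):
        na, nb = len(samples[a]), len(samples[b])
        var = (n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))) * (
            1.0 / na + 1.0 / nb
        )
        if var <= 0:
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / np.sqrt(var)
            p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * m) if adjust == "bonferroni" else p_raw
        pairwise.append(PairwiseDunn(a, b, float(z), float(p_raw), float(p_adj)))

    return GroupComparisonResult(
        groups=labels,
        n={g: int(len(samples[g])) for g in labels},
        mean={g: float(samples[g].mean()) for g in labels},
        sd={g: float(samples[g].std(ddof=1)) if len(samples[g]) > 1 else 0.0 for g in labels},
        median={g: float(np.median(samples[g])) for g in labels},
        h_statistic=float(h),
        df=len(labels) - 1,
        p_omnibus=float(p_omni),
        pairwise=pairwise,
    )


def chi_square(
    observed: np.ndarray | list[list[int]], correction: str = "none"
) -> ContingencyResult:
    """Pearson chi-square test of independence on an r x c count table.

    ``correction='yates'`` applies the continuity correction and is defined
    only for 2x2 tables. The default is uncorrected.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("observed must be at least a 2x2 table")
    if (obs < 0).any():
        raise ValueError("negative cell counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero row/column total: expected counts undefined")
    if correction not in ("none", "yates"):
        raise ValueError(f"unknown correction {correction!r}")
    if correction == "yates" and obs.shape != (2, 2):
        raise ValueError("Yates correction is defined only for 2x2 tables")
    chi2, p, dof, expected = sps.chi2_contingency(obs, correction=(correction == "yates"))
    return ContingencyResult(
        observed=obs.astype(int),
        expected=expected,
        statistic=float(chi2),
        df=int(dof),
        p_value=float(p),
        correction=correction,
    )


def mann_whitney(
    sample_a: np.ndarray | list[float], sample_b: np.ndarray | list[float]
) -> TwoSampleResult:
    """Two-sided Mann-Whitney U via the normal approximation with tie correction."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
    return TwoSampleResult(
        u_statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=len(a),
        n_b=len(b),
    )
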