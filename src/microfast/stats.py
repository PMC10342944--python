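"""Cytometric population statistics: blood-volume correction, the study's
three comparisons (one-sided paired t for kinetics, Welch for RA vs MetS,
Wilcoxon signed-rank for joint counts) and per-population significance
profiles with a combined score.

The combined score of a population is the *weakest* (largest) of its three
p-values: a population must differ in every comparison to rank well, which
is what makes it specific to the disease rather than to fasting in general.

The Wilcoxon signed-rank null distribution is computed exactly (dynamic
programming over sign assignments, midranks doubled to stay integral) up
to n = 25 and by normal approximation with continuity and tie correction
above. Paired/Welch t-tests delegate to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateDataError(ValueError):
    """Raised when a test statistic is undefined on the given data."""


@dataclass
class TestResult:
    statistic: float
    df: float | None
    p: float


@dataclass
class PopulationCountTable:
    """Leukocyte population fractions per sample.

    fractions: DataFrame samples x populations (rows sum to <= 1).
    meta: DataFrame indexed by sample_id with donor, group, timepoint,
    leukocyte_count (cells/nL).
    """

    fractions: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.fractions.to_numpy() < -1e-12).any():
            raise ValueError("population fractions must be >= 0")
        if (self.fractions.sum(axis=1) > 1 + 1e-6).any():
            raise ValueError("population fractions must sum to <= 1 per sample")

    def per_volume(self) -> pd.DataFrame:
        """Absolute counts in cells/nL (see per_volume_correction)."""
        return self.fractions.mul(self.meta["leukocyte_count"], axis=0)


def per_volume_correction(fractions, leukocyte_count):
    """Convert leukocyte fractions to cells per blood volume (cells/nL)
    using the donor's actual leukocyte blood count at sampling."""
    return np.asarray(fractions, dtype=float) * np.asarray(
        leukocyte_count, dtype=float
    )


def _clean_pairs(before, after):
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError("before/after must be paired (equal length)")
    keep = ~(np.isnan(b) | np.isnan(a))
    return b[keep], a[keep]


def paired_t_one_sided(before, after, direction: str = "increase") -> TestResult:
    """One-sided paired t-test on after - before.

    direction='increase' tests H1: mean(after) > mean(before);
    'decrease' tests the opposite. Pairs with missing values are dropped.
    A mean difference of zero gives t = 0 and one-sided p = 0.5; exactly
    constant differences (zero variance) are degenerate and raise.
    """
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    b, a = _clean_pairs(before, after)
    if len(b) < 2:
        raise DegenerateDataError("paired t-test needs at least 2 pairs")
    d = a - b
    if np.ptp(d) == 0:
        raise DegenerateDataError("differences have zero variance")
    alt = "greater" if direction == "increase" else "less"
    res = sps.ttest_rel(a, b, alternative=alt)
    return TestResult(float(res.statistic), float(len(b) - 1), float(res.pvalue))


def welch_test(a, b, sides: int = 2, direction: str = "increase") -> TestResult:
    """Welch's unequal-variance t-test between two groups.

    Two-sided by default (sides=2); sides=1 uses `direction` with respect
    to group a (increase: mean(a) > mean(b)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise DegenerateDataError("Welch test needs >= 2 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, float(len(a) + len(b) - 2), 1.0)
        raise DegenerateDataError("both groups constant with unequal means")
    if sides == 2:
        alt = "two-sided"
    else:
        alt = "greater" if direction == "increase" else "less"
    res = sps.ttest_ind(a, b, equal_var=False, alternative=alt)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue))


def _signed_rank_exact_sf(ranks2: np.ndarray, w2: int, tail: str) -> float:
    """Exact tail probability of the signed-rank sum by DP enumeration.

    ranks2 are midranks doubled to integers; w2 the (doubled) observed
    positive-rank sum. Counts sign assignments (2^n equally likely) whose
    positive-rank sum is >= / <= w2.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= 2.0 ** len(ranks2)
    if tail == "ge":
        return float(counts[w2:].sum())
    return float(counts[: w2 + 1].sum())


def wilcoxon_signed_rank(
    before,
    after,
    sides: int = 1,
    direction: str = "increase",
    exact_max_n: int = 25,
) -> TestResult:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped. The statistic is W+ (sum of ranks of
    positive differences of after - before). For n <= exact_max_n the
    p-value is exact (enumeration over sign assignments); above, a normal
    approximation with continuity correction and tie correction is used.
    One-sided by default; direction='increase' tests for after > before.
    """
    b, a = _clean_pairs(before, after)
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.round(2 * ranks).astype(np.int64)
        w2 = int(round(2 * w_plus))
        p_ge = _signed_rank_exact_sf(ranks2, w2, "ge")
        p_le = _signed_rank_exact_sf(ranks2, w2, "le")
    else:
        mu = n * (n + 1) / 4.0
        tie_term = 0.0
        _, t_counts = np.unique(ranks, return_counts=True)
        tie_term = ((t_counts**3 - t_counts).sum()) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        p_ge = float(sps.norm.sf((w_plus - mu - 0.5) / sigma))
        p_le = float(sps.norm.cdf((w_plus - mu + 0.5) / sigma))
    if sides == 2:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    elif direction == "increase":
        p = p_ge
    else:
        p = p_le
    return TestResult(w_plus, None, float(min(p, 1.0)))


def _paired_series(
    values: pd.Series, meta: pd.DataFrame, group: str, tp0: str, tp1: str
):
    """Donor-matched value pairs for one population; incomplete pairs are
    dropped."""
    sub = meta[meta["group"] == group]
    piv = (
        pd.DataFrame({"value": values.loc[sub.index], "donor": sub["donor"],
                      "timepoint": sub["timepoint"]})
        .pivot_table(index="donor", columns="timepoint", values="value")
    )
    if tp0 not in piv.columns or tp1 not in piv.columns:
        raise DegenerateDataError(f"missing timepoint {tp0}/{tp1} for group {group}")
    piv = piv[[tp0, tp1]].dropna()
    return piv[tp0].to_numpy(), piv[tp1].to_numpy()


def significance_profile(
    table: PopulationCountTable,
    alpha: float = 0.05,
    direction: str = "increase",
    value: str = "fraction",
    case_group: str = "RA",
    control_group: str = "MetS",
) -> pd.DataFrame:
    """Per-population significance profile and combined score.

    For every population: one-sided paired t in the case group between T0
    and T1 and between T0 and T2 (declared `direction`), Welch test
    (two-sided) case vs control at T0, -log10 transforms, significance
    flags at `alpha`, and the combined score = max of the three p-values
    (the weakest comparison). Rows are sorted by ascending combined score.

    value='per_volume' runs the profile on blood-volume-corrected counts.
    """
    data = table.per_volume() if value == "per_volume" else table.fractions
    meta = table.meta
    t0_mask = (meta["timepoint"] == "T0")
    case_t0 = meta.index[t0_mask & (meta["group"] == case_group)]
    ctrl_t0 = meta.index[t0_mask & (meta["group"] == control_group)]
    rows = []
    for pop in data.columns:
        values = data[pop]
        ps = {}
        for tp, key in (("T1", "p_t0_t1"), ("T2", "p_t0_t2")):
            b, a = _paired_series(values, meta, case_group, "T0", tp)
            try:
                ps[key] = paired_t_one_sided(b, a, direction=direction).p
            except DegenerateDataError:
                ps[key] = 1.0
        try:
            ps["p_welch_t0"] = welch_test(
                values.loc[case_t0], values.loc[ctrl_t0], sides=2
            ).p
        except DegenerateDataError:
            ps["p_welch_t0"] = 1.0
        combined = max(ps.values())
        rows.append(
            {
                "population_id": pop,
                **ps,
                "neglog10_t0_t1": -np.log10(ps["p_t0_t1"]),
                "neglog10_t0_t2": -np.log10(ps["p_t0_t2"]),
                "neglog10_welch_t0": -np.log10(ps["p_welch_t0"]),
                "n_significant": sum(p < alpha for p in ps.values()),
                "combined_score": combined,
                "neglog10_combined": -np.log10(combined),
            }
        )
    profile = pd.DataFrame(rows).set_index("population_id")
    profile = profile.sort_values("combined_score", kind="stable")
    profile["rank"] = np.arange(1, len(profile) + 1)
    return profile


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted q-values (optional; the default profiles report raw p)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = np.minimum(q, 1.0)
    return out
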