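"""Nonparametric statistical battery for the quarter-wise BV/TV comparisons.

The study-level analysis compares adjacent tube quarters and positionally
corresponding straight-vs-bent quarters with Mann-Whitney U tests, sides and
sexes with Kruskal-Wallis ANOVA, screens every group for normality with a
Monte-Carlo Lilliefors Kolmogorov-Smirnov test (plus Shapiro-Wilk), and
reports right-left bivariate correlations per design and region.  All tests
are two-sided; p-values are reported raw (no multiplicity correction), with
an optional Holm adjustment available.

The Mann-Whitney U statistic counts ``#{(i,j): x_i > y_j} + 0.5 #ties``.
Exact p-values come from full enumeration of the C(n+m, n) group labelings
(mid-ranks under ties); the asymptotic path uses the normal approximation
with tie-corrected variance and continuity correction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

EXACT_ENUMERATION_LIMIT = 16  # max n+m for the auto exact path


class StatsError(RuntimeError):
    pass


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    method: str  # exact | asymptotic | monte_carlo
    n_per_group: tuple[int, ...]
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise StatsError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


@lru_cache(maxsize=64)
def _exact_u_distribution_no_ties(n: int, m: int) -> np.ndarray:
    """Counts of labelings per U value (index = 2*U, no ties -> U integral)
    by enumeration of rank-position subsets."""
    counts = np.zeros(n * m + 1, dtype=np.int64)
    ranks = range(n + m)
    for combo in itertools.combinations(ranks, n):
        # U = sum of (rank position) - number of x's below each = #pairs x>y
        u = sum(combo) - n * (n - 1) // 2
        counts[u] += 1
    return counts


def _exact_p_from_counts(counts: np.ndarray, u: float, nm: int,
                         alternative: str) -> float:
    total = counts.sum()
    support = np.arange(counts.size, dtype=float)
    eps = 1e-9
    if alternative == "two_sided":
        dev = np.abs(support - nm / 2.0)
        mass = counts[dev >= abs(u - nm / 2.0) - eps].sum()
    elif alternative == "greater":
        mass = counts[support >= u - eps].sum()
    elif alternative == "less":
        mass = counts[support <= u + eps].sum()
    else:
        raise StatsError(f"unknown alternative '{alternative}'")
    return float(mass) / float(total)


def _exact_u_counts_with_ties(pooled: np.ndarray, n: int) -> np.ndarray:
    """Enumerate every labeling of the pooled values; U can be half-integral
    under ties, so counts are indexed by 2*U."""
    nm = n * (pooled.size - n)
    counts = np.zeros(2 * nm + 1, dtype=np.int64)
    idx = np.arange(pooled.size)
    for combo in itertools.combinations(idx, n):
        xsel = np.zeros(pooled.size, dtype=bool)
        xsel[list(combo)] = True
        u = _u_statistic(pooled[xsel], pooled[~xsel])
        counts[int(round(2 * u))] += 1
    return counts


def mann_whitney_u(x, y, alternative: str = "two_sided",
                   method: str = "auto", continuity: bool = True
                   ) -> TestResult:
    """Mann-Whitney U test of two independent samples.

    ``method='auto'`` enumerates exactly when ``n + m <= 16`` and otherwise
    uses the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise StatsError("samples must be non-empty")
    if alternative not in ("two_sided", "less", "greater"):
        raise StatsError(f"unknown alternative '{alternative}'")
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size

    if method == "auto":
        method = "exact" if n + m <= EXACT_ENUMERATION_LIMIT else "asymptotic"
    if method == "exact" and n + m > 2 * EXACT_ENUMERATION_LIMIT:
        raise StatsError("exact enumeration infeasible for this sample size")

    if method == "exact":
        if has_ties:
            counts2 = _exact_u_counts_with_ties(pooled, n)
            # index = 2U; deviations measured on the 2U scale
            support = np.arange(counts2.size, dtype=float)
            eps = 1e-9
            if alternative == "two_sided":
                dev = np.abs(support - n * m)
                mass = counts2[dev >= abs(2 * u - n * m) - eps].sum()
            elif alternative == "greater":
                mass = counts2[support >= 2 * u - eps].sum()
            else:
                mass = counts2[support <= 2 * u + eps].sum()
            p = float(mass) / float(counts2.sum())
        else:
            counts = _exact_u_distribution_no_ties(n, m)
            p = _exact_p_from_counts(counts, u, n * m, alternative)
    elif method == "asymptotic":
        mean = n * m / 2.0
        tie_counts = np.unique(pooled, return_counts=True)[1]
        npool = n + m
        tie_term = ((tie_counts ** 3 - tie_counts).sum()
                    / (npool * (npool - 1.0))) if npool > 1 else 0.0
        var = n * m / 12.0 * ((npool + 1.0) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            sd = np.sqrt(var)
            cc = 0.5 if continuity else 0.0
            if alternative == "two_sided":
                z = (abs(u - mean) - cc) / sd
                p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
            elif alternative == "greater":
                z = (u - mean - cc) / sd
                p = float(sps.norm.sf(z))
            else:
                z = (u - mean + cc) / sd
                p = float(sps.norm.cdf(z))
    else:
        raise StatsError(f"unknown method '{method}'")

    return TestResult("mann_whitney_u", u, p, method, (n, m),
                      {"alternative": alternative, "ties": bool(has_ties)})


# ---------------------------------------------------------------------------
# Kruskal-Wallis, correlation, normality
# ---------------------------------------------------------------------------

def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis rank ANOVA (mid-ranks, tie corrected, chi-square p)."""
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise StatsError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise StatsError("groups must be non-empty")
    total_n = sum(g.size for g in groups)
    if total_n < 3:
        raise StatsError("need total N >= 3")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        return TestResult("kruskal_wallis", 0.0, 1.0, "asymptotic",
                          tuple(g.size for g in groups))
    h, p = sps.kruskal(*groups)
    return TestResult("kruskal_wallis", float(h), float(p), "asymptotic",
                      tuple(g.size for g in groups))


def correlation(x, y, kind: str = "pearson") -> TestResult:
    """Bivariate correlation of paired samples (Pearson or Spearman), with a
    two-sided p from the t transform on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise StatsError("paired samples must have equal length")
    if x.size < 3:
        raise StatsError("need n >= 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("zero variance sample")
    if kind == "pearson":
        r, p = sps.pearsonr(x, y)
    elif kind == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise StatsError(f"unknown correlation kind '{kind}'")
    return TestResult(f"correlation_{kind}", float(r), float(p),
                      "asymptotic", (x.size,))


def _lilliefors_d(sample: np.ndarray) -> float:
    n = sample.size
    z = np.sort((sample - sample.mean()) / sample.std(ddof=1))
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    return float(max((i / n - cdf).max(), (cdf - (i - 1) / n).max()))


def lilliefors_normality(x, n_mc: int = 2000,
                         seed: int | np.random.Generator = 0) -> TestResult:
    """Kolmogorov-Smirnov normality test with Lilliefors' correction.

    D is the sup-distance between the empirical CDF and the normal CDF with
    mean and SD estimated from the sample; the p-value is the Monte-Carlo
    proportion of standard-normal samples of the same size (with
    re-estimated parameters, the Lilliefors null) whose D* >= D.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 4:
        raise StatsError("Lilliefors test needs n >= 4")
    if np.std(x) == 0:
        raise StatsError("zero variance sample")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    d_obs = _lilliefors_d(x)

    sims = rng.standard_normal((n_mc, n))
    sims = (sims - sims.mean(axis=1, keepdims=True)) \
        / sims.std(axis=1, ddof=1, keepdims=True)
    sims.sort(axis=1)
    cdf = sps.norm.cdf(sims)
    i = np.arange(1, n + 1)
    d_star = np.maximum((i / n - cdf).max(axis=1),
                        (cdf - (i - 1) / n).max(axis=1))
    p = float((1 + (d_star >= d_obs).sum()) / (n_mc + 1))
    return TestResult("lilliefors_ks", d_obs, p, "monte_carlo", (n,),
                      {"n_mc": n_mc})


def shapiro_wilk(x) -> TestResult:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise StatsError("Shapiro-Wilk needs n >= 3")
    w, p = sps.shapiro(x)
    return TestResult("shapiro_wilk", float(w), float(p), "asymptotic",
                      (x.size,))


def holm_adjust(pvalues: dict[str, float]) -> dict[str, float]:
    """Holm step-down adjustment (optional; off by default in reports)."""
    items = sorted(pvalues.items(), key=lambda kv: kv[1])
    k = len(items)
    adjusted, running = {}, 0.0
    for rank, (key, p) in enumerate(items):
        running = max(running, min(1.0, (k - rank) * p))
        adjusted[key] = running
    return adjusted


# ---------------------------------------------------------------------------
# study-level report
# ---------------------------------------------------------------------------

REGIONS = ("all", "q1", "q2", "q3", "q4")
ADJACENT = (("q1", "q2"), ("q2", "q3"), ("q3", "q4"))


@dataclass
class StatsReport:
    """All comparisons of the study design, assembled from morphometry rows."""

    adjacent_quarter_tests: dict  # (design, 'q1_vs_q2') -> TestResult
    design_tests: dict            # region -> TestResult (straight vs bent)
    side_test: dict               # design -> TestResult
    sex_test: dict                # design -> TestResult
    side_correlations: dict       # (design, region) -> TestResult | None
    normality_screen: dict        # (design, region) -> {test_name: TestResult}
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def enc(tr):
            if tr is None:
                return None
            return {"test": tr.test_name, "statistic": tr.statistic,
                    "p_value": tr.p_value, "method": tr.method,
                    "n_per_group": list(tr.n_per_group), **tr.extras}

        return {
            "adjacent_quarter_tests": {
                f"{d}:{k}": enc(v)
                for (d, k), v in self.adjacent_quarter_tests.items()},
            "design_tests": {k: enc(v) for k, v in self.design_tests.items()},
            "side_test": {k: enc(v) for k, v in self.side_test.items()},
            "sex_test": {k: enc(v) for k, v in self.sex_test.items()},
            "side_correlations": {
                f"{d}:{r}": enc(v)
                for (d, r), v in self.side_correlations.items()},
            "normality_screen": {
                f"{d}:{r}": {name: enc(tr) for name, tr in tests.items()}
                for (d, r), tests in self.normality_screen.items()},
            "notes": list(self.notes),
        }

    def correlation_table(self) -> pd.DataFrame:
        """Right-left correlation grid: rows all-VOI and quarters 1-4,
        columns straight and bent."""
        rows = []
        for region in REGIONS:
            row = {"region": region}
            for design in ("straight", "bent"):
                tr = self.side_correlations.get((design, region))
                row[design] = tr.statistic if tr is not None else np.nan
                row[f"{design}_p"] = tr.p_value if tr is not None else np.nan
            rows.append(row)
        return pd.DataFrame(rows)


def build_stats_report(results: pd.DataFrame, manifest: pd.DataFrame,
                       correlation_kind: str = "pearson",
                       n_mc: int = 2000, seed: int = 0) -> StatsReport:
    """Assemble every comparison of the study from tidy morphometry rows.

    ``results`` needs columns specimen_id, design, region, bvtv; ``manifest``
    needs specimen_id, donor_id, side, sex.  Side analyses use complete
    left/right donor pairs only; unpaired specimens are excluded and logged.
    """
    df = results.merge(
        manifest[["specimen_id", "donor_id", "side", "sex"]],
        on="specimen_id", validate="many_to_one").sort_values(
            ["design", "region", "specimen_id"], kind="mergesort")
    notes: list[str] = []
    rng = np.random.default_rng(seed)
    designs = sorted(df["design"].unique())

    def sample(design, region, **sel):
        q = df[(df["design"] == design) & (df["region"] == region)]
        for k, v in sel.items():
            q = q[q[k] == v]
        return q["bvtv"].to_numpy()

    adjacent = {}
    for design in designs:
        for a, b in ADJACENT:
            adjacent[(design, f"{a}_vs_{b}")] = mann_whitney_u(
                sample(design, a), sample(design, b))

    design_tests = {}
    if {"straight", "bent"} <= set(designs):
        for region in REGIONS:
            design_tests[region] = mann_whitney_u(
                sample("straight", region), sample("bent", region))

    # donors with both sides present; the unilateral specimen is excluded
    side_counts = manifest.groupby("donor_id")["side"].nunique()
    paired_donors = set(side_counts[side_counts == 2].index)
    unpaired = sorted(set(manifest["donor_id"]) - paired_donors)
    if unpaired:
        notes.append(f"side analyses exclude unpaired donor(s): "
                     f"{', '.join(map(str, unpaired))}")
        logger.info("excluding unpaired donors from side analyses: %s",
                    unpaired)

    side_test, sex_test, side_corr = {}, {}, {}
    for design in designs:
        whole = df[(df["design"] == design) & (df["region"] == "all")]
        paired_whole = whole[whole["donor_id"].isin(paired_donors)]
        groups = [paired_whole[paired_whole["side"] == s]["bvtv"].to_numpy()
                  for s in ("left", "right")]
        if all(g.size >= 1 for g in groups) and sum(g.size for g in groups) >= 3:
            side_test[design] = kruskal_wallis(groups)
        sexes = [whole[whole["sex"] == s]["bvtv"].to_numpy()
                 for s in ("m", "f")]
        if all(g.size >= 1 for g in sexes) and sum(g.size for g in sexes) >= 3:
            sex_test[design] = kruskal_wallis(sexes)

        for region in REGIONS:
            sub = df[(df["design"] == design) & (df["region"] == region)
                     & df["donor_id"].isin(paired_donors)]
            wide = sub.pivot_table(index="donor_id", columns="side",
                                   values="bvtv")
            wide = wide.dropna()
            if len(wide) >= 3 and {"left", "right"} <= set(wide.columns):
                side_corr[(design, region)] = correlation(
                    wide["left"], wide["right"], kind=correlation_kind)
            else:
                side_corr[(design, region)] = None
                notes.append(f"no complete pairs for correlation "
                             f"{design}:{region}")

    normality = {}
    for design in designs:
        for region in REGIONS:
            vals = sample(design, region)
            tests = {}
            if vals.size >= 4 and np.std(vals) > 0:
                tests["lilliefors_ks"] = lilliefors_normality(
                    vals, n_mc=n_mc, seed=rng)
                tests["shapiro_wilk"] = shapiro_wilk(vals)
            normality[(design, region)] = tests

    return StatsReport(adjacent_quarter_tests=adjacent,
                       design_tests=design_tests, side_test=side_test,
                       sex_test=sex_test, side_correlations=side_corr,
                       normality_screen=normality, notes=notes)
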