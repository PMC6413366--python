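"""Cohort-level statistics: association, two-sample, normality and survival.

Thin, typed wrappers over scipy.stats and lifelines, with two additions of
note: contingency tests report both the Pearson and likelihood-ratio (G)
chi-square (statistics packages print both, and published p-values may quote
either), and a self-contained Cox partial-likelihood *score* test is provided
because it is the exact algebraic twin of the log-rank test for a binary
covariate without ties — a useful cross-check that the survival machinery is
wired correctly.

Age at diagnosis serves as the survival time with all events observed (the
study design euthanizes at diagnosis); censoring support is retained for
generality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "TestResult",
    "KMResult",
    "contingency_test",
    "welch_t_test",
    "normality_check",
    "km_estimate",
    "log_rank_test",
    "cox_ph",
    "cox_score_test",
    "build_tables",
    "display_pct",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    dof: float
    p_value: float
    method: str
    n: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        assert 0.0 <= self.p_value <= 1.0


@dataclass
class KMResult:
    """Product-limit survival estimate."""

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    median: float | None

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def contingency_test(table, method: str = "pearson") -> TestResult:
    """Chi-square test of independence on an r x c count table.

    ``method`` is ``pearson`` (X^2) or ``likelihood_ratio`` (G = 2*sum O ln(O/E));
    no continuity correction in either case.  Both variants' statistics are
    carried in ``extra`` regardless of which is primary.
    """
    table = np.asarray(table, float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal total in contingency table")
    if method not in ("pearson", "likelihood_ratio"):
        raise ValueError(f"unknown method {method!r}")
    pearson = stats.chi2_contingency(table, correction=False)
    lr = stats.chi2_contingency(table, correction=False, lambda_="log-likelihood")
    chosen = pearson if method == "pearson" else lr
    return TestResult(
        statistic=float(chosen.statistic),
        dof=int(chosen.dof),
        p_value=float(chosen.pvalue),
        method=f"chi-square ({method})",
        n=int(table.sum()),
        extra={
            "pearson_statistic": float(pearson.statistic),
            "pearson_p": float(pearson.pvalue),
            "likelihood_ratio_statistic": float(lr.statistic),
            "likelihood_ratio_p": float(lr.pvalue),
        },
    )


def permutation_contingency_p(
    table, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Monte-Carlo permutation p for a 2x2 table's Pearson statistic.

    Conditions on both margins: under label permutation the top-left cell is
    hypergeometric, so the null is sampled directly.  Suited to tables too
    small for the asymptotic chi-square reference distribution.
    """
    table = np.asarray(table, float)
    if table.shape != (2, 2):
        raise ValueError("permutation method supports 2x2 tables")
    r1, r2 = table.sum(axis=1)
    c1, _ = table.sum(axis=0)
    n = table.sum()

    def pearson(a):
        t = np.stack(
            [np.stack([a, r1 - a], -1), np.stack([c1 - a, r2 - c1 + a], -1)], 1
        )
        e = np.outer([r1, r2], [c1, n - c1]) / n
        return ((t - e) ** 2 / e).sum(axis=(1, 2))

    obs = float(pearson(np.array([table[0, 0]]))[0])
    rng = np.random.default_rng(seed)
    draws = rng.hypergeometric(r1, r2, c1, size=n_perm).astype(float)
    return float(np.mean(pearson(draws) >= obs - 1e-12))


def welch_t_test(x, y) -> TestResult:
    """Two-sided t-test corrected for unequal variances (Welch/Satterthwaite)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.allclose(x.mean(), y.mean()):
            return TestResult(0.0, float(len(x) + len(y) - 2), 1.0,
                              "Welch t-test", len(x) + len(y))
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        dof=float(res.df),
        p_value=float(res.pvalue),
        method="Welch t-test",
        n=len(x) + len(y),
    )


def normality_check(x) -> TestResult:
    """Shapiro-Wilk W test of normality (scipy's approximation to p)."""
    x = np.asarray(x, float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("sample is constant; normality test undefined")
    w, p = stats.shapiro(x)
    return TestResult(float(w), len(x) - 1, float(p), "Shapiro-Wilk W", len(x))


def km_estimate(times, events=None) -> KMResult:
    """Kaplan-Meier product-limit estimate; events default to all observed.

    The median is the smallest time with S(t) <= 0.5, None when the curve
    never reaches 0.5.
    """
    times = np.asarray(times, float)
    if len(times) == 0:
        raise ValueError("empty sample")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    events = np.ones(len(times), bool) if events is None else np.asarray(events, bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index else kmf.event_table
    t = table.index.to_numpy(float)
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index).to_numpy(float)
    median = kmf.median_survival_time_
    return KMResult(
        times=t,
        at_risk=table["at_risk"].to_numpy(int),
        events=table["observed"].to_numpy(int),
        survival=surv,
        median=None if np.isinf(median) else float(median),
    )


def log_rank_test(groups) -> TestResult:
    """Log-rank test across >= 2 groups of (times, events) tuples."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for i, g in enumerate(groups):
        t, e = (g if isinstance(g, tuple) else (g, None))
        t = np.asarray(t, float)
        e = np.ones(len(t), bool) if e is None else np.asarray(e, bool)
        times.append(t)
        events.append(e)
        labels.append(np.full(len(t), i))
    times = np.concatenate(times)
    events = np.concatenate(events)
    labels = np.concatenate(labels)
    if events.sum() == 0:
        raise ValueError("no events observed in any group")
    res = multivariate_logrank_test(times, labels, events)
    return TestResult(
        statistic=float(res.test_statistic),
        dof=int(res.degrees_of_freedom),
        p_value=float(res.p_value),
        method="log-rank",
        n=len(times),
    )


def cox_score_test(times, events, group) -> TestResult:
    """Partial-likelihood score test at beta = 0 for one binary covariate.

    Without tied event times this equals the log-rank chi-square exactly
    (Breslow tie handling reduces to the same sums).  Self-contained
    implementation used as an independent cross-check of the survival stack.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    x = np.asarray(group, float)
    order = np.argsort(times, kind="stable")
    times, events, x = times[order], events[order], x[order]
    u = 0.0
    v = 0.0
    n = len(times)
    for i in range(n):
        if not events[i]:
            continue
        at_risk = times >= times[i]
        m = at_risk.sum()
        xbar = x[at_risk].mean()
        u += x[i] - xbar
        v += np.sum((x[at_risk] - xbar) ** 2) / m
    if v == 0:
        raise ValueError("score-test variance is zero (degenerate grouping)")
    stat = u * u / v
    return TestResult(
        statistic=float(stat),
        dof=1,
        p_value=float(stats.chi2.sf(stat, 1)),
        method="Cox score test",
        n=n,
    )


def cox_ph(
    records: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "age_months",
    event_col: str = "event",
    ties: str = "efron",
) -> pd.DataFrame:
    """Cox proportional-hazards fit; returns per-covariate log-HR, HR, SE, p.

    ``records`` must already carry numeric covariate columns (dummy-code
    categoricals upstream).  Efron tie handling by default.
    """
    df = records[[duration_col, event_col] + covariates].copy()
    if df[event_col].sum() == 0:
        raise ValueError("no observed events; Cox model cannot be fit")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    out = cph.summary[["coef", "exp(coef)", "se(coef)", "z", "p"]].copy()
    out.columns = ["log_hr", "hr", "se", "z", "p"]
    out.attrs["log_likelihood_ratio_p"] = float(
        cph.log_likelihood_ratio_test().p_value
    )
    return out


# ---------------------------------------------------------------------------
# Summary tables
# ---------------------------------------------------------------------------

def display_pct(count: int, total: int) -> int:
    """Percentage rounded to integer, half away from zero (display convention)."""
    if total == 0:
        return 0
    return int(np.floor(100.0 * count / total + 0.5))


def build_tables(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Study-population and ploidy summary tables.

    ``records`` columns: fish_id, genotype, sex, location, age_months, event,
    ploidy_category.  Returns ``population`` (counts, ages, locations by
    genotype), ``ploidy_by_genotype`` and ``ploidy_by_sex`` (diploid/aneuploid
    counts with integer display percentages and aneuploid subtypes; the
    by-sex table pools genotypes and drops undetermined sex), and
    ``ploidy_by_location`` (per genotype, coelomic/ocular/other breakdown).
    """
    required = {"fish_id", "genotype", "sex", "location", "age_months",
                "ploidy_category"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
    genotypes = sorted(records["genotype"].unique())

    def ploidy_block(df: pd.DataFrame) -> dict:
        n = len(df)
        aneu = df["ploidy_category"] != "diploid"
        block = {
            "n": n,
            "diploid_n": int((~aneu).sum()),
            "diploid_pct": display_pct(int((~aneu).sum()), n),
            "aneuploid_n": int(aneu.sum()),
            "aneuploid_pct": display_pct(int(aneu.sum()), n),
        }
        for sub in ("hypodiploid_aneuploid", "hyperdiploid_aneuploid",
                    "tetraploid_aneuploid", "complex_aneuploid"):
            block[sub] = int((df["ploidy_category"] == sub).sum())
        return block

    pop_rows = []
    for g in genotypes:
        df = records[records["genotype"] == g]
        fish = df.drop_duplicates("fish_id")
        ages = fish["age_months"]
        row = {
            "genotype": g,
            "n_fish": len(fish),
            "n_tumors": len(df),
            "males": int((fish["sex"] == "M").sum()),
            "females": int((fish["sex"] == "F").sum()),
            "sex_undetermined": int((~fish["sex"].isin(["M", "F"])).sum()),
            "median_age": float(ages.median()) if len(fish) else np.nan,
            "age_min": float(ages.min()) if len(fish) else np.nan,
            "age_max": float(ages.max()) if len(fish) else np.nan,
        }
        for loc in ("coelom", "ocular", "other"):
            cnt = int((df["location"] == loc).sum())
            row[f"{loc}_n"] = cnt
            row[f"{loc}_pct"] = display_pct(cnt, len(df))
        pop_rows.append(row)
    population = pd.DataFrame(pop_rows).set_index("genotype") if pop_rows else (
        pd.DataFrame()
    )

    ploidy_by_genotype = pd.DataFrame(
        {g: ploidy_block(records[records["genotype"] == g]) for g in genotypes}
    ).T
    sexed = records[records["sex"].isin(["F", "M"])]
    ploidy_by_sex = pd.DataFrame(
        {s: ploidy_block(sexed[sexed["sex"] == s]) for s in ("F", "M")}
    ).T

    loc_rows = []
    for g in genotypes:
        for loc in ("coelom", "ocular", "other"):
            df = records[(records["genotype"] == g) & (records["location"] == loc)]
            if len(df) == 0:
                continue
            loc_rows.append({"genotype": g, "location": loc, **ploidy_block(df)})
    ploidy_by_location = pd.DataFrame(loc_rows)

    return {
        "population": population,
        "ploidy_by_genotype": ploidy_by_genotype,
        "ploidy_by_sex": ploidy_by_sex,
        "ploidy_by_location": ploidy_by_location,
    }
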