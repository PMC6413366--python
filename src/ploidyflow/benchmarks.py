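"""Seeded end-to-end benchmarks: parameter recovery, classification accuracy,
preset profile conformance, and statistical calibration.

Each function regenerates its inputs from a seed, runs the relevant pipeline
stage, and returns summary numbers.  Problem sizes follow the package's
standard evaluation settings: 10,000 events per specimen (a typical
acquisition target), 100 one-cycle simulations for recovery, 200 matched
pairs across five DNA-index levels for classification, and 10,000 replicates
for test-size calibration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cellcycle import fit_cell_cycle, make_histogram
from .cohort import (
    build_tables,
    contingency_test,
    cox_score_test,
    km_estimate,
    log_rank_test,
    permutation_contingency_p,
    welch_t_test,
)
from .datasets import GENOTYPE_PLOIDY_TABLE, SEX_PLOIDY_TABLE, study_cohort
from .gating import GateConfig, gate_debris, gate_singlets, place_markers, quantify_compartments
from .ploidy import call_from_events
from .simulate import (
    PopulationSpec,
    SimulationSpec,
    TESTIS_COMPARTMENTS,
    compartment_fractions,
    simulate_events,
    simulate_pair,
    testis_preset,
)

__all__ = [
    "cohort_table_percentages",
    "chi_square_reproduction",
    "cellcycle_recovery",
    "ploidy_classification",
    "testis_profiles",
    "statistical_calibration",
]

DI_LEVELS = (0.85, 1.0, 1.2, 1.5, 2.0)
EXPECTED_CATEGORY = {
    0.85: "hypodiploid_aneuploid",
    1.0: "diploid",
    1.2: "hyperdiploid_aneuploid",
    1.5: "hyperdiploid_aneuploid",
    2.0: "tetraploid_aneuploid",
}


def cohort_table_percentages() -> dict[str, float]:
    """Diploid/aneuploid display percentages from the reconstructed cohort."""
    tables = build_tables(study_cohort())
    bg = tables["ploidy_by_genotype"]
    bs = tables["ploidy_by_sex"]
    loc = tables["ploidy_by_location"]
    coel = loc[loc["location"] == "coelom"].set_index("genotype")
    return {
        "diploid_pct_brca2": float(bg.loc["brca2_tp53", "diploid_pct"]),
        "aneuploid_pct_brca2": float(bg.loc["brca2_tp53", "aneuploid_pct"]),
        "diploid_pct_tp53": float(bg.loc["tp53", "diploid_pct"]),
        "aneuploid_pct_tp53": float(bg.loc["tp53", "aneuploid_pct"]),
        "diploid_pct_female": float(bs.loc["F", "diploid_pct"]),
        "aneuploid_pct_female": float(bs.loc["F", "aneuploid_pct"]),
        "diploid_pct_male": float(bs.loc["M", "diploid_pct"]),
        "aneuploid_pct_male": float(bs.loc["M", "aneuploid_pct"]),
        "coelomic_aneuploid_pct_brca2": float(
            coel.loc["brca2_tp53", "aneuploid_pct"]
        ),
        "coelomic_aneuploid_pct_tp53": float(coel.loc["tp53", "aneuploid_pct"]),
        "n_tumors": 103,
    }


def chi_square_reproduction() -> dict[str, float]:
    """Both chi-square variants on the published genotype- and sex-by-ploidy tables."""
    gp = contingency_test(GENOTYPE_PLOIDY_TABLE)
    sp = contingency_test(SEX_PLOIDY_TABLE)
    return {
        "genotype_ploidy_p_pearson": gp.extra["pearson_p"],
        "genotype_ploidy_p_likelihood_ratio": gp.extra["likelihood_ratio_p"],
        "sex_ploidy_p_pearson": sp.extra["pearson_p"],
        "sex_ploidy_p_likelihood_ratio": sp.extra["likelihood_ratio_p"],
    }


def cellcycle_recovery(n_sims: int = 100, seed: int = 0, n_events: int = 10_000):
    """One-cycle recovery study: CV 3-5%, debris 0-15%, known phase mix.

    Returns median absolute errors: G1/S/G2M fractions in percentage points,
    the G0/G1 peak position in percent, and the debris fraction in points.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 101)))
    err = {"g1_pp": [], "s_pp": [], "g2m_pp": [], "mu_pct": [], "debris_pp": [],
           "cv_pp": []}
    for _ in range(n_sims):
        cv = rng.uniform(3.0, 5.0)
        debris = rng.uniform(0.0, 0.15)
        g1 = rng.uniform(0.6, 0.85)
        s = rng.uniform(0.05, min(0.2, 0.95 - g1))
        g2m = 1.0 - g1 - s
        spec = SimulationSpec(
            populations=(PopulationSpec(1.0, 1.0, cv, g1, s, g2m),),
            n_events=n_events,
            debris_fraction=debris,
            seed=int(rng.integers(2**31)),
        )
        fit = fit_cell_cycle(make_histogram(simulate_events(spec), bins=512), 1)
        c = fit.cycles[0]
        err["g1_pp"].append(abs(c.frac_g1 - g1) * 100)
        err["s_pp"].append(abs(c.frac_s - s) * 100)
        err["g2m_pp"].append(abs(c.frac_g2m - g2m) * 100)
        err["mu_pct"].append(abs(c.mu_g1 / spec.diploid_channel - 1.0) * 100)
        err["debris_pp"].append(abs(fit.debris_fraction - debris) * 100)
        err["cv_pp"].append(abs(c.cv_g1 - cv))
    return {f"median_abs_err_{k}": float(np.median(v)) for k, v in err.items()}


def ploidy_classification(n_pairs: int = 200, seed: int = 0,
                          n_events: int = 10_000):
    """DNA-index recovery and category accuracy over matched pairs.

    Pairs span DNA index {0.85, 1.0, 1.2, 1.5, 2.0} (equal numbers), CV 3-5%,
    aneuploid share 0.35-0.8 (single population at index 1.0).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 202)))
    n_per = n_pairs // len(DI_LEVELS)
    di_ok = 0
    di_defined = 0
    cat_ok = 0
    total = 0
    for di in DI_LEVELS:
        for _ in range(n_per):
            cv = float(rng.uniform(3.0, 5.0))
            share = 1.0 if di == 1.0 else float(rng.uniform(0.35, 0.8))
            tumor, somatic = simulate_pair(
                di, seed=int(rng.integers(2**31)), cv_pct=cv,
                aneuploid_share=share, n_events=n_events,
            )
            call = call_from_events(tumor, somatic)
            total += 1
            if call.category == EXPECTED_CATEGORY[di]:
                cat_ok += 1
            if call.dna_index is not None:
                di_defined += 1
                if abs(call.dna_index - di) <= 0.02:
                    di_ok += 1
    return {
        "category_accuracy_pct": 100.0 * cat_ok / total,
        "di_within_0p02_pct": 100.0 * di_ok / max(di_defined, 1),
        "n_pairs": total,
    }


def testis_profiles(seed: int = 0, n_events: int = 10_000):
    """Marker-gate compartment percentages for each testis genotype preset.

    The 2C anchor for marker placement is the known diploid channel for the
    meiotically arrested genotypes (whose profiles lack the 1C/2C pair that
    automatic placement keys on) and automatic for the others.
    """
    out = {}
    gc = GateConfig()
    for i, genotype in enumerate(sorted(TESTIS_COMPARTMENTS)):
        spec = testis_preset(genotype, n_events=n_events, seed=seed + i)
        events = simulate_events(spec, sample_id=genotype)
        gated = gate_debris(gate_singlets(events, gc), gc)
        hist = make_histogram(gated, bins=512)
        anchor = None if genotype in ("wild_type", "tp53") else spec.diploid_channel
        markers = place_markers(hist, anchor_2c=anchor)
        cfg = GateConfig(markers=markers)
        frac = quantify_compartments(gated, cfg)
        pct = frac.as_dict()
        out[genotype] = {
            "pct": pct,
            "modal": max(pct, key=pct.get),
            "truth": compartment_fractions(spec),
        }
    return out


def statistical_calibration(seed: int = 0, n_reps: int = 10_000):
    """Type-I error rates and oracle-equivalence gaps for the statistics layer.

    Returns the null rejection rates of the Welch t-test (Normal(0,1), n=20
    per arm) and Pearson chi-square (2x2 multinomial, n=200, independent
    margins) at alpha = 0.05; the worst |Cox score - log-rank| statistic gap
    over tie-free two-group survival draws; the worst |KM - empirical
    survivor| gap without censoring; and the gap between the asymptotic
    log-rank p and a 10,000-permutation exact p at n=20.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 303)))

    x = rng.normal(size=(n_reps, 20))
    y = rng.normal(size=(n_reps, 20))
    res = stats.ttest_ind(x, y, axis=1, equal_var=False)
    welch_rate = float(np.mean(res.pvalue <= 0.05))

    probs = np.array([0.25, 0.25, 0.25, 0.25])
    tables = rng.multinomial(200, probs, size=n_reps).reshape(n_reps, 2, 2)
    rej = 0
    valid = 0
    for t in tables:
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            continue
        valid += 1
        if contingency_test(t, method="pearson").p_value <= 0.05:
            rej += 1
    chisq_rate = rej / max(valid, 1)

    # Cox score vs log-rank equivalence (no ties)
    max_gap = 0.0
    for _ in range(20):
        t1 = rng.exponential(1.0, size=30)
        t2 = rng.exponential(0.6, size=30)
        times = np.concatenate([t1, t2])
        group = np.concatenate([np.zeros(30), np.ones(30)])
        events = np.ones(60, bool)
        score = cox_score_test(times, events, group).statistic
        lr = log_rank_test([(t1, None), (t2, None)]).statistic
        max_gap = max(max_gap, abs(score - lr))

    # KM vs empirical survivor (uncensored)
    km_gap = 0.0
    for _ in range(5):
        t = rng.exponential(1.0, size=50)
        km = km_estimate(t)
        n = len(t)
        srt = np.sort(t)
        emp = 1.0 - np.searchsorted(srt, km.times, side="right") / n
        km_gap = max(km_gap, float(np.max(np.abs(km.survival - emp))))

    # log-rank asymptotic p vs label-permutation p at n=20
    t_small = rng.exponential(1.0, size=20)
    g_small = np.array([0] * 10 + [1] * 10, float)
    ev = np.ones(20, bool)
    obs = cox_score_test(t_small, ev, g_small).statistic
    p_asym = float(stats.chi2.sf(obs, 1))
    count = 0
    for _ in range(10_000):
        perm = rng.permutation(g_small)
        if cox_score_test(t_small, ev, perm).statistic >= obs - 1e-12:
            count += 1
    p_perm = count / 10_000

    # small-table permutation p vs full fixed-margin enumeration
    def exact_conditional_p(table):
        table = np.asarray(table)
        r1, r2 = table.sum(axis=1)
        c1, c2 = table.sum(axis=0)
        n = table.sum()

        def pearson(a):
            t = np.array([[a, r1 - a], [c1 - a, r2 - c1 + a]], float)
            e = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
            return ((t - e) ** 2 / e).sum()

        obs_stat = pearson(table[0, 0])
        return float(
            sum(
                stats.hypergeom.pmf(a, n, r1, c1)
                for a in range(max(0, c1 - r2), min(r1, c1) + 1)
                if pearson(a) >= obs_stat - 1e-12
            )
        )

    small_gap = 0.0
    for tbl in ([[3, 2], [1, 5]], [[4, 1], [2, 5]], [[2, 4], [4, 2]]):
        p_mc = permutation_contingency_p(tbl, n_perm=20_000, seed=seed)
        small_gap = max(small_gap, abs(p_mc - exact_conditional_p(tbl)))
    return {
        "contingency_mc_vs_enumeration_max_gap": small_gap,
        "welch_type1_rate": welch_rate,
        "chisq_type1_rate": float(chisq_rate),
        "cox_score_vs_logrank_max_abs_gap": float(max_gap),
        "km_vs_empirical_max_abs_gap": float(km_gap),
        "logrank_asymptotic_vs_permutation_p_gap": abs(p_asym - p_perm),
    }
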