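"""Record-level reconstruction of the published study cohort.

The study reports only summary tables (counts by genotype, sex, location and
ploidy category, plus median ages).  This module rebuilds a per-tumor record
table that is simultaneously consistent with every printed marginal:

* 49 + 50 fish and 52 + 51 tumors per genotype (four fish carry two tumors);
* diploid/aneuploid counts by genotype (25/27 and 18/33) and by sex
  (17/35 females, 26/24 males; one fish of undetermined sex);
* aneuploid subtype counts by genotype and by sex;
* tumor locations by genotype (30/19/3 and 40/9/2 coelom/ocular/other) with
  the coelomic diploid/aneuploid splits 15/15 and 13/27;
* of the four two-tumor fish, three carry discordant ploidy and one two
  aneuploid tumors.

Cell-level allocations not pinned down by any printed marginal (e.g. which
ocular tumors are hypodiploid) are fixed arbitrarily but deterministically.
Ages are deterministic lognormal quantile grids per genotype x sex matched to
the printed medians — cosmetic structure for table display, not data.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["study_cohort", "GENOTYPE_PLOIDY_TABLE", "SEX_PLOIDY_TABLE"]

#: genotype x (diploid, aneuploid) tumor counts
GENOTYPE_PLOIDY_TABLE = [[25, 27], [18, 33]]
#: sex x (diploid, aneuploid) tumor counts (undetermined-sex fish excluded)
SEX_PLOIDY_TABLE = [[17, 35], [26, 24]]

#: Median age at diagnosis (months) by genotype and sex.
MEDIAN_AGES = {
    ("brca2_tp53", "M"): 9.0,
    ("brca2_tp53", "F"): 7.4,
    ("brca2_tp53", "U"): 8.2,
    ("tp53", "M"): 11.3,
    ("tp53", "F"): 9.7,
}

# (genotype, sex, location, ploidy_category, count); sums to 103 tumors and
# reproduces every marginal listed in the module docstring.
_CELLS = [
    # --- brca2_tp53, diploid (25) ---
    ("brca2_tp53", "F", "coelom", "diploid", 7),
    ("brca2_tp53", "F", "ocular", "diploid", 4),
    ("brca2_tp53", "M", "coelom", "diploid", 8),
    ("brca2_tp53", "M", "ocular", "diploid", 5),
    ("brca2_tp53", "M", "other", "diploid", 1),
    # --- brca2_tp53, aneuploid (27: 4 hypo, 19 hyper, 1 tetra, 3 complex) ---
    ("brca2_tp53", "F", "coelom", "hyperdiploid_aneuploid", 9),
    ("brca2_tp53", "F", "ocular", "hyperdiploid_aneuploid", 3),
    ("brca2_tp53", "F", "ocular", "hypodiploid_aneuploid", 2),
    ("brca2_tp53", "F", "ocular", "complex_aneuploid", 1),
    ("brca2_tp53", "F", "other", "tetraploid_aneuploid", 1),
    ("brca2_tp53", "M", "coelom", "hyperdiploid_aneuploid", 5),
    ("brca2_tp53", "M", "ocular", "hypodiploid_aneuploid", 2),
    ("brca2_tp53", "M", "ocular", "complex_aneuploid", 2),
    ("brca2_tp53", "M", "other", "hyperdiploid_aneuploid", 1),
    ("brca2_tp53", "U", "coelom", "hyperdiploid_aneuploid", 1),
    # --- tp53, diploid (18) ---
    ("tp53", "F", "coelom", "diploid", 5),
    ("tp53", "F", "ocular", "diploid", 1),
    ("tp53", "M", "coelom", "diploid", 8),
    ("tp53", "M", "ocular", "diploid", 3),
    ("tp53", "M", "other", "diploid", 1),
    # --- tp53, aneuploid (33: 3 hypo, 23 hyper, 0 tetra, 7 complex) ---
    ("tp53", "F", "coelom", "hyperdiploid_aneuploid", 12),
    ("tp53", "F", "coelom", "complex_aneuploid", 4),
    ("tp53", "F", "ocular", "hypodiploid_aneuploid", 2),
    ("tp53", "F", "ocular", "hyperdiploid_aneuploid", 1),
    ("tp53", "M", "coelom", "hyperdiploid_aneuploid", 9),
    ("tp53", "M", "coelom", "hypodiploid_aneuploid", 1),
    ("tp53", "M", "coelom", "complex_aneuploid", 1),
    ("tp53", "M", "ocular", "complex_aneuploid", 2),
    ("tp53", "M", "other", "hyperdiploid_aneuploid", 1),
]

# Two-tumor fish: (genotype, sex, [(location, category), (location, category)]).
# Three discordant pairs and one concordant-aneuploid pair.
_TWO_TUMOR_FISH = [
    ("brca2_tp53", "F", [("coelom", "diploid"),
                         ("ocular", "hyperdiploid_aneuploid")]),
    ("brca2_tp53", "M", [("coelom", "diploid"),
                         ("ocular", "hypodiploid_aneuploid")]),
    ("brca2_tp53", "M", [("coelom", "hyperdiploid_aneuploid"),
                         ("ocular", "complex_aneuploid")]),
    ("tp53", "M", [("coelom", "diploid"),
                   ("ocular", "complex_aneuploid")]),
]


def _age_grid(n: int, median: float, sigma: float = 0.12) -> np.ndarray:
    """Deterministic lognormal quantile grid with the given sample median."""
    from scipy.stats import norm

    q = (np.arange(n) + 0.5) / n
    return median * np.exp(sigma * norm.ppf(q))


def study_cohort() -> pd.DataFrame:
    """The reconstructed 103-tumor cohort table.

    Columns: fish_id, genotype, sex, location, age_months, event,
    ploidy_category.  Deterministic: repeated calls return identical frames.
    """
    tumors = []
    for genotype, sex, location, category, count in _CELLS:
        for _ in range(count):
            tumors.append(
                {"genotype": genotype, "sex": sex, "location": location,
                 "ploidy_category": category}
            )
    # assign fish ids: each two-tumor fish claims one matching unclaimed tumor
    # per (location, category) slot; remaining tumors get their own fish
    claimed = [False] * len(tumors)
    fish: list[list[int]] = []
    for genotype, sex, slots in _TWO_TUMOR_FISH:
        members = []
        for location, category in slots:
            for i, t in enumerate(tumors):
                if claimed[i]:
                    continue
                if (t["genotype"], t["sex"], t["location"],
                        t["ploidy_category"]) == (genotype, sex, location,
                                                  category):
                    claimed[i] = True
                    members.append(i)
                    break
            else:  # pragma: no cover - table and pairs are mutually consistent
                raise AssertionError("two-tumor slot not satisfiable")
        fish.append(members)
    for i in range(len(tumors)):
        if not claimed[i]:
            fish.append([i])

    # deterministic fish ordering, then ages per genotype x sex
    def fish_key(members):
        t = tumors[members[0]]
        return (t["genotype"], t["sex"], t["location"], t["ploidy_category"],
                members[0])

    fish.sort(key=fish_key)
    rows = []
    by_group: dict[tuple[str, str], list[int]] = {}
    for fid, members in enumerate(fish):
        t0 = tumors[members[0]]
        by_group.setdefault((t0["genotype"], t0["sex"]), []).append(fid)
    ages: dict[int, float] = {}
    for (genotype, sex), fids in sorted(by_group.items()):
        grid = _age_grid(len(fids), MEDIAN_AGES[(genotype, sex)])
        for fid, age in zip(fids, grid):
            ages[fid] = float(age)
    for fid, members in enumerate(fish):
        genotype = tumors[members[0]]["genotype"]
        for i in members:
            t = tumors[i]
            rows.append(
                {
                    "fish_id": f"{genotype}-{fid:03d}",
                    "genotype": t["genotype"],
                    "sex": t["sex"],
                    "location": t["location"],
                    "age_months": round(ages[fid], 2),
                    "event": 1,
                    "ploidy_category": t["ploidy_category"],
                }
            )
    df = pd.DataFrame(rows).sort_values(["genotype", "fish_id"]).reset_index(
        drop=True
    )
    assert len(df) == 103
    return df
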