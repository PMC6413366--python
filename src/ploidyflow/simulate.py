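"""Synthetic DNA-content cytometry events and cohort tables with known ground truth.

The simulator emulates propidium-iodide (PI) DNA histograms of dissociated
tissue: one or more cell-cycle populations at arbitrary DNA index, sliced-nuclei
debris, cell doublets, and forward-scatter nuisance structure.  Every event
carries truth labels so downstream gating, deconvolution and ploidy calling can
be scored against the generating parameters.

All randomness flows from one integer seed through a splittable
``numpy.random.SeedSequence``; identical specs produce byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSpec",
    "SimulationSpec",
    "CohortDesign",
    "CohortRecord",
    "EVENT_COLUMNS",
    "simulate_events",
    "testis_preset",
    "simulate_cohort",
    "simulate_pair",
    "DEBRIS_KERNELS",
]

EVENT_COLUMNS = ["sample_id", "FSC-A", "FSC-H", "PI-A", "PI-H"]
TRUTH_COLUMNS = ["truth_population", "truth_is_debris", "truth_is_doublet"]

#: Fixed lognormal parameters for singlet forward scatter (arbitrary units).
#: Scatter is nuisance structure only; the median and spread are chosen so the
#: FSC-H/FSC-A ratio of singlets sits tightly inside the default gating band.
FSC_MEDIAN = 1.0e5
FSC_SIGMA = 0.30
FSC_HEIGHT_RATIO = 0.80
FSC_HEIGHT_JITTER = 0.02
PIA_JITTER = 0.02


class SpecValidationError(ValueError):
    """A simulation spec violated an invariant; the message names the field."""


@dataclass(frozen=True)
class PopulationSpec:
    """One cell-cycle population at a given DNA index.

    ``dna_index`` is the ratio of this population's G0/G1 DNA content to the
    diploid (2C) reference; ``fraction`` is its share of non-debris singlet
    events; ``cv_pct`` the percent CV of its G0/G1 peak; the three phase
    fractions partition the population among G0/G1, S and G2/M.
    """

    dna_index: float
    fraction: float
    cv_pct: float = 4.0
    frac_g1: float = 1.0
    frac_s: float = 0.0
    frac_g2m: float = 0.0
    label: str = ""

    def validate(self) -> None:
        if not self.dna_index > 0:
            raise SpecValidationError(f"dna_index must be > 0, got {self.dna_index}")
        if not 0.0 <= self.fraction <= 1.0:
            raise SpecValidationError(f"fraction must be in [0, 1], got {self.fraction}")
        if not self.cv_pct > 0:
            raise SpecValidationError(f"cv_pct must be > 0, got {self.cv_pct}")
        for name in ("frac_g1", "frac_s", "frac_g2m"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecValidationError(f"{name} must be in [0, 1], got {v}")
        total = self.frac_g1 + self.frac_s + self.frac_g2m
        if abs(total - 1.0) > 1e-9:
            raise SpecValidationError(
                f"frac_g1 + frac_s + frac_g2m must sum to 1, got {total}"
            )


@dataclass(frozen=True)
class SimulationSpec:
    """Full specification of one synthetic specimen."""

    populations: tuple[PopulationSpec, ...]
    n_events: int = 10_000
    debris_fraction: float = 0.0
    doublet_fraction: float = 0.0
    diploid_channel: float = 1.0e5
    seed: int = 0
    #: name in :data:`DEBRIS_KERNELS`; "arcsine" is the sliced-nucleus default
    debris_kernel: str = "arcsine"
    doublet_height_ratio: float = 0.6

    def __post_init__(self):
        object.__setattr__(self, "populations", tuple(self.populations))

    def validate(self) -> None:
        if not self.populations:
            raise SpecValidationError("populations must be non-empty")
        for p in self.populations:
            p.validate()
        total = sum(p.fraction for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise SpecValidationError(f"population fractions must sum to 1, got {total}")
        if self.n_events < 1:
            raise SpecValidationError(f"n_events must be >= 1, got {self.n_events}")
        if not self.diploid_channel > 0:
            raise SpecValidationError(
                f"diploid_channel must be > 0, got {self.diploid_channel}"
            )
        if not 0.0 <= self.debris_fraction < 1.0:
            raise SpecValidationError(
                f"debris_fraction must be in [0, 1), got {self.debris_fraction}"
            )
        if not 0.0 <= self.doublet_fraction < 1.0:
            raise SpecValidationError(
                f"doublet_fraction must be in [0, 1), got {self.doublet_fraction}"
            )
        if self.debris_fraction + self.doublet_fraction >= 1.0:
            raise SpecValidationError(
                "debris_fraction + doublet_fraction must be < 1"
            )
        if self.debris_kernel not in DEBRIS_KERNELS:
            raise SpecValidationError(
                f"debris_kernel must be one of {sorted(DEBRIS_KERNELS)}, "
                f"got {self.debris_kernel!r}"
            )


def _arcsine(rng: np.random.Generator, size: int) -> np.ndarray:
    # sliced-nucleus fragment-size density 1/(pi*sqrt(b(1-b))) on (0,1)
    return rng.beta(0.5, 0.5, size=size)


def _uniform_low(rng: np.random.Generator, size: int) -> np.ndarray:
    # fragments uniformly below 45% of the parent; useful to construct debris
    # that is cleanly separable by a threshold gate
    return rng.uniform(0.0, 0.45, size=size)


DEBRIS_KERNELS = {"arcsine": _arcsine, "uniform_low": _uniform_low}


def _draw_singlets(spec: SimulationSpec, rng: np.random.Generator, n: int):
    """Draw n singlet PI-H values plus their population indices."""
    fractions = np.array([p.fraction for p in spec.populations])
    pop_idx = rng.choice(len(fractions), size=n, p=fractions)
    pi = np.empty(n)
    for i, pop in enumerate(spec.populations):
        mask = pop_idx == i
        k = int(mask.sum())
        if k == 0:
            continue
        phase = rng.choice(3, size=k, p=[pop.frac_g1, pop.frac_s, pop.frac_g2m])
        mult = np.ones(k)
        mult[phase == 1] = rng.uniform(1.0, 2.0, size=int((phase == 1).sum()))
        mult[phase == 2] = 2.0
        mean = spec.diploid_channel * pop.dna_index
        sd = pop.cv_pct / 100.0 * mean
        pi[mask] = mult * mean + rng.normal(0.0, sd, size=k)
    return np.maximum(pi, 0.0), pop_idx


def _fsc(rng: np.random.Generator, n: int):
    fsc_a = FSC_MEDIAN * np.exp(rng.normal(0.0, FSC_SIGMA, size=n))
    fsc_h = FSC_HEIGHT_RATIO * fsc_a * (1.0 + rng.normal(0.0, FSC_HEIGHT_JITTER, size=n))
    return fsc_a, np.maximum(fsc_h, 0.0)


def simulate_events(spec: SimulationSpec, sample_id: str = "synthetic") -> pd.DataFrame:
    """Simulate one specimen's event table.

    Returns a DataFrame with columns ``sample_id, FSC-A, FSC-H, PI-A, PI-H``
    plus truth labels ``truth_population`` (population label or index),
    ``truth_is_debris`` and ``truth_is_doublet``.

    Non-debris singlet PI-H is Normal(diploid_channel x dna_index x phase
    multiplier, cv/100 x diploid_channel x dna_index) with multiplier 1 for
    G0/G1, 2 for G2/M and uniform (1, 2) for S (zero-order S phase).  Debris
    takes PI = parent x B with B from the configured fragment kernel; a doublet
    sums two singlet PI signals with FSC-H suppressed relative to FSC-A so a
    ratio gate can remove it.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_events

    category = rng.choice(
        3,
        size=n,
        p=[
            1.0 - spec.debris_fraction - spec.doublet_fraction,
            spec.debris_fraction,
            spec.doublet_fraction,
        ],
    )
    n_singlet = int((category == 0).sum())
    n_debris = int((category == 1).sum())
    n_doublet = int((category == 2).sum())

    pi = np.empty(n)
    pop_label = np.full(n, "", dtype=object)
    fsc_a = np.empty(n)
    fsc_h = np.empty(n)

    labels = [p.label or f"pop{i}" for i, p in enumerate(spec.populations)]

    s_pi, s_idx = _draw_singlets(spec, rng, n_singlet)
    s_fa, s_fh = _fsc(rng, n_singlet)
    pi[category == 0] = s_pi
    fsc_a[category == 0] = s_fa
    fsc_h[category == 0] = s_fh
    pop_label[category == 0] = np.array(labels, dtype=object)[s_idx]

    if n_debris:
        parent_pi, parent_idx = _draw_singlets(spec, rng, n_debris)
        b = DEBRIS_KERNELS[spec.debris_kernel](rng, n_debris)
        d_fa, d_fh = _fsc(rng, n_debris)
        pi[category == 1] = parent_pi * b
        fsc_a[category == 1] = d_fa * b
        fsc_h[category == 1] = d_fh * b
        pop_label[category == 1] = "debris"

    if n_doublet:
        p1, _ = _draw_singlets(spec, rng, n_doublet)
        p2, _ = _draw_singlets(spec, rng, n_doublet)
        fa1, _ = _fsc(rng, n_doublet)
        fa2, _ = _fsc(rng, n_doublet)
        pi[category == 2] = p1 + p2
        fsc_a[category == 2] = fa1 + fa2
        fsc_h[category == 2] = spec.doublet_height_ratio * (fa1 + fa2)
        pop_label[category == 2] = "doublet"

    pi_a = pi * (1.0 + rng.normal(0.0, PIA_JITTER, size=n))

    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "FSC-A": fsc_a,
            "FSC-H": fsc_h,
            "PI-A": np.maximum(pi_a, 0.0),
            "PI-H": pi,
            "truth_population": pop_label,
            "truth_is_debris": category == 1,
            "truth_is_doublet": category == 2,
        }
    )


# ---------------------------------------------------------------------------
# Testis presets
# ---------------------------------------------------------------------------

#: Default 1C/2C/S/4C compartment shares per genotype.  These are presets that
#: satisfy the qualitative profile of each genotype (modal compartment, 1C
#: depletion, S elevation), not measured values: zebrafish testes with intact
#: spermatogenesis are dominated by haploid spermatozoa; brca2-mutant testes
#: arrest in meiosis I and accumulate 4C cells with elevated S; combined
#: brca2/tp53 mutants accumulate 2C spermatogonia.
TESTIS_COMPARTMENTS: dict[str, dict[str, float]] = {
    "wild_type": {"1C": 0.55, "2C": 0.20, "S": 0.08, "4C": 0.17},
    "tp53": {"1C": 0.50, "2C": 0.27, "S": 0.07, "4C": 0.16},
    "brca2": {"1C": 0.01, "2C": 0.25, "S": 0.24, "4C": 0.50},
    "brca2_tp53": {"1C": 0.01, "2C": 0.60, "S": 0.14, "4C": 0.25},
}


def testis_preset(
    genotype: str,
    n_events: int = 10_000,
    cv_pct: float = 4.0,
    diploid_channel: float = 1.0e5,
    debris_fraction: float = 0.03,
    doublet_fraction: float = 0.02,
    seed: int = 0,
) -> SimulationSpec:
    """Simulation spec for a whole-testis DNA profile of the given genotype.

    The 2C/S/4C compartments are expressed as the G0/G1, S and G2/M phases of
    a diploid germline population; the 1C compartment is a separate haploid
    population at DNA index 0.5.
    """
    if genotype not in TESTIS_COMPARTMENTS:
        raise SpecValidationError(
            f"unknown genotype {genotype!r}; valid values: "
            f"{sorted(TESTIS_COMPARTMENTS)}"
        )
    c = TESTIS_COMPARTMENTS[genotype]
    germ = c["2C"] + c["S"] + c["4C"]
    populations = (
        PopulationSpec(
            dna_index=0.5, fraction=c["1C"], cv_pct=cv_pct, label="haploid"
        ),
        PopulationSpec(
            dna_index=1.0,
            fraction=germ,
            cv_pct=cv_pct,
            frac_g1=c["2C"] / germ,
            frac_s=c["S"] / germ,
            frac_g2m=c["4C"] / germ,
            label="germline",
        ),
    )
    return SimulationSpec(
        populations=populations,
        n_events=n_events,
        debris_fraction=debris_fraction,
        doublet_fraction=doublet_fraction,
        diploid_channel=diploid_channel,
        seed=seed,
    )


def compartment_fractions(spec: SimulationSpec) -> dict[str, float]:
    """Ground-truth 1C/2C/S/4C shares of non-debris singlets for a testis spec."""
    out = {"1C": 0.0, "2C": 0.0, "S": 0.0, "4C": 0.0}
    for p in spec.populations:
        if p.dna_index == 0.5:
            out["1C"] += p.fraction * p.frac_g1
            # an S/G2M tail of a haploid population overlaps 2C; presets keep it at 0
            out["2C"] += p.fraction * p.frac_g2m
        else:
            out["2C"] += p.fraction * p.frac_g1
            out["S"] += p.fraction * p.frac_s
            out["4C"] += p.fraction * p.frac_g2m
    return out


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

PLOIDY_CATEGORIES = (
    "diploid",
    "hypodiploid_aneuploid",
    "hyperdiploid_aneuploid",
    "tetraploid_aneuploid",
    "complex_aneuploid",
)

#: Default aneuploid-subtype mix among aneuploid cancers (pooled study counts:
#: 7 hypodiploid, 42 hyperdiploid, 1 tetraploid, 10 complex of 60 aneuploid).
ANEUPLOID_SUBTYPE_P = {
    "hypodiploid_aneuploid": 7 / 60,
    "hyperdiploid_aneuploid": 42 / 60,
    "tetraploid_aneuploid": 1 / 60,
    "complex_aneuploid": 10 / 60,
}


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design for a synthetic cancer cohort.

    Defaults follow the study population: ~50 fish per genotype, aneuploidy
    probability 0.67 for females and 0.48 for males, median ages at diagnosis
    of 8.2 (brca2_tp53) and 10.8 (tp53) months, and location frequencies
    dominated by coelomic tumors.
    """

    group_sizes: dict = field(
        default_factory=lambda: {"brca2_tp53": 49, "tp53": 50}
    )
    aneuploidy_p_by_sex: dict = field(
        default_factory=lambda: {"F": 0.67, "M": 0.48}
    )
    median_age_months: dict = field(
        default_factory=lambda: {"brca2_tp53": 8.2, "tp53": 10.8}
    )
    #: lognormal sigma of age about its median; 0.15 reproduces the printed
    #: age ranges (roughly median x/ 1.6)
    age_dispersion: float = 0.15
    location_p: dict = field(
        default_factory=lambda: {
            "brca2_tp53": {"coelom": 30 / 52, "ocular": 19 / 52, "other": 3 / 52},
            "tp53": {"coelom": 40 / 51, "ocular": 9 / 51, "other": 2 / 51},
        }
    )
    female_p: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not self.group_sizes or sum(self.group_sizes.values()) <= 0:
            raise SpecValidationError("group_sizes must contain at least one fish")
        for g, n in self.group_sizes.items():
            if n < 0:
                raise SpecValidationError(f"group_sizes[{g!r}] must be >= 0")
        for s, p in self.aneuploidy_p_by_sex.items():
            if not 0.0 <= p <= 1.0:
                raise SpecValidationError(
                    f"aneuploidy_p_by_sex[{s!r}] must be in [0, 1], got {p}"
                )
        for g, m in self.median_age_months.items():
            if not m > 0:
                raise SpecValidationError(
                    f"median_age_months[{g!r}] must be > 0, got {m}"
                )
        if not 0.0 <= self.female_p <= 1.0:
            raise SpecValidationError(f"female_p must be in [0, 1], got {self.female_p}")


@dataclass(frozen=True)
class CohortRecord:
    """One cancer specimen in the cohort table."""

    fish_id: str
    genotype: str
    sex: str
    location: str
    age_months: float
    event_observed: bool = True
    ploidy_category: str = "diploid"

    @property
    def aneuploid(self) -> bool:
        return self.ploidy_category != "diploid"


def simulate_cohort(design: CohortDesign) -> list[CohortRecord]:
    """Draw a cohort of cancer records with ground-truth ploidy.

    Each fish gets a sex, tumor location, age at diagnosis (lognormal about
    the genotype median) and a ploidy category drawn from the sex-specific
    aneuploidy probability, with aneuploid subtypes at their pooled study
    frequencies.
    """
    design.validate()
    rng = np.random.default_rng(np.random.SeedSequence(design.seed))
    records: list[CohortRecord] = []
    subtypes = list(ANEUPLOID_SUBTYPE_P)
    subtype_p = np.array([ANEUPLOID_SUBTYPE_P[s] for s in subtypes])
    for genotype in sorted(design.group_sizes):
        n = design.group_sizes[genotype]
        median = design.median_age_months.get(genotype, 9.0)
        locs = sorted(design.location_p.get(genotype, {"coelom": 1.0}))
        loc_p = np.array(
            [design.location_p.get(genotype, {"coelom": 1.0})[l] for l in locs]
        )
        loc_p = loc_p / loc_p.sum()
        for i in range(n):
            sex = "F" if rng.random() < design.female_p else "M"
            location = locs[rng.choice(len(locs), p=loc_p)]
            age = median * math.exp(rng.normal(0.0, design.age_dispersion))
            p_aneu = design.aneuploidy_p_by_sex.get(sex, 0.5)
            if rng.random() < p_aneu:
                category = subtypes[rng.choice(len(subtypes), p=subtype_p)]
            else:
                category = "diploid"
            records.append(
                CohortRecord(
                    fish_id=f"{genotype}-{i:03d}",
                    genotype=genotype,
                    sex=sex,
                    location=location,
                    age_months=age,
                    event_observed=True,
                    ploidy_category=category,
                )
            )
    return records


def cohort_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    """Cohort records as the canonical TSV-layout DataFrame."""
    return pd.DataFrame(
        [
            {
                "fish_id": r.fish_id,
                "genotype": r.genotype,
                "sex": r.sex,
                "location": r.location,
                "age_months": r.age_months,
                "event": int(r.event_observed),
                "ploidy_category": r.ploidy_category,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# Matched tumor/somatic pairs
# ---------------------------------------------------------------------------

def simulate_pair(
    di_true: float,
    seed: int,
    cv_pct: float = 4.0,
    n_events: int = 10_000,
    aneuploid_share: float = 0.6,
    debris_fraction: float = 0.05,
    doublet_fraction: float = 0.02,
    diploid_channel: float = 1.0e5,
    somatic_cv_pct: float | None = None,
    phase_fractions: tuple[float, float, float] = (0.85, 0.05, 0.10),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a matched (tumor, somatic) pair of event tables.

    The somatic specimen is a single diploid cycle.  The tumor contains an
    aneuploid population at ``di_true`` with share ``aneuploid_share`` plus an
    internal diploid population for the remainder; at ``di_true == 1`` or
    ``aneuploid_share >= 1`` it collapses to a single population.
    """
    g1, s, g2m = phase_fractions
    ss = np.random.SeedSequence(seed).spawn(2)
    somatic_spec = SimulationSpec(
        populations=(
            PopulationSpec(
                dna_index=1.0,
                fraction=1.0,
                cv_pct=somatic_cv_pct if somatic_cv_pct is not None else cv_pct,
                frac_g1=0.90,
                frac_s=0.04,
                frac_g2m=0.06,
                label="somatic",
            ),
        ),
        n_events=n_events,
        debris_fraction=debris_fraction,
        doublet_fraction=doublet_fraction,
        diploid_channel=diploid_channel,
        seed=int(ss[0].generate_state(1)[0] % (2**31)),
    )
    pops: list[PopulationSpec]
    if abs(di_true - 1.0) < 1e-12 or aneuploid_share >= 1.0 - 1e-12:
        pops = [
            PopulationSpec(
                dna_index=di_true,
                fraction=1.0,
                cv_pct=cv_pct,
                frac_g1=g1,
                frac_s=s,
                frac_g2m=g2m,
                label="tumor",
            )
        ]
    else:
        pops = [
            PopulationSpec(
                dna_index=1.0,
                fraction=1.0 - aneuploid_share,
                cv_pct=cv_pct,
                frac_g1=0.90,
                frac_s=0.04,
                frac_g2m=0.06,
                label="internal_diploid",
            ),
            PopulationSpec(
                dna_index=di_true,
                fraction=aneuploid_share,
                cv_pct=cv_pct,
                frac_g1=g1,
                frac_s=s,
                frac_g2m=g2m,
                label="aneuploid",
            ),
        ]
    tumor_spec = SimulationSpec(
        populations=tuple(pops),
        n_events=n_events,
        debris_fraction=debris_fraction,
        doublet_fraction=doublet_fraction,
        diploid_channel=diploid_channel,
        seed=int(ss[1].generate_state(1)[0] % (2**31)),
    )
    return (
        simulate_events(tumor_spec, sample_id="tumor"),
        simulate_events(somatic_spec, sample_id="somatic"),
    )


def spec_to_json(spec: SimulationSpec) -> dict:
    d = asdict(spec)
    d["populations"] = [asdict(p) for p in spec.populations]
    return d


def spec_from_json(d: dict) -> SimulationSpec:
    pops = tuple(PopulationSpec(**p) for p in d["populations"])
    rest = {k: v for k, v in d.items() if k != "populations"}
    return SimulationSpec(populations=pops, **rest)
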