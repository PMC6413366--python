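"""DNA-index computation and tumor ploidy calling for matched specimen pairs.

The decision tree mirrors routine clinical DNA-cytometry practice:

1. QC exclusions — a somatic (normal-tissue) G0/G1 CV above 6.0, too few
   events to fit a cycle, or an undefinable diploid population exclude the
   pair.
2. Reference selection — the DNA index denominator is the tumor's *internal*
   diploid G0/G1 peak when one matches the somatic peak and has CV <= 6.0;
   otherwise the matched somatic peak.  When the aneuploid population is minor
   (<= 20% of modeled events) or is ambiguously modeled against the diploid
   G2/M, the predominant diploid peak is used for the index instead.
3. DNA index = tumor G0/G1 peak / reference diploid G0/G1 peak.
4. Categories — diploid within 1 +/- delta (default 0.05); hypodiploid below;
   tetraploid within 2 +/- delta_t (default 0.10); hyperdiploid otherwise
   above the diploid band; two or more distinct non-harmonic aneuploid G0/G1
   peaks make the tumor complex aneuploid with no single DNA index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cellcycle import (
    CellCycleFit,
    DNAHistogram,
    FitError,
    detect_g1_peaks,
    fit_cell_cycle,
    make_histogram,
    primary_peaks,
)

__all__ = [
    "PloidyConfig",
    "SpecimenPair",
    "PloidyCall",
    "apply_exclusions",
    "select_reference",
    "compute_dna_index",
    "classify_ploidy",
    "call_pair",
    "call_from_events",
]

CATEGORIES = (
    "diploid",
    "hypodiploid_aneuploid",
    "hyperdiploid_aneuploid",
    "tetraploid_aneuploid",
    "complex_aneuploid",
)

QC_FLAGS = (
    "somatic_cv_gt_6",
    "insufficient_events",
    "no_diploid_definable",
    "minor_aneuploid_le_20pct",
    "ambiguous_g2m_vs_aneuploid",
    "excluded",
)


@dataclass(frozen=True)
class PloidyConfig:
    """Tunable thresholds of the calling tree."""

    cv_threshold: float = 6.0
    min_events: int = 1000
    #: relative tolerance for matching a tumor cycle to the somatic peak
    match_tol: float = 0.05
    #: aneuploid share at or below which the predominant diploid peak is used
    minor_threshold: float = 0.20
    #: half-width of the diploid DNA-index band
    diploid_delta: float = 0.05
    #: half-width of the tetraploid band around 2.0
    tetraploid_delta: float = 0.10
    #: reduced-chi-square gap below which the aneuploid-vs-G2/M topologies tie
    ambiguity_delta_rcs: float = 0.05
    #: "distinct" complex peaks are separated by > this many pooled sigmas
    distinct_sigmas: float = 3.0
    harmonic_tol: float = 0.06


@dataclass
class SpecimenPair:
    """Matched tumor and somatic specimens from one fish."""

    fish_id: str
    tumor_fit: CellCycleFit | None = None
    somatic_fit: CellCycleFit | None = None
    tumor_hist: DNAHistogram | None = None
    somatic_hist: DNAHistogram | None = None
    location: str = "coelom"
    metadata: dict = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return self.tumor_fit is not None and self.somatic_fit is not None


@dataclass
class PloidyCall:
    """Outcome of the decision tree for one pair."""

    fish_id: str
    dna_index: float | None
    category: str | None
    reference_source: str | None
    qc_flags: set = field(default_factory=set)

    def __post_init__(self):
        if self.category == "complex_aneuploid":
            assert self.dna_index is None
        if "excluded" in self.qc_flags:
            assert self.category is None
        if self.dna_index is not None:
            assert self.dna_index > 0

    @property
    def excluded(self) -> bool:
        return "excluded" in self.qc_flags

    def to_json(self) -> dict:
        return {
            "fish_id": self.fish_id,
            "dna_index": self.dna_index,
            "category": self.category,
            "reference_source": self.reference_source,
            "qc_flags": sorted(self.qc_flags),
        }


def apply_exclusions(pair: SpecimenPair, config: PloidyConfig = PloidyConfig()) -> set:
    """QC flags for the pair; ``excluded`` is present iff a hard criterion fires.

    Computable criteria: somatic G0/G1 CV > 6.0 (strict), insufficient events
    in either specimen, and an undefinable somatic diploid population.
    Found-dead / no-gross-tumor exclusions are metadata pass-throughs handled
    upstream.
    """
    flags: set[str] = set()
    if pair.somatic_fit is None:
        flags |= {"no_diploid_definable", "excluded"}
        return flags
    som = pair.somatic_fit
    som_cv = som.cycles[som.predominant_cycle].cv_g1
    if som_cv > config.cv_threshold:
        flags |= {"somatic_cv_gt_6", "excluded"}
    if som.n_events_fit < config.min_events:
        flags |= {"insufficient_events", "excluded"}
    if pair.tumor_fit is not None and pair.tumor_fit.n_events_fit < config.min_events:
        flags |= {"insufficient_events", "excluded"}
    if pair.tumor_fit is None and pair.tumor_hist is None:
        flags |= {"insufficient_events", "excluded"}
    return flags


def _split_cycles(tumor: CellCycleFit, somatic_mu: float, config: PloidyConfig):
    """Partition tumor cycles into (diploid-matching, aneuploid) index lists."""
    diploid, aneuploid = [], []
    for i, c in enumerate(tumor.cycles):
        if abs(c.mu_g1 / somatic_mu - 1.0) <= config.match_tol:
            diploid.append(i)
        else:
            aneuploid.append(i)
    return diploid, aneuploid


def select_reference(
    pair: SpecimenPair, config: PloidyConfig = PloidyConfig()
) -> tuple[float, str]:
    """Reference diploid G0/G1 channel and its provenance for the DNA index.

    Returns ``(reference_channel, source)`` with source one of
    ``internal_diploid``, ``matched_somatic``, ``predominant_diploid``.
    Raises ValueError when neither a somatic reference nor an internal diploid
    exists.
    """
    if pair.somatic_fit is None:
        if pair.tumor_fit is None:
            raise ValueError("no_diploid_definable: neither specimen has a fit")
        raise ValueError("no_diploid_definable: somatic diploid not available")
    tumor = pair.tumor_fit
    som = pair.somatic_fit
    somatic_mu = som.cycles[som.predominant_cycle].mu_g1
    if tumor is None:
        return somatic_mu, "matched_somatic"
    diploid_idx, aneuploid_idx = _split_cycles(tumor, somatic_mu, config)
    if not diploid_idx:
        return somatic_mu, "matched_somatic"
    internal = max(diploid_idx, key=lambda i: tumor.cycles[i].cycle_fraction)
    internal_cycle = tumor.cycles[internal]
    if internal_cycle.cv_g1 > config.cv_threshold:
        return somatic_mu, "matched_somatic"
    aneuploid_share = sum(tumor.cycles[i].cycle_fraction for i in aneuploid_idx)
    if aneuploid_idx and (
        aneuploid_share <= config.minor_threshold or tumor.ambiguous
    ):
        return internal_cycle.mu_g1, "predominant_diploid"
    return internal_cycle.mu_g1, "internal_diploid"


def compute_dna_index(tumor_peak: float, reference_peak: float) -> float:
    """DNA index: tumor G0/G1 peak channel over the diploid reference channel."""
    if not tumor_peak > 0 or not reference_peak > 0:
        raise ValueError(
            f"peak channels must be positive, got tumor={tumor_peak}, "
            f"reference={reference_peak}"
        )
    return tumor_peak / reference_peak


def classify_ploidy(
    di: float | None,
    n_aneuploid_peaks: int = 1,
    config: PloidyConfig = PloidyConfig(),
) -> str:
    """Ploidy category from the DNA index and the distinct-peak count."""
    if n_aneuploid_peaks >= 2:
        return "complex_aneuploid"
    if di is None:
        raise ValueError("DNA index undefined but tumor does not have multiple peaks")
    d, dt = config.diploid_delta, config.tetraploid_delta
    if di < 1.0 - d:
        return "hypodiploid_aneuploid"
    if di <= 1.0 + d:
        return "diploid"
    if 2.0 - dt <= di <= 2.0 + dt:
        return "tetraploid_aneuploid"
    return "hyperdiploid_aneuploid"


def _distinct_aneuploid_peaks(
    peaks: list[tuple[float, float]],
    somatic_mu: float,
    sigma: float,
    config: PloidyConfig,
) -> list[float]:
    """Channels of distinct non-diploid, non-harmonic G0/G1 peaks."""
    prim = primary_peaks(peaks, ratio_tol=config.harmonic_tol)
    aneu: list[float] = []
    for ch, _h in prim:
        if abs(ch / somatic_mu - 1.0) <= config.match_tol:
            continue
        if any(abs(ch - other) <= config.distinct_sigmas * sigma for other in aneu):
            continue
        # a peak at ~2x the somatic channel may be the diploid G2/M: kept here,
        # arbitrated by model comparison in call_pair
        aneu.append(ch)
    return aneu


def call_pair(pair: SpecimenPair, config: PloidyConfig = PloidyConfig()) -> PloidyCall:
    """Run exclusions -> reference selection -> DNA index -> category."""
    flags = apply_exclusions(pair, config)
    if "excluded" in flags:
        return PloidyCall(
            fish_id=pair.fish_id,
            dna_index=None,
            category=None,
            reference_source=None,
            qc_flags=flags,
        )
    tumor, som = pair.tumor_fit, pair.somatic_fit
    if tumor is None:
        flags |= {"insufficient_events", "excluded"}
        return PloidyCall(
            fish_id=pair.fish_id,
            dna_index=None,
            category=None,
            reference_source=None,
            qc_flags=flags,
        )
    somatic_mu = som.cycles[som.predominant_cycle].mu_g1
    sigma = som.cycles[som.predominant_cycle].cv_g1 / 100.0 * somatic_mu

    if pair.tumor_hist is not None:
        peaks = detect_g1_peaks(pair.tumor_hist)
        aneu_peaks = _distinct_aneuploid_peaks(peaks, somatic_mu, sigma, config)
    else:
        aneu_peaks = [
            c.mu_g1
            for i, c in enumerate(tumor.cycles)
            if i not in _split_cycles(tumor, somatic_mu, config)[0]
        ]
    if len(aneu_peaks) >= 2:
        return PloidyCall(
            fish_id=pair.fish_id,
            dna_index=None,
            category="complex_aneuploid",
            reference_source=None,
            qc_flags=flags,
        )

    reference, source = select_reference(pair, config)
    diploid_idx, aneuploid_idx = _split_cycles(tumor, somatic_mu, config)
    if tumor.ambiguous:
        flags.add("ambiguous_g2m_vs_aneuploid")
    if source == "predominant_diploid":
        if not tumor.ambiguous:
            flags.add("minor_aneuploid_le_20pct")
        # index the predominant diploid population against the somatic peak
        tumor_peak = reference
        reference = somatic_mu
    elif aneuploid_idx:
        major = max(aneuploid_idx, key=lambda i: tumor.cycles[i].cycle_fraction)
        tumor_peak = tumor.cycles[major].mu_g1
    else:
        tumor_peak = tumor.cycles[tumor.predominant_cycle].mu_g1
    di = compute_dna_index(tumor_peak, reference)
    category = classify_ploidy(di, n_aneuploid_peaks=len(aneu_peaks), config=config)
    return PloidyCall(
        fish_id=pair.fish_id,
        dna_index=di,
        category=category,
        reference_source=source,
        qc_flags=flags,
    )


def _fit_tumor_with_arbitration(
    hist: DNAHistogram,
    somatic_mu: float,
    sigma: float,
    config: PloidyConfig,
) -> CellCycleFit:
    """Fit the tumor histogram, arbitrating aneuploid-G1 vs diploid-G2/M.

    A detected peak near twice the somatic channel alongside a diploid peak can
    be modeled either as a second cycle's G0/G1 or as the diploid cycle's G2/M;
    both topologies are fitted and the lower reduced chi-square wins.  A gap
    below ``ambiguity_delta_rcs`` marks the fit ambiguous, which routes the
    call through the predominant-diploid rule.
    """
    peaks = detect_g1_peaks(hist)
    prim = primary_peaks(peaks, ratio_tol=config.harmonic_tol)
    near_somatic = lambda ch: abs(ch / somatic_mu - 1.0) <= config.match_tol
    near_double_somatic = lambda ch: (
        abs(ch / (2.0 * somatic_mu) - 1.0) <= config.match_tol
    )
    has_diploid = any(near_somatic(ch) for ch, _ in peaks)
    # the ~2x-somatic condition is judged on the RAW peak list: a genuine
    # aneuploid G0/G1 near twice the diploid channel is broadened (sd scales
    # with DNA content) and can fall below any height-based harmonic heuristic
    near_double = [ch for ch, _ in peaks if near_double_somatic(ch)]

    def harmonic_of_raw(ch, h):
        return any(
            p < ch
            and abs(ch / (2.0 * p) - 1.0) <= config.harmonic_tol
            and h < hp
            for p, hp in peaks
        )

    others = [
        ch
        for ch, h in peaks
        if not near_somatic(ch)
        and not near_double_somatic(ch)
        and not harmonic_of_raw(ch, h)
    ]

    if has_diploid and near_double and not others:
        # topology A: diploid cycle only (the 2x peak is its G2/M)
        # topology B: diploid cycle + aneuploid cycle at ~2x
        try:
            fit_a = fit_cell_cycle(hist, 1, init=[somatic_mu])
        except FitError as err:
            fit_a = err.partial
        try:
            fit_b = fit_cell_cycle(hist, 2, init=[somatic_mu, near_double[0]])
        except FitError as err:
            fit_b = err.partial
        if fit_a is None and fit_b is None:
            raise FitError("tumor fit failed under both topologies")
        if fit_b is None:
            return fit_a
        if fit_a is None:
            return fit_b
        delta = abs(fit_a.rcs - fit_b.rcs)
        fit = fit_b if fit_b.rcs < fit_a.rcs else fit_a
        if delta < config.ambiguity_delta_rcs:
            fit.ambiguous = True
        return fit

    n_cycles = min(max(len(prim), 1), 3)
    init = sorted(ch for ch, _ in sorted(prim, key=lambda p: -p[1])[:n_cycles])
    if not init:
        init = [somatic_mu]
        n_cycles = 1
    return fit_cell_cycle(hist, n_cycles, init=init)


def call_from_events(
    tumor_events: pd.DataFrame,
    somatic_events: pd.DataFrame,
    fish_id: str = "pair",
    config: PloidyConfig = PloidyConfig(),
    gate_config=None,
    bins: int = 512,
) -> PloidyCall:
    """End-to-end call from two event tables: gate, fit, and run the tree."""
    from .gating import GateConfig, gate_debris, gate_singlets

    gc = gate_config or GateConfig()
    tum = gate_debris(gate_singlets(tumor_events, gc), gc)
    som = gate_debris(gate_singlets(somatic_events, gc), gc)
    som_hist = make_histogram(som, bins=bins)
    tum_hist = make_histogram(tum, bins=bins)
    try:
        som_fit = fit_cell_cycle(som_hist, 1)
    except (FitError, ValueError):
        som_fit = None
    pair = SpecimenPair(
        fish_id=fish_id,
        somatic_fit=som_fit,
        somatic_hist=som_hist,
        tumor_hist=tum_hist,
    )
    if som_fit is not None:
        somatic_mu = som_fit.cycles[som_fit.predominant_cycle].mu_g1
        sigma = som_fit.cycles[som_fit.predominant_cycle].cv_g1 / 100.0 * somatic_mu
        try:
            pair.tumor_fit = _fit_tumor_with_arbitration(
                tum_hist, somatic_mu, sigma, config
            )
        except (FitError, ValueError):
            pair.tumor_fit = None
    return call_pair(pair, config)
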