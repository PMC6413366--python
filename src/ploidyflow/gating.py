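"""Event gating and marker-gate quantification of DNA-content compartments.

Reproduces the standard strategy for whole-testis DNA profiles: a singlet gate
on the FSC-H/FSC-A pulse ratio (doublets have suppressed height), a debris
threshold on PI-A and FSC-A, then channel-interval "marker" gates that count
events in the 1C, 2C, S and 4C compartments of a PI-H histogram without model
fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_widths

from .cellcycle import DNAHistogram, make_histogram

log = logging.getLogger(__name__)

__all__ = [
    "GateConfig",
    "CompartmentFractions",
    "gate_singlets",
    "gate_debris",
    "place_markers",
    "quantify_compartments",
    "make_histogram",
]

COMPARTMENTS = ("1C", "2C", "S", "4C")


class SchemaError(ValueError):
    """The event table is missing a required column."""


@dataclass
class GateConfig:
    """Gating parameters.

    ``singlet_ratio_band`` bounds FSC-H/FSC-A for singlets; ``pia_threshold``
    and ``fsca_threshold`` drop low-PI-A / low-FSC-A debris; ``markers`` maps
    compartment names to half-open channel intervals [lo, hi) on PI-H.
    """

    singlet_ratio_band: tuple[float, float] = (0.7, 0.9)
    pia_threshold: float = 0.0
    fsca_threshold: float = 0.0
    markers: dict[str, tuple[float, float]] | None = None
    marker_halfwidth_sigmas: float = 2.5

    def validate_markers(self) -> None:
        if self.markers is None:
            raise ValueError("markers are not defined; run place_markers first")
        intervals = sorted(self.markers.values())
        for (lo, hi) in intervals:
            if not lo < hi:
                raise ValueError(f"marker interval [{lo}, {hi}) is empty or inverted")
        for (_, hi_prev), (lo_next, _) in zip(intervals, intervals[1:]):
            if lo_next < hi_prev:
                raise ValueError("marker intervals overlap")

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, d: dict) -> "GateConfig":
        d = dict(d)
        if d.get("markers"):
            d["markers"] = {k: tuple(v) for k, v in d["markers"].items()}
        if "singlet_ratio_band" in d:
            d["singlet_ratio_band"] = tuple(d["singlet_ratio_band"])
        return cls(**d)


@dataclass
class CompartmentFractions:
    """Percentages of gated events in each DNA-content compartment."""

    pct_1C: float
    pct_2C: float
    pct_S: float
    pct_4C: float
    n_gated: int

    def as_dict(self) -> dict[str, float]:
        return {
            "1C": self.pct_1C,
            "2C": self.pct_2C,
            "S": self.pct_S,
            "4C": self.pct_4C,
        }


def _require(events: pd.DataFrame, columns: tuple[str, ...]) -> None:
    missing = [c for c in columns if c not in events.columns]
    if missing:
        raise SchemaError(f"event table is missing column(s): {missing}")


def _annotate(events: pd.DataFrame, gate: str, kept: int, dropped: int) -> pd.DataFrame:
    prov = list(events.attrs.get("gates", []))
    prov.append({"gate": gate, "kept": kept, "dropped": dropped})
    events.attrs["gates"] = prov
    return events


def gate_singlets(events: pd.DataFrame, config: GateConfig) -> pd.DataFrame:
    """Retain events whose FSC-H/FSC-A ratio falls inside the singlet band.

    Rows with FSC-A == 0 are excluded and counted in the gate report.  Row
    order is preserved; gate provenance is attached to ``DataFrame.attrs``.
    """
    _require(events, ("FSC-A", "FSC-H"))
    if len(events) == 0:
        warnings.warn("gate_singlets: empty event table")
        return _annotate(events.copy(), "singlets", 0, 0)
    lo, hi = config.singlet_ratio_band
    fsc_a = events["FSC-A"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fsc_a > 0, events["FSC-H"].to_numpy(float) / fsc_a, np.nan)
    keep = (ratio >= lo) & (ratio <= hi)
    out = events.loc[keep].copy()
    return _annotate(out, "singlets", int(keep.sum()), int(len(events) - keep.sum()))


def gate_debris(events: pd.DataFrame, config: GateConfig) -> pd.DataFrame:
    """Drop low-PI-A / low-FSC-A events below the configured thresholds."""
    _require(events, ("PI-A", "FSC-A"))
    if len(events) == 0:
        warnings.warn("gate_debris: empty event table")
        return _annotate(events.copy(), "debris", 0, 0)
    keep = (events["PI-A"].to_numpy(float) >= config.pia_threshold) & (
        events["FSC-A"].to_numpy(float) >= config.fsca_threshold
    )
    out = events.loc[keep].copy()
    if len(out) == 0:
        warnings.warn("gate_debris: all events fell below the threshold")
    return _annotate(out, "debris", int(keep.sum()), int(len(events) - keep.sum()))


def _peak_sigma(hist: DNAHistogram, peak_bin: int, counts_s: np.ndarray) -> float:
    """Gaussian sigma estimate from the smoothed peak's FWHM."""
    widths = peak_widths(counts_s, [peak_bin], rel_height=0.5)[0]
    bin_w = hist.bin_edges[1] - hist.bin_edges[0]
    fwhm = max(widths[0], 1.0) * bin_w
    return fwhm / 2.3548


def detect_histogram_peaks(
    hist: DNAHistogram,
    smooth_bins: int = 5,
    prominence_frac: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moving-average smoothing followed by prominence-filtered local maxima.

    Returns (channels, heights, sigmas) sorted by channel; ties in height
    break toward the lower channel by construction of the scan order.
    """
    counts = hist.counts.astype(float)
    if counts.sum() == 0:
        return np.array([]), np.array([]), np.array([])
    kernel = np.ones(smooth_bins) / smooth_bins
    half = smooth_bins // 2
    padded = np.pad(counts, half, mode="edge")
    smoothed = np.convolve(padded, kernel, mode="valid")[: len(counts)]
    prominence = prominence_frac * smoothed.max()
    idx, _ = find_peaks(smoothed, prominence=prominence)
    centers = hist.centers
    sigmas = np.array([_peak_sigma(hist, i, smoothed) for i in idx])
    return centers[idx], smoothed[idx], sigmas


def place_markers(
    hist: DNAHistogram,
    anchor_2c: float | None = None,
    k_sigma: float = 2.5,
    ratio_tol: float = 0.1,
) -> dict[str, tuple[float, float]]:
    """Place 1C/2C/S/4C marker intervals from histogram peaks.

    Looks for a 1C/2C peak pair with channel ratio ~2 (the haploid compartment
    sits at half the diploid channel); with a supplied ``anchor_2c`` the 2C
    position is taken as given, covering profiles with no 1C population.  The
    4C marker is centered at twice the 2C channel and the S interval spans the
    gap between the 2C and 4C markers.  Intervals are half-open [lo, hi).
    """
    channels, heights, sigmas = detect_histogram_peaks(hist)
    if anchor_2c is None:
        if len(channels) < 2:
            raise ValueError(
                "could not resolve a 1C/2C peak pair; supply anchor_2c to place "
                "markers manually"
            )
        best = None
        for i in range(len(channels)):
            for j in range(i + 1, len(channels)):
                r = channels[j] / channels[i]
                if abs(r - 2.0) <= 2.0 * ratio_tol:
                    score = heights[i] + heights[j]
                    if best is None or score > best[0]:
                        best = (score, i, j)
        if best is None:
            raise ValueError(
                "no peak pair with channel ratio ~2 found; supply anchor_2c"
            )
        _, i1, i2 = best
        c1, s1 = channels[i1], sigmas[i1]
        c2, s2 = channels[i2], sigmas[i2]
    else:
        c2 = float(anchor_2c)
        if len(channels):
            near = np.argmin(np.abs(channels - c2))
            s2 = sigmas[near] if abs(channels[near] - c2) < 0.2 * c2 else 0.04 * c2
        else:
            s2 = 0.04 * c2
        c1, s1 = c2 / 2.0, s2 / 2.0

    c4 = 2.0 * c2
    # prefer the measured width of a detected peak near 2x the 2C channel;
    # G2/M peaks broaden less than a doubling of the G1 width in practice
    s4 = s2
    if len(channels):
        near4 = np.argmin(np.abs(channels - c4))
        if abs(channels[near4] - c4) < 0.1 * c4:
            s4 = sigmas[near4]
    m1 = (c1 - k_sigma * s1, c1 + k_sigma * s1)
    m2 = (c2 - k_sigma * s2, c2 + k_sigma * s2)
    m4 = (c4 - k_sigma * s4, c4 + k_sigma * s4)
    # clip any 1C/2C overlap at the midpoint between peaks
    if m1[1] > m2[0]:
        mid = (c1 + c2) / 2.0
        m1 = (m1[0], mid)
        m2 = (mid, m2[1])
    ms = (m2[1], m4[0])
    if not ms[0] < ms[1]:
        mid = (c2 + c4) / 2.0
        m2 = (m2[0], mid)
        m4 = (mid, m4[1])
        ms = (m2[1], m4[0])
        log.warning("place_markers: 2C and 4C markers abut; S interval is empty")
    return {
        "1C": (max(m1[0], 0.0), m1[1]),
        "2C": m2,
        "S": ms,
        "4C": m4,
    }


def quantify_compartments(
    events: pd.DataFrame, config: GateConfig
) -> CompartmentFractions:
    """Percent of gated events whose PI-H falls in each marker interval.

    Half-open [lo, hi) convention; events between markers count toward
    ``n_gated`` but no compartment, so percentages may sum below 100.
    """
    _require(events, ("PI-H",))
    config.validate_markers()
    pi = events["PI-H"].to_numpy(float)
    n = len(pi)
    pct = {}
    for name in COMPARTMENTS:
        lo, hi = config.markers.get(name, (0.0, 0.0))
        inside = np.count_nonzero((pi >= lo) & (pi < hi))
        pct[name] = 100.0 * inside / n if n else 0.0
    return CompartmentFractions(
        pct_1C=pct["1C"],
        pct_2C=pct["2C"],
        pct_S=pct["S"],
        pct_4C=pct["4C"],
        n_gated=n,
    )
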