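"""Univariate DNA-histogram deconvolution: 1-3 cell cycles plus debris.

Model class
-----------
Each cell cycle contributes a Gaussian G0/G1 peak at channel ``mu`` with
standard deviation ``cv/100 * mu``, a Gaussian G2/M peak at ``g2_ratio * mu``
(ratio bounded to [1.85, 2.10]; the biological value is ~2 with an allowance
for dye/instrument nonlinearity), and a zero-order S phase: a constant density
between the two peaks convolved with the G1 Gaussian width.  Debris from
sliced/fragmented nuclei is modeled by an arcsine fragment-size kernel: a
fragment of a parent nucleus of content m carries content m*B with
B ~ p(b) = 1/(pi*sqrt(b(1-b))) on (0, 1), so the per-bin debris mass has the
closed form (2/pi)*(asin(sqrt(hi/m)) - asin(sqrt(lo/m))).  The kernel is
applied to the fitted cycle peaks (and the S midpoint) with one amplitude
parameter.  The exact background formula of commercial packages is
proprietary; this kernel carries the same "sliced nuclei" construction and is
swappable.

Parameters are estimated by bounded nonlinear least squares on binned counts
with Poisson-motivated weights 1/sqrt(max(count, 1)); goodness of fit is the
reduced chi-square over bins with expected count >= 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import ndtr  # Gaussian CDF, vectorized

__all__ = [
    "DNAHistogram",
    "CellCycleFit",
    "make_histogram",
    "detect_g1_peaks",
    "primary_peaks",
    "fit_cell_cycle",
    "peak_cv",
    "FitError",
]

G2_RATIO_BOUNDS = (1.85, 2.10)
CV_BOUNDS = (0.5, 15.0)
DEFAULT_BINS = 1024
MIN_EVENTS_DEFAULT = 1000


class FitError(RuntimeError):
    """Deconvolution failed; ``partial`` carries the best fit reached."""

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial


@dataclass
class DNAHistogram:
    """Binned PI-H signal with half-open [lo, hi) bins."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.counts = np.asarray(self.counts)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("len(counts) must equal len(bin_edges) - 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": self.centers, "count": self.counts})


def make_histogram(
    data, bins: int = DEFAULT_BINS, upper: float | None = None
) -> DNAHistogram:
    """Histogram PI-H values into ``bins`` half-open bins over [0, upper].

    ``data`` may be an event DataFrame (uses the PI-H column) or an array.
    Default upper edge is 1.05x the maximum value.
    """
    if isinstance(data, pd.DataFrame):
        values = data["PI-H"].to_numpy(float)
    else:
        values = np.asarray(data, float)
    if len(values) == 0:
        raise ValueError("cannot histogram an empty sample")
    if upper is None:
        upper = 1.05 * float(values.max())
        if upper <= 0:
            upper = 1.0
    edges = np.linspace(0.0, upper, bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return DNAHistogram(bin_edges=edges, counts=counts)


@dataclass
class CycleParams:
    """Fitted parameters of one cell cycle."""

    mu_g1: float
    cv_g1: float
    g2_ratio: float
    frac_g1: float
    frac_s: float
    frac_g2m: float
    cycle_fraction: float


@dataclass
class CellCycleFit:
    """Result of a 1-3 cycle deconvolution."""

    cycles: list[CycleParams]
    debris_fraction: float
    rcs: float
    n_events_fit: int
    n_free_params: int = 0
    converged: bool = True
    ambiguous: bool = False

    def __post_init__(self):
        assert abs(sum(c.cycle_fraction for c in self.cycles) - 1.0) <= 1e-6
        for c in self.cycles:
            assert abs(c.frac_g1 + c.frac_s + c.frac_g2m - 1.0) <= 1e-6
            assert c.cv_g1 > 0
        mus = [c.mu_g1 for c in self.cycles]
        assert all(a < b for a, b in zip(mus, mus[1:])), "mu_g1 not increasing"
        assert 0.0 <= self.debris_fraction < 1.0
        assert self.rcs >= 0

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def predominant_cycle(self) -> int:
        return int(np.argmax([c.cycle_fraction for c in self.cycles]))

    def to_json(self) -> dict:
        return {
            "cycles": [vars(c) for c in self.cycles],
            "debris_fraction": self.debris_fraction,
            "rcs": self.rcs,
            "n_events_fit": self.n_events_fit,
            "n_free_params": self.n_free_params,
            "converged": self.converged,
            "ambiguous": self.ambiguous,
        }

    @classmethod
    def from_json(cls, d: dict) -> "CellCycleFit":
        return cls(
            cycles=[CycleParams(**c) for c in d["cycles"]],
            debris_fraction=d["debris_fraction"],
            rcs=d["rcs"],
            n_events_fit=d["n_events_fit"],
            n_free_params=d.get("n_free_params", 0),
            converged=d.get("converged", True),
            ambiguous=d.get("ambiguous", False),
        )


def peak_cv(fit: CellCycleFit, cycle: int = 0) -> float:
    """Percent CV (100 * sd / mean) of the G0/G1 peak of the given cycle."""
    if not 0 <= cycle < fit.n_cycles:
        raise IndexError(f"cycle {cycle} out of range for a {fit.n_cycles}-cycle fit")
    return fit.cycles[cycle].cv_g1


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

def detect_g1_peaks(
    hist: DNAHistogram,
    smooth_bins: int = 5,
    prominence_frac: float = 0.03,
) -> list[tuple[float, float]]:
    """Candidate G0/G1 peak (channel, height) pairs, ascending by channel.

    The histogram is smoothed with a fixed-width moving average and local
    maxima above a prominence threshold (a fraction of the tallest smoothed
    bin) are returned.  Harmonics (G2/M companions at ~2x) are NOT removed
    here; see :func:`primary_peaks`.
    """
    from .gating import detect_histogram_peaks  # local import: avoid cycle

    channels, heights, _ = detect_histogram_peaks(
        hist, smooth_bins=smooth_bins, prominence_frac=prominence_frac
    )
    return list(zip(channels.tolist(), heights.tolist()))


def primary_peaks(
    peaks: list[tuple[float, float]],
    ratio_tol: float = 0.06,
    height_frac: float = 0.5,
) -> list[tuple[float, float]]:
    """Drop peaks that look like 2x harmonics (G2/M) of a lower peak.

    A G2/M companion sits at ~2x its G0/G1 peak and is much shorter (its
    height scales with the G2/M fraction); a peak at 2x that rivals the lower
    peak's height is more plausibly a genuine tetraploid-range G0/G1 and is
    kept for downstream model arbitration.
    """
    kept: list[tuple[float, float]] = []
    for ch, h in peaks:
        harmonic = any(
            abs(ch / (2.0 * ch0) - 1.0) <= ratio_tol and h < height_frac * h0
            for ch0, h0 in kept
        )
        if not harmonic:
            kept.append((ch, h))
    return kept


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------

def _gauss_bin_mass(edges: np.ndarray, mu: float, sd: float) -> np.ndarray:
    z = (edges - mu) / sd
    cdf = ndtr(z)
    return np.diff(cdf)


def _s_phase_bin_mass(
    centers: np.ndarray, widths: np.ndarray, mu: float, mu2: float, sd: float
) -> np.ndarray:
    # flat density on (mu, mu2) convolved with N(0, sd); midpoint rule per bin
    dens = (ndtr((centers - mu) / sd) - ndtr((centers - mu2) / sd)) / (mu2 - mu)
    return dens * widths


def _debris_bin_mass(edges: np.ndarray, parent: float, sd: float = 0.0) -> np.ndarray:
    frac = np.clip(edges / parent, 0.0, 1.0)
    cdf = (2.0 / np.pi) * np.arcsin(np.sqrt(frac))
    mass = np.diff(cdf)
    if sd > 0:
        # smear the fragment spectrum with the parent peak's Gaussian width,
        # mirroring measurement spread; matters most near the arcsine edge at
        # the parent channel
        bin_w = edges[1] - edges[0]
        half = max(int(np.ceil(4.0 * sd / bin_w)), 1)
        z = np.arange(-half, half + 1) * bin_w
        kernel = np.exp(-0.5 * (z / sd) ** 2)
        kernel /= kernel.sum()
        mass = np.convolve(mass, kernel, mode="same")
    return mass


def _unpack(x: np.ndarray, n_cycles: int):
    a_debris = x[0]
    cycles = []
    for c in range(n_cycles):
        mu, cv, r, a_g1, a_s, a_g2m = x[1 + 6 * c : 7 + 6 * c]
        cycles.append((mu, cv, r, a_g1, a_s, a_g2m))
    return a_debris, cycles


def _model_counts(x: np.ndarray, hist: DNAHistogram, n_cycles: int) -> np.ndarray:
    edges = hist.bin_edges
    centers = hist.centers
    widths = np.diff(edges)
    a_debris, cycles = _unpack(x, n_cycles)
    model = np.zeros(len(centers))
    parents: list[tuple[float, float]] = []  # (channel, weight) for debris kernel
    for mu, cv, r, a_g1, a_s, a_g2m in cycles:
        sd = cv / 100.0 * mu
        mu2 = r * mu
        model += a_g1 * _gauss_bin_mass(edges, mu, sd)
        model += a_g2m * _gauss_bin_mass(edges, mu2, sd)
        model += a_s * _s_phase_bin_mass(centers, widths, mu, mu2, sd)
        parents += [(mu, a_g1, sd), (mu2, a_g2m, sd), (0.5 * (mu + mu2), a_s, sd)]
    wsum = sum(w for _, w, _ in parents)
    if a_debris > 0 and wsum > 0:
        debris = np.zeros(len(centers))
        for ch, w, sd in parents:
            if w > 0:
                debris += (w / wsum) * _debris_bin_mass(edges, ch, sd)
        model += a_debris * debris
    return model


def _fit_once(hist, n_cycles, x0, lb, ub):
    # Stage 1: Poisson-motivated weights 1/sqrt(max(observed, 1)).  Stage 2:
    # reweight by the stage-1 *expected* counts and refit — observed-count
    # weights over-weight downward-fluctuating sparse bins and bias low-density
    # components (S plateau, debris) downward at modest event numbers.
    counts = hist.counts.astype(float)
    n_total = counts.sum()
    res = None
    w = 1.0 / np.sqrt(np.maximum(counts, 1.0))
    for _ in range(2):
        def residuals(x, w=w):
            # soft mass conservation: amplitudes are event counts, and the
            # histogram range covers the data, so components parked outside
            # the range (which would otherwise act as free debris shape via
            # the parent weights) are penalized
            total_amp = x[0] + sum(x[4 + 6 * c : 7 + 6 * c].sum() for c in range(n_cycles))
            mass_pen = (total_amp - n_total) / np.sqrt(max(n_total, 1.0))
            fit_res = (_model_counts(x, hist, n_cycles) - counts) * w
            return np.append(fit_res, mass_pen)

        res = least_squares(
            residuals, x0, bounds=(lb, ub), method="trf",
            xtol=1e-8, ftol=1e-8, gtol=1e-8,
        )
        if not res.success:
            break
        expected = _model_counts(res.x, hist, n_cycles)
        w = 1.0 / np.sqrt(np.maximum(expected, 1.0))
        x0 = res.x
    return res


def fit_cell_cycle(
    hist: DNAHistogram,
    n_cycles: int = 1,
    init: list[float] | None = None,
    fit_s: bool = True,
    fit_debris: bool = True,
    min_events: int = MIN_EVENTS_DEFAULT,
    max_restarts: int = 5,
) -> CellCycleFit:
    """Deconvolve a DNA histogram into ``n_cycles`` cell cycles plus debris.

    ``init`` optionally supplies G0/G1 peak channel guesses (ascending, one
    per cycle); otherwise they are taken from :func:`detect_g1_peaks` after
    harmonic filtering.  Histograms with fewer than ``min_events`` total
    events produce a warning, not an error.  Deterministic given (hist, init).

    Raises :class:`FitError` (carrying the best partial fit) on
    non-convergence after bounded restarts, and ValueError when ``n_cycles``
    exceeds the number of detectable peaks and no ``init`` is given.
    """
    if n_cycles not in (1, 2, 3):
        raise ValueError(f"n_cycles must be 1, 2 or 3, got {n_cycles}")
    n_total = hist.n_total
    if n_total == 0:
        raise ValueError("histogram is empty")
    if n_total < min_events:
        warnings.warn(
            f"only {n_total} events in histogram; at least {min_events} are "
            "recommended for a stable cell-cycle fit"
        )

    if init is None:
        cand = primary_peaks(detect_g1_peaks(hist))
        if len(cand) < n_cycles:
            raise ValueError(
                f"detected only {len(cand)} candidate G0/G1 peak(s) but "
                f"n_cycles={n_cycles}; supply init or reduce n_cycles"
            )
        # strongest n_cycles candidates, ascending by channel
        cand = sorted(sorted(cand, key=lambda p: -p[1])[:n_cycles])
        init = [ch for ch, _ in cand]
    if len(init) != n_cycles:
        raise ValueError("init must supply one peak guess per cycle")
    init = sorted(float(v) for v in init)

    upper = hist.bin_edges[-1]
    x0, lb, ub = [0.0], [0.0], [np.inf]
    if not fit_debris:
        ub[0] = 1e-12
    for mu0 in init:
        guess_counts = max(n_total / n_cycles, 1.0)
        x0 += [mu0, 4.0, 2.0, 0.7 * guess_counts, 0.1 * guess_counts, 0.2 * guess_counts]
        lb += [0.7 * mu0, CV_BOUNDS[0], G2_RATIO_BOUNDS[0], 0.0, 0.0, 0.0]
        ub += [
            min(1.3 * mu0, upper),
            CV_BOUNDS[1],
            G2_RATIO_BOUNDS[1],
            np.inf,
            1e-12 if not fit_s else np.inf,
            np.inf,
        ]
    x0[0] = 0.05 * n_total if fit_debris else 0.0
    x0 = np.minimum(np.maximum(np.array(x0), lb), ub)
    lb, ub = np.array(lb), np.array(ub)

    rng = np.random.default_rng(0)  # deterministic restart jitter
    best = None
    for attempt in range(max_restarts + 1):
        try:
            res = _fit_once(hist, n_cycles, x0, lb, ub)
        except Exception:
            res = None
        if res is not None and (best is None or res.cost < best.cost):
            best = res
        if res is not None and res.success:
            break
        jitter = rng.normal(1.0, 0.03, size=len(x0))
        x0 = np.minimum(np.maximum(x0 * jitter, lb), ub)

    if best is None:
        raise FitError("cell-cycle fit failed on every restart")
    fit = _result_to_fit(best, hist, n_cycles)
    if not best.success:
        raise FitError(
            "cell-cycle fit did not converge within the restart budget",
            partial=fit,
        )
    return fit


def _result_to_fit(res, hist: DNAHistogram, n_cycles: int) -> CellCycleFit:
    counts = hist.counts.astype(float)
    a_debris, cycles_raw = _unpack(res.x, n_cycles)
    amp_nondebris = sum(a_g1 + a_s + a_g2m for _, _, _, a_g1, a_s, a_g2m in cycles_raw)
    total = amp_nondebris + a_debris
    cycles: list[CycleParams] = []
    for mu, cv, r, a_g1, a_s, a_g2m in sorted(cycles_raw, key=lambda c: c[0]):
        csum = a_g1 + a_s + a_g2m
        if csum <= 0:
            csum = 1.0
        cycles.append(
            CycleParams(
                mu_g1=float(mu),
                cv_g1=float(cv),
                g2_ratio=float(r),
                frac_g1=float(a_g1 / csum),
                frac_s=float(a_s / csum),
                frac_g2m=float(a_g2m / csum),
                cycle_fraction=float((a_g1 + a_s + a_g2m) / max(amp_nondebris, 1e-300)),
            )
        )
    # renormalize cycle fractions against accumulated float error
    cf = np.array([c.cycle_fraction for c in cycles])
    for c, v in zip(cycles, cf / cf.sum()):
        c.cycle_fraction = float(v)

    model = _model_counts(res.x, hist, n_cycles)
    mask = model >= 1.0
    n_free = len(res.x)
    dof = max(int(mask.sum()) - n_free, 1)
    chi2 = float(np.sum((model[mask] - counts[mask]) ** 2 / model[mask]))
    return CellCycleFit(
        cycles=cycles,
        debris_fraction=float(a_debris / max(total, 1e-300)),
        rcs=chi2 / dof,
        n_events_fit=hist.n_total,
        n_free_params=n_free,
        converged=bool(res.success),
    )
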