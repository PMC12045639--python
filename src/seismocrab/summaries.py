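"""Descriptive statistics, data-hygiene filters, and parameter-recovery
regressions.

Covers the derived morphology covariates (claw size = claw width × length,
carapace size likewise), the redundant-variable correlation screen (|r| ≥
0.70), the middle-90% outlier trim, the erroneous-recording exclusion rate,
the ±3 s wind-mean window, log–log attenuation and log-linear wind-noise
regressions, and an automated decay-over-distance interference flag.

Mixed-effects modelling is deliberately left to external statistics tooling:
the tables emitted here stay keyed by burrow/crab id so repeated-measures
structure is preserved downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .core_io import MorphoRecord, WindSeries
from .features import summed_energy
from .windowing import SignalWindow


def exclusion_rate(n_excluded: int, n_retained: int) -> float:
    """Erroneous-recording exclusion rate, %, as 100 × excluded/retained,
    rounded to 1 decimal place (311 excluded against 8207 retained → 3.8)."""
    if n_retained <= 0:
        raise ValueError("n_retained must be positive")
    if n_excluded < 0:
        raise ValueError("n_excluded must be non-negative")
    return round(100.0 * n_excluded / n_retained, 1)


@dataclass
class DerivedMorphology:
    claw_size: float  # mm², claw width × length
    carapace_size: float  # mm², carapace width × length


def morpho_sizes(record: MorphoRecord) -> DerivedMorphology:
    """Derived size covariates: products of the two claw and the two
    carapace dimensions."""
    for name in ("claw1", "claw2", "car1", "car2"):
        v = getattr(record, name)
        if v is None or not v > 0:
            raise ValueError(f"{name} must be present and positive")
    return DerivedMorphology(
        claw_size=record.claw1 * record.claw2,
        carapace_size=record.car1 * record.car2,
    )


def correlation_screen(
    variables: dict[str, np.ndarray],
    threshold: float = 0.70,
    priority: Sequence[str] = (),
):
    """Drop one variable of every strongly correlated pair (Pearson |r| ≥
    ``threshold``).

    ``priority`` orders the variables by preference; earlier names win a
    correlated pair (unlisted variables rank after listed ones, in input
    order).  Returns ``(retained_names, report)`` where report lists
    ``(kept, dropped, r)`` per screened pair.
    """
    names = list(variables)
    if len(names) < 2:
        raise ValueError("need at least two variables to screen")
    arrs = {k: np.asarray(v, dtype=float) for k, v in variables.items()}
    n0 = len(arrs[names[0]])
    for k, v in arrs.items():
        if len(v) != n0:
            raise ValueError("variables must have equal length")
        if np.var(v) == 0:
            raise ValueError(f"variable {k!r} has zero variance")

    def rank(name: str) -> tuple:
        return (priority.index(name) if name in priority else len(priority),
                names.index(name))

    retained = set(names)
    report = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r = float(np.corrcoef(arrs[a], arrs[b])[0, 1])
            if abs(r) >= threshold:
                keep, drop = sorted((a, b), key=rank)
                report.append((keep, drop, r))
                if keep in retained:
                    retained.discard(drop)
    return [n for n in names if n in retained], report


def trim_middle_90(values) -> np.ndarray:
    """Retain values inside the closed [5th, 95th] percentile interval
    (linear-interpolation quantiles) — the middle-90% outlier trim."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    lo, hi = np.percentile(values, [5, 95])
    return values[(values >= lo) & (values <= hi)]


def mean_wind_around(event_time: float, wind: WindSeries, half_window: float = 3.0) -> float:
    """Mean wind speed from ``half_window`` s before to after the event
    (closed interval, default ±3 s)."""
    sel = (wind.times >= event_time - half_window) & (
        wind.times <= event_time + half_window
    )
    if not sel.any():
        raise ValueError(
            f"no wind samples within ±{half_window} s of t={event_time}"
        )
    return float(np.mean(wind.speeds[sel]))


@dataclass
class SlopeFit:
    """A simple-regression slope with its standard error."""

    slope: float
    stderr: float
    intercept: float
    n: int

    def within(self, target: float, n_se: float = 2.0) -> bool:
        return abs(self.slope - target) <= n_se * self.stderr


def _ols_slope(x: np.ndarray, y: np.ndarray) -> SlopeFit:
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return SlopeFit(
        slope=float(fit.params[1]),
        stderr=float(fit.bse[1]),
        intercept=float(fit.params[0]),
        n=len(y),
    )


def fit_attenuation(energies, distances_cm) -> SlopeFit:
    """OLS of log(energy) on log(distance).  Under a power law
    E ∝ d^(−α) the slope estimates −α."""
    energies = np.asarray(energies, dtype=float)
    distances_cm = np.asarray(distances_cm, dtype=float)
    if len(np.unique(distances_cm)) < 3:
        raise ValueError("need at least 3 distinct distances")
    if np.any(energies <= 0) or np.any(distances_cm <= 0):
        raise ValueError("energies and distances must be positive")
    return _ols_slope(np.log(distances_cm), np.log(energies))


def fit_wind_noise(noise_energies, wind_speeds) -> SlopeFit:
    """OLS of log(noise energy) on wind speed; the slope is the log-linear
    wind effect on background noise."""
    noise_energies = np.asarray(noise_energies, dtype=float)
    wind_speeds = np.asarray(wind_speeds, dtype=float)
    if len(noise_energies) < 3:
        raise ValueError("need at least 3 points")
    if np.any(noise_energies <= 0):
        raise ValueError("energies must be positive")
    return _ols_slope(wind_speeds, np.log(noise_energies))


def flag_interference(close_window: SignalWindow, far_window: SignalWindow) -> bool:
    """Automated surrogate for the manual interference screen: flag a
    recording when the far pair carries strictly more summed energy than the
    close pair, violating decay over distance for a signaller at the burrow.

    Best-effort heuristic — it approximates, not reproduces, the original
    video-based screening.
    """
    far = normalize_far_energy(far_window)
    return far > summed_energy(close_window)


def normalize_far_energy(far_window: SignalWindow) -> float:
    """Summed normalised energy of the far pair of a window."""
    for key in ("far_low", "far_high"):
        if key not in far_window.segments:
            raise ValueError(f"window missing channel {key}")
    from .features import normalized_energy

    return normalized_energy(far_window.segments["far_low"]) + normalized_energy(
        far_window.segments["far_high"]
    )
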