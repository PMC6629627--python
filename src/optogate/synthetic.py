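"""Synthetic-data generators with known ground truth.

Every input the characterization pipeline consumes can be generated
here from explicit distributions and integer seeds:

* :func:`gen_events` — one cytometry sample: event-level reporter
  fluorescence drawn lognormal around a condition-dependent median,
  plus an additive lognormal autofluorescence component, with an
  elliptical (FSC, SSC) cell cluster and an optional uniform
  debris/background fraction.
* :func:`gen_bead_sample` — a multi-peak calibration-bead sample with a
  known channel gain, returned alongside the true mapping.
* :func:`gen_dose_response` — replicate sample medians on a Hill curve
  with multiplicative lognormal day-to-day noise.
* :func:`gen_step_experiment` — step ON/OFF timecourse medians from the
  closed-form delayed-cascade trajectory, with the same replicate noise.

Lognormal components are parameterized by median m and coefficient of
variation cv: the underlying normal has mu = ln(m) and
sigma = sqrt(ln(1 + cv^2)), so the median is exactly m and the CV
exactly cv. All generators consume an explicit integer seed; none touch
global random state, and identical spec + seed gives bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cytometry import EventTable
from .hill import HillParams, hill_eval
from .kinetics import KineticParams, closed_form_step

__all__ = [
    "EventGenSpec",
    "DoseResponseDesign",
    "StepDesign",
    "gen_events",
    "gen_bead_sample",
    "gen_dose_response",
    "gen_step_experiment",
]


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _median_lognormal(rng: np.random.Generator, median: float, cv: float, n: int):
    """Lognormal draws with exact median ``median`` and CV ``cv``."""
    if median == 0.0:
        return np.zeros(n)
    return median * np.exp(rng.normal(0.0, _lognormal_sigma(cv), n))


@dataclass(frozen=True)
class EventGenSpec:
    """One synthetic cytometry sample.

    ``median_fluorescence`` is the median of the reporter component
    (i.e. the median after autofluorescence subtraction);
    ``autofluorescence_median`` is added per event. ``scatter_spread``
    is the relative sd of the elliptical (FSC, SSC) cluster and
    ``background_fraction`` the share of events drawn uniformly over
    the scatter range instead (debris stand-in).
    """

    n_events: int
    median_fluorescence: float
    event_cv: float = 0.3
    autofluorescence_median: float = 0.0
    scatter_center: tuple[float, float] = (500.0, 300.0)
    scatter_spread: float = 0.12
    background_fraction: float = 0.0
    seed: int = 0
    channel: str = "fl1"

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not np.isfinite(self.event_cv) or self.event_cv <= 0:
            raise ValueError("event_cv must be finite and > 0")
        for name in ("median_fluorescence", "autofluorescence_median"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not (0.0 <= self.background_fraction < 1.0):
            raise ValueError("background_fraction must be in [0, 1)")


def gen_events(spec: EventGenSpec) -> EventTable:
    """Draw one event table per the spec; reproducible given the seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events
    reporter = _median_lognormal(rng, spec.median_fluorescence, spec.event_cv, n)
    auto = _median_lognormal(rng, spec.autofluorescence_median, spec.event_cv, n)
    fl = reporter + auto

    fx, fy = spec.scatter_center
    n_bg = int(np.floor(spec.background_fraction * n))
    n_cl = n - n_bg
    fsc = np.concatenate([
        rng.normal(fx, spec.scatter_spread * fx, n_cl),
        rng.uniform(0.0, 4.0 * fx, n_bg),
    ])
    ssc = np.concatenate([
        rng.normal(fy, spec.scatter_spread * fy, n_cl),
        rng.uniform(0.0, 4.0 * fy, n_bg),
    ])
    df = pd.DataFrame({
        "event_id": np.arange(n),
        "fsc": fsc,
        "ssc": ssc,
        spec.channel: fl,
    })
    return EventTable(
        data=df,
        sample_id=f"synth-{spec.seed}",
        metadata={
            "truth_median": spec.median_fluorescence,
            "truth_autofluorescence": spec.autofluorescence_median,
            "background_fraction": spec.background_fraction,
        },
    )


def gen_bead_sample(
    peak_true_values,
    channel_gain: float = 0.05,
    channel_offset: float = 0.0,
    peak_cv: float = 0.05,
    events_per_peak: int = 2000,
    seed: int = 0,
    exponent: float = 1.0,
    channel: str = "fl1",
) -> tuple[EventTable, dict]:
    """Calibration-bead sample with a known channel mapping.

    Each bead peak of true value v sits at channel position
    ``offset + gain * v**exponent`` (the default exponent 1 is a
    straight line in log-log space when offset is 0) with lognormal
    spread ``peak_cv``. Returns the event table and a truth record with
    the mapping and the noise-free peak positions.
    """
    vals = np.asarray(peak_true_values, dtype=float)
    if len(vals) < 2:
        raise ValueError("calibration is underdetermined with < 2 bead peaks")
    if np.any(vals <= 0) or np.any(np.diff(vals) <= 0):
        raise ValueError("peak values must be positive and strictly increasing")
    if channel_gain <= 0:
        raise ValueError("channel_gain must be > 0")
    rng = np.random.default_rng(seed)
    centers = channel_offset + channel_gain * vals**exponent
    fl = np.concatenate([
        c * np.exp(rng.normal(0.0, _lognormal_sigma(peak_cv), events_per_peak))
        if peak_cv > 0 else np.full(events_per_peak, c)
        for c in centers
    ])
    n = len(fl)
    df = pd.DataFrame({
        "event_id": np.arange(n),
        "fsc": rng.normal(400.0, 30.0, n),
        "ssc": rng.normal(250.0, 20.0, n),
        channel: fl,
    })
    truth = {
        "gain": channel_gain,
        "offset": channel_offset,
        "exponent": exponent,
        "peak_true_values": vals,
        "peak_channel_centers": centers,
    }
    return EventTable(data=df, sample_id=f"beads-{seed}"), truth


@dataclass(frozen=True)
class DoseResponseDesign:
    """Replicated dose-response experiment from a known Hill truth."""

    truth: HillParams
    doses: tuple[float, ...]
    n_replicates: int = 3
    replicate_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if any((not np.isfinite(d)) or d < 0 for d in self.doses):
            raise ValueError("doses must be finite and non-negative")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")


def gen_dose_response(design: DoseResponseDesign) -> pd.DataFrame:
    """Sample medians on the Hill curve with multiplicative replicate noise.

    Returns a tidy frame (dose, replicate, median); each median is
    Hill(truth, dose) times a unit-median lognormal factor with CV
    ``replicate_cv``. Replicate labels are day identifiers suitable for
    pooled fitting.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for rep in range(design.n_replicates):
        for dose in design.doses:
            clean = float(hill_eval(design.truth, dose))
            noise = (
                float(np.exp(rng.normal(0.0, _lognormal_sigma(design.replicate_cv))))
                if design.replicate_cv > 0 else 1.0
            )
            rows.append({"dose": dose, "replicate": f"day{rep + 1}",
                         "median": clean * noise})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StepDesign:
    """Replicated step ON/OFF timecourse from a known kinetic truth."""

    truth: KineticParams
    c_initial: float
    c_final: float
    sample_times: tuple[float, ...]
    n_replicates: int = 3
    replicate_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("sample_times must be non-negative, strictly increasing")
        if self.c_initial <= 0 or self.c_final <= 0:
            raise ValueError("c_initial and c_final must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")


def gen_step_experiment(design: StepDesign) -> pd.DataFrame:
    """Observed-reporter medians along the step response, with noise.

    Noise-free medians are G(t) of the closed-form cascade solution with
    p(0) = g(0) = G(0) = c_initial and drive c_final; replicate noise is
    multiplicative as in :func:`gen_dose_response`.
    """
    rng = np.random.default_rng(design.seed)
    t = np.asarray(design.sample_times, dtype=float)
    clean = closed_form_step(design.truth, design.c_initial, design.c_final, t).G
    rows = []
    for rep in range(design.n_replicates):
        if design.replicate_cv > 0:
            noise = np.exp(
                rng.normal(0.0, _lognormal_sigma(design.replicate_cv), len(t))
            )
        else:
            noise = np.ones(len(t))
        for ti, gi, ni in zip(t, clean, noise):
            rows.append({"time_min": ti, "replicate": f"day{rep + 1}",
                         "median": gi * ni})
    return pd.DataFrame(rows)
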