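"""Flow-cytometry event processing and replicate statistics.

Raw event tables (one row per event: forward scatter FSC, side scatter
SSC, one or more fluorescence channels in arbitrary units) are reduced
to a single calibrated reporter value per sample the way a standard
optogenetic characterization pipeline does:

1. :func:`density_gate` keeps the densest fraction of events in
   (FSC, SSC) space, discarding debris and doublets.
2. :func:`fit_bead_calibration` fits a log-log line through the peaks of
   a calibration-bead sample with known fluorophore-equivalent values
   (MEFL for fluorescein, MEAP for allophycocyanin);
   :func:`to_mefl` applies it to a channel.
3. :func:`summarize_sample` takes the median of the gated, calibrated
   events; :func:`subtract_autofluorescence` removes the same-day
   reporter-free control's cell fluorescence.
4. :func:`detect` applies a one-sided one-sample t-test against zero to
   day replicates (failures are reported "not detected");
   :func:`welch_test` and :func:`fold_change` support comparisons
   between conditions.

The canonical on-disk format is a plain event CSV (columns: event_id,
fsc, ssc, fl1..fln) plus a ``units`` flag; see :func:`read_event_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EventTable",
    "BeadCalibration",
    "SampleSummary",
    "ReplicateStat",
    "density_gate",
    "fit_bead_calibration",
    "to_mefl",
    "summarize_sample",
    "subtract_autofluorescence",
    "detect",
    "welch_test",
    "fold_change",
    "read_event_csv",
    "write_event_csv",
]

RAW = "raw"
CALIBRATED = "calibrated"


@dataclass(frozen=True)
class EventTable:
    """Per-event measurements for one cytometry sample.

    ``data`` holds at least columns ``fsc`` and ``ssc`` plus one or more
    fluorescence channels. ``calibration_state`` transitions only
    raw -> calibrated (enforced by :func:`to_mefl`).
    """

    data: pd.DataFrame
    sample_id: str = ""
    calibration_state: str = RAW
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValueError("an event table needs at least one event")
        for col in ("fsc", "ssc"):
            if col not in self.data.columns:
                raise ValueError(f"missing required column {col!r}")
        if self.calibration_state not in (RAW, CALIBRATED):
            raise ValueError(f"unknown calibration state {self.calibration_state!r}")

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("fsc", "ssc", "event_id")]


@dataclass(frozen=True)
class BeadCalibration:
    """Log-log linear mapping from channel units to calibrated units.

    log10(value) = slope * log10(channel) + intercept, fitted through
    bead peaks with known assigned values. Strictly increasing requires
    slope > 0.
    """

    peak_channel_positions: np.ndarray
    assigned_values: np.ndarray
    slope: float
    intercept: float
    residual: float
    units: str = "MEFL"

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration mapping must be strictly increasing")

    def apply(self, channel_values: np.ndarray) -> np.ndarray:
        v = np.asarray(channel_values, dtype=float)
        if np.any(v <= 0):
            raise ValueError("channel values must be positive to calibrate")
        return 10.0 ** (self.slope * np.log10(v) + self.intercept)


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample reduction: gated count, cell and reporter fluorescence."""

    sample_id: str
    gated_events: int
    cell_fluorescence: float
    reporter_fluorescence: float | None = None
    units: str = "MEFL"
    condition: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ReplicateStat:
    """Mean +/- sd over day replicates with the detection outcome."""

    mean: float
    sd: float
    n: int
    detected: bool | None = None
    p_value: float | None = None
    degenerate_sd: bool = False


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def density_gate(events: EventTable, fraction: float = 0.5) -> EventTable:
    """Retain the ``fraction`` of events with highest (FSC, SSC) density.

    Density is a Gaussian kernel estimate on linear scatter values with
    Scott's bandwidth rule. Exactly ``round(fraction * n)`` events (half
    away from zero, minimum 1) are kept; ties at the boundary break by
    ascending event index, so the count contract is exact and the result
    deterministic for a fixed input.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction!r}")
    n = events.n_events
    keep = max(_round_half_up(fraction * n), 1)
    if keep >= n:
        return events
    xy = np.vstack([events.data["fsc"].to_numpy(float),
                    events.data["ssc"].to_numpy(float)])
    try:
        kde = stats.gaussian_kde(xy)  # Scott's rule by default
        dens = kde(xy)
    except np.linalg.LinAlgError:
        # degenerate scatter (zero variance in a dimension): all equally dense
        dens = np.zeros(n)
    order = np.argsort(-dens, kind="stable")  # stable: ties by ascending index
    idx = np.sort(order[:keep])
    gated = events.data.iloc[idx].reset_index(drop=True)
    meta = dict(events.metadata)
    meta["gate_fraction"] = fraction
    meta["pre_gate_events"] = n
    return replace(events, data=gated, metadata=meta)


def fit_bead_calibration(
    bead_events: EventTable,
    assigned_values,
    channel: str,
    n_peaks: int | None = None,
    saturation_limit: float | None = None,
    units: str = "MEFL",
) -> BeadCalibration:
    """Locate bead peaks in a channel and fit the log-log calibration line.

    Peaks are modes of a Gaussian kernel density estimate of
    log10(channel); the ``n_peaks`` most prominent modes, taken in
    increasing channel order, are matched to the assigned values in
    increasing order and a straight line is least-squares fitted in
    log10-log10 space. A top peak within 1% of ``saturation_limit``
    (the instrument maximum, if given) is excluded along with its
    assigned value before fitting.
    """
    vals = np.asarray(assigned_values, dtype=float)
    if n_peaks is None:
        n_peaks = len(vals)
    if n_peaks != len(vals):
        raise ValueError("n_peaks must equal the number of assigned values")
    if n_peaks < 2:
        raise ValueError("calibration is underdetermined with < 2 bead peaks")
    if np.any(np.diff(vals) <= 0) or np.any(vals <= 0):
        raise ValueError("assigned values must be positive and strictly increasing")

    ch = bead_events.data[channel].to_numpy(float)
    ch = ch[ch > 0]
    if len(ch) < 2 * n_peaks:
        raise ValueError("too few positive events to locate bead peaks")
    logch = np.log10(ch)
    kde = stats.gaussian_kde(logch, bw_method=0.05)
    grid = np.linspace(logch.min() - 0.1, logch.max() + 0.1, 4000)
    d = kde(grid)
    from scipy.signal import find_peaks

    locs, props = find_peaks(d, prominence=1e-4 * d.max())
    if len(locs) < n_peaks:
        raise ValueError(
            f"found only {len(locs)} density modes, need {n_peaks} bead peaks"
        )
    top = np.sort(locs[np.argsort(props["prominences"])[-n_peaks:]])
    # polish each mode off the grid (the KDE is smooth; grid resolution alone
    # would limit calibration accuracy)
    from scipy.optimize import minimize_scalar

    step = grid[1] - grid[0]
    polished = []
    for loc in top:
        res = minimize_scalar(
            lambda z: -kde(z)[0],
            bounds=(grid[loc] - step, grid[loc] + step),
            method="bounded",
            options={"xatol": 1e-10},
        )
        polished.append(res.x)
    peak_pos = 10.0 ** np.sort(polished)

    use = np.ones(n_peaks, dtype=bool)
    if saturation_limit is not None and peak_pos[-1] >= 0.99 * saturation_limit:
        use[-1] = False
        if use.sum() < 2:
            raise ValueError("fewer than 2 usable peaks after saturation exclusion")
    px, pv = peak_pos[use], vals[use]
    if np.any(np.diff(px) <= 0):
        raise ValueError("non-monotone peak/value pairing")
    slope, intercept = np.polyfit(np.log10(px), np.log10(pv), 1)
    pred = slope * np.log10(px) + intercept
    residual = float(np.sum((np.log10(pv) - pred) ** 2))
    return BeadCalibration(
        peak_channel_positions=px,
        assigned_values=pv,
        slope=float(slope),
        intercept=float(intercept),
        residual=residual,
        units=units,
    )


def to_mefl(events: EventTable, calib: BeadCalibration, channel: str) -> EventTable:
    """Map ``channel`` through the bead calibration; mark the table calibrated.

    Calibrating an already-calibrated table is an error (the state
    machine admits only raw -> calibrated).
    """
    if events.calibration_state == CALIBRATED:
        raise ValueError("events are already calibrated; refusing to calibrate twice")
    if channel not in events.data.columns:
        raise KeyError(f"channel {channel!r} not in event table")
    data = events.data.copy()
    data[channel] = calib.apply(data[channel].to_numpy(float))
    meta = dict(events.metadata)
    meta["calibration_units"] = calib.units
    return replace(events, data=data, calibration_state=CALIBRATED, metadata=meta)


def summarize_sample(events: EventTable, channel: str) -> float:
    """Median of the named channel over all (gated) events.

    Even event counts use the mean-of-the-two-middle-values convention
    (numpy's median).
    """
    if events.n_events < 1:
        raise ValueError("cannot summarize an empty sample")
    return float(np.median(events.data[channel].to_numpy(float)))


def subtract_autofluorescence(
    sample: float, control: float, units: tuple[str, str] | None = None
) -> float:
    """Reporter fluorescence: sample cell fluorescence minus the same-day
    reporter-free control's cell fluorescence. May be negative; negative
    values are resolved downstream by the detection test."""
    if units is not None and units[0] != units[1]:
        raise ValueError(f"unit mismatch: {units[0]!r} vs {units[1]!r}")
    return float(sample) - float(control)


def detect(replicate_values, alpha: float = 0.05) -> ReplicateStat:
    """One-sided one-sample t-test of day replicates against zero.

    ``detected`` is True when the one-sided p-value (alternative: mean
    greater than zero) is below ``alpha``; otherwise the sample is
    reported "not detected" (N.D.). Mean and sd are reported regardless.
    With zero sample sd the t statistic is undefined; the limit of the
    test is used: p = 0 if the mean is positive, else p = 1.
    """
    v = np.asarray(replicate_values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need at least 2 replicate values")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        p = 0.0 if mean > 0 else 1.0
        return ReplicateStat(mean=mean, sd=sd, n=len(v), detected=p < alpha,
                             p_value=p, degenerate_sd=True)
    res = stats.ttest_1samp(v, 0.0, alternative="greater")
    p = float(res.pvalue)
    return ReplicateStat(mean=mean, sd=sd, n=len(v), detected=p < alpha, p_value=p)


def welch_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variances two-sample t-test (two-sided).

    Returns (t, Welch-Satterthwaite degrees of freedom, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    if va + vb == 0.0:
        df = float(len(a) + len(b) - 2)
        t = 0.0 if np.mean(a) == np.mean(b) else np.inf * np.sign(np.mean(a) - np.mean(b))
        return float(t), df, 1.0 if t == 0.0 else 0.0
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def fold_change(
    numerator_reps, denominator_reps, pairing: str = "by_day"
) -> ReplicateStat:
    """Fold change between two conditions (e.g. activating vs de-activating
    light), as a dimensionless replicate statistic.

    ``by_day`` (default) divides matched same-day replicates and reports
    mean +/- sd of the per-day ratios — the natural pairing when each
    condition is run once per experimental day. ``ratio_of_means``
    reports the single ratio of means with first-order error
    propagation: sd = r * sqrt(cv_num^2 + cv_den^2).
    """
    num = np.asarray(numerator_reps, dtype=float)
    den = np.asarray(denominator_reps, dtype=float)
    if np.any(den <= 0):
        raise ValueError("denominator replicates must be strictly positive")
    if pairing == "by_day":
        if len(num) != len(den):
            raise ValueError("by_day pairing needs equal-length matched replicates")
        ratios = num / den
        return ReplicateStat(
            mean=float(np.mean(ratios)),
            sd=float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0,
            n=len(ratios),
        )
    if pairing == "ratio_of_means":
        mn, md = float(np.mean(num)), float(np.mean(den))
        r = mn / md
        cv_n = np.std(num, ddof=1) / mn if len(num) > 1 else 0.0
        cv_d = np.std(den, ddof=1) / md if len(den) > 1 else 0.0
        return ReplicateStat(mean=r, sd=float(abs(r) * np.hypot(cv_n, cv_d)), n=1)
    raise ValueError(f"unknown pairing {pairing!r}")


def write_event_csv(events: EventTable, path: str | Path) -> None:
    """Write the canonical event CSV (event_id, fsc, ssc, channels...)."""
    df = events.data.copy()
    if "event_id" not in df.columns:
        df.insert(0, "event_id", np.arange(len(df)))
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_id={events.sample_id}\n")
        fh.write(f"# calibration_state={events.calibration_state}\n")
        df.to_csv(fh, index=False)


def read_event_csv(path: str | Path) -> EventTable:
    """Read the canonical event CSV written by :func:`write_event_csv`."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    state = meta.get("calibration_state", RAW)
    return EventTable(
        data=df,
        sample_id=meta.get("sample_id", path.stem),
        calibration_state=state,
    )
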