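"""Steady-state Hill transfer function: evaluation and log-residual fitting.

The dose-response of the light- (or inducer-) driven system is modeled as

    y(x) = y0 + dy * x^n / (x^n + K^n)

with basal output ``y0`` (MEFL), dynamic span ``dy`` (MEFL), Hill
coefficient ``n`` and half-maximum dose ``K`` (input units: light
intensity in umol m^-2 s^-1, xylose %, or IPTG uM). Fitting pools all
replicate points and minimizes the sum of squared differences between
log(observation) and log(model) by damped least squares, which weights
the decades-spanning output range evenly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = ["HillParams", "FitResult", "hill_eval", "fit_hill"]


@dataclass(frozen=True)
class HillParams:
    """Transfer-function parameters. All four must be positive."""

    y0: float
    dy: float
    n: float
    K: float

    def __post_init__(self) -> None:
        for name in ("y0", "dy", "n", "K"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return {"y0": self.y0, "dy": self.dy, "n": self.n, "K": self.K}


@dataclass
class FitResult:
    """Outcome of a damped-least-squares fit on log residuals."""

    params: HillParams
    stderr: dict[str, float | None]
    residual: float  # sum of squared log differences
    success: bool
    nfev: int
    message: str = ""
    extra: dict = field(default_factory=dict)


def hill_eval(params: HillParams, x) -> np.ndarray | float:
    """Evaluate the Hill curve at dose(s) ``x >= 0``.

    ``x = 0`` returns exactly ``y0`` (no 0/0 ambiguity).
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0):
        raise ValueError("doses must be non-negative")
    out = np.full_like(xa, params.y0, dtype=float)
    pos = xa > 0
    # evaluate in log space to stay finite across decades
    r = np.exp(params.n * (np.log(xa[pos]) - np.log(params.K)))
    out[pos] = params.y0 + params.dy * r / (r + 1.0)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def _initial_guess(x: np.ndarray, y: np.ndarray) -> HillParams:
    """Scale-free defaults: basal = min y, span = max - min, K from the
    geometric middle of the positive doses, n = 1."""
    y0 = max(float(np.min(y)), 1e-12)
    dy = max(float(np.max(y) - np.min(y)), 1e-6 * y0)
    pos = x[x > 0]
    K = float(np.exp(np.median(np.log(pos)))) if len(pos) else 1.0
    return HillParams(y0=y0, dy=dy, n=1.0, K=K)


def fit_hill(
    x,
    y,
    replicate=None,
    init: HillParams | None = None,
    max_nfev: int = 1000,
) -> FitResult:
    """Fit a Hill transfer function to pooled dose-response points.

    Parameters
    ----------
    x, y
        Dose and observed output per point. Replicates are pooled:
        pass every point of every replicate; the objective is symmetric
        under reordering. All ``y`` must be > 0 (log residuals).
    replicate
        Optional labels, kept for bookkeeping only (the pooled objective
        ignores them).
    init
        Optional starting parameters; a scale-free default is derived
        from the data otherwise.

    The four parameters are optimized on log scale internally, which
    enforces positivity without hard bounds; estimates and standard
    errors (delta method from the damped-least-squares covariance) are
    reported on the natural scale. Non-convergence is flagged on the
    result, not raised.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be matching 1-D arrays")
    if np.any(ya <= 0):
        raise ValueError(
            "all outputs must be > 0 for log-residual fitting; remove or "
            "re-measure nonpositive points (no silent flooring is applied)"
        )
    if len(np.unique(xa)) < 4:
        raise ValueError("need >= 4 distinct doses to fit 4 parameters")
    if init is None:
        init = _initial_guess(xa, ya)

    pset = lmfit.Parameters()
    for name, v in init.as_dict().items():
        pset.add(f"log_{name}", value=np.log(v))

    log_y = np.log(ya)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        hp = HillParams(
            y0=np.exp(p["log_y0"].value),
            dy=np.exp(p["log_dy"].value),
            n=np.exp(p["log_n"].value),
            K=np.exp(p["log_K"].value),
        )
        return log_y - np.log(hill_eval(hp, xa))

    out = lmfit.minimize(
        residual, pset, method="leastsq", xtol=1e-12, ftol=1e-12, max_nfev=max_nfev
    )
    est = {name: float(np.exp(out.params[f"log_{name}"].value))
           for name in ("y0", "dy", "n", "K")}
    stderr = {}
    for name in ("y0", "dy", "n", "K"):
        se = out.params[f"log_{name}"].stderr
        stderr[name] = None if se is None else float(se) * est[name]
    return FitResult(
        params=HillParams(**est),
        stderr=stderr,
        residual=float(np.sum(np.asarray(out.residual) ** 2)),
        success=bool(out.success),
        nfev=int(out.nfev),
        message=str(out.message),
    )
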