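"""Empirical total-solubility model versus electrolyte molality.

The smoothing model

    log10 S_T(m) = log10 S_T0 + [a_inf + (a_0 - a_inf)/(1 + m)] * m

interpolates between a limiting slope ``a_0`` at zero ionic strength and
``a_inf`` at infinite ionic strength; with ``a_0 == a_inf`` it collapses to
a straight line in ``m``.  Written in the basis ``(1, m, m/(1+m))`` the
model is linear in its parameters, so fits are exact (weighted) linear
least squares and need no iterative optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DegenerateFitError, InsufficientDataError
from .units import SolubilityPoint

__all__ = [
    "SmoothingParams",
    "predict_log_ST",
    "fit_total_solubility",
    "salting_out_percent",
]

LN10 = np.log(10.0)


@dataclass(frozen=True)
class SmoothingParams:
    """Fitted parameters of the smoothing solubility model."""

    log_S_T0: float
    a_0: float
    a_inf: float
    covariance: np.ndarray  # 3x3, ordered (log_S_T0, a_0, a_inf)
    model: str  # "linear" | "extended"
    rss: float = 0.0
    dof: int = 0
    n_obs: int = 0
    f_pvalue: float | None = field(default=None)  # extended-vs-linear F test

    @property
    def stderr(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """t-based confidence intervals, rows (log_S_T0, a_0, a_inf)."""
        t = stats.t.ppf(0.5 + level / 2.0, max(self.dof, 1))
        centers = np.array([self.log_S_T0, self.a_0, self.a_inf])
        half = t * self.stderr
        return np.column_stack([centers - half, centers + half])


def smoothing_curve(
    m, log_S_T0: float, a_0: float, a_inf: float
):
    """Evaluate the smoothing model; accepts scalars or arrays."""
    m = np.asarray(m, dtype=float)
    return log_S_T0 + (a_inf + (a_0 - a_inf) / (1.0 + m)) * m


def predict_log_ST(params: SmoothingParams, m) -> np.ndarray | float:
    """Predicted log10 total solubility at salt molality ``m`` (>= 0)."""
    if np.any(np.asarray(m) < 0):
        raise ValueError("molality must be non-negative")
    out = smoothing_curve(m, params.log_S_T0, params.a_0, params.a_inf)
    return float(out) if np.isscalar(m) else out


def _observations(
    points: list[SolubilityPoint], weighting: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand points into (m, log10 S_T, weight) observation arrays."""
    ms, ys, ws = [], [], []
    for p in points:
        if p.S_T <= 0 or any(r <= 0 for r in p.replicates):
            raise ValueError("solubilities must be positive for a log-scale fit")
        if weighting == "replicates" and p.replicates:
            for r in p.replicates:
                ms.append(p.m_salt)
                ys.append(np.log10(r))
                ws.append(1.0)
        elif weighting == "point_sd" and p.sd > 0:
            n = max(len(p.replicates), 1)
            var_log = (p.sd / (p.S_T * LN10)) ** 2 / n
            ms.append(p.m_salt)
            ys.append(np.log10(p.S_T))
            ws.append(1.0 / var_log)
        else:
            ms.append(p.m_salt)
            ys.append(np.log10(p.S_T))
            ws.append(1.0)
    return np.asarray(ms), np.asarray(ys), np.asarray(ws)


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted LS: coefficients, covariance, rss (unweighted), dof."""
    sw = np.sqrt(w)
    Xw, yw = X * sw[:, None], y * sw
    coef, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < X.shape[1]:
        raise DegenerateFitError("singular design in solubility fit")
    resid = y - X @ coef
    rss_w = float(np.sum(w * resid**2))
    dof = len(y) - X.shape[1]
    sigma2 = rss_w / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
    return coef, cov, float(np.sum(resid**2)), rss_w, dof


def fit_total_solubility(
    points: list[SolubilityPoint],
    model: str = "auto",
    weighting: str = "replicates",
    alpha: float = 0.05,
) -> SmoothingParams:
    """Fit the smoothing model to total-solubility points.

    Parameters
    ----------
    points:
        Solubility points; distinct ``m_salt`` values are required (one may
        be the pure-water point at ``m_salt = 0``).
    model:
        ``"linear"`` (a_0 == a_inf), ``"extended"``, or ``"auto"`` which
        selects by an extra-sum-of-squares F test at level ``alpha``.
    weighting:
        ``"replicates"`` (default) fits every replicate as an observation;
        ``"point_sd"`` fits per-point means weighted by propagated replicate
        variance; ``"uniform"`` fits unweighted means.
    """
    if model not in ("linear", "extended", "auto"):
        raise ValueError(f"unknown model {model!r}")
    n_distinct = len({p.m_salt for p in points})
    need = 3 if model == "linear" else 4
    if n_distinct < need:
        raise InsufficientDataError(
            f"need >= {need} distinct molalities for the {model} model, "
            f"got {n_distinct}"
        )
    m, y, w = _observations(points, weighting)

    X_lin = np.column_stack([np.ones_like(m), m])
    X_ext = np.column_stack([np.ones_like(m), m, m / (1.0 + m)])
    lin = _wls(X_lin, y, w)
    ext = _wls(X_ext, y, w)

    f_p = None
    if model == "auto":
        rss_lin_w, rss_ext_w, dof_ext = lin[3], ext[3], ext[4]
        scale = max(abs(y).max(), 1.0)
        if rss_ext_w <= 1e-24 * scale**2:
            # both fits are numerically exact -> prefer the simpler line
            chosen = "linear" if rss_lin_w <= 1e-24 * scale**2 else "extended"
            f_p = 0.0 if chosen == "extended" else 1.0
        else:
            F = (rss_lin_w - rss_ext_w) / (rss_ext_w / dof_ext)
            f_p = float(stats.f.sf(max(F, 0.0), 1, dof_ext))
            chosen = "extended" if f_p < alpha else "linear"
    else:
        chosen = model

    if chosen == "linear":
        coef, cov_b, rss, _, dof = lin
        T = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        log0, a0, ainf = coef[0], coef[1], coef[1]
    else:
        coef, cov_b, rss, _, dof = ext
        # (log_S_T0, a_0, a_inf) from basis coefficients (b0, b1, b2):
        # a_inf = b1, a_0 = b1 + b2
        T = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0], [0.0, 1.0, 0.0]])
        log0, a0, ainf = coef[0], coef[1] + coef[2], coef[1]
    return SmoothingParams(
        log_S_T0=float(log0),
        a_0=float(a0),
        a_inf=float(ainf),
        covariance=T @ cov_b @ T.T,
        model=chosen,
        rss=rss,
        dof=dof,
        n_obs=len(y),
        f_pvalue=f_p,
    )


def salting_out_percent(S_T0: float, S_T: float) -> float:
    """Percentage decrease of total solubility relative to pure water.

    Positive values mean salting-out, negative salting-in; bounded above
    by 100 (complete loss of solubility).
    """
    if S_T0 <= 0:
        raise ValueError("S_T0 must be positive")
    if S_T < 0:
        raise ValueError("S_T must be non-negative")
    return (S_T0 - S_T) * 100.0 / S_T0
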