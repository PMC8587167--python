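"""Activity coefficients of the neutral species and Setschenow fits.

From solubility ratios, ``log10 gamma = log10(S0_water / S0(I))`` (the
infinite-dilution reference state fixes gamma = 1 in pure water).  Two
salting models are fitted through the origin:

constant   log10 gamma = k * m
extended   log10 gamma = [k_inf + (k_0 - k_inf)/(1 + m)] * m

The extended form lets the Setschenow coefficient relax from ``k_0`` at
zero ionic strength to ``k_inf`` at high ionic strength while keeping
``log gamma(0) = 0`` exactly; with ``k_0 == k_inf`` it reduces to the
constant model.  Both are linear in their parameters, so the fits are
exact least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateFitError, InsufficientDataError

__all__ = [
    "ActivityPoint",
    "SetschenowFit",
    "log_gamma",
    "predict_log_gamma",
    "effective_k",
    "fit_setschenow",
    "fit_setschenow_solubility",
]


@dataclass(frozen=True)
class ActivityPoint:
    """log10 activity coefficient of the neutral species at one molality."""

    m_salt: float
    log_gamma: float

    @property
    def gamma(self) -> float:
        return float(10.0**self.log_gamma)


@dataclass(frozen=True)
class SetschenowFit:
    """Fitted salting model.

    For the constant model ``k_0 == k_inf == k``.  ``intercept_log_s0``
    is filled by :func:`fit_setschenow_solubility`, which estimates the
    pure-water neutral solubility jointly instead of conditioning on it.
    """

    model: str  # "constant" | "extended"
    k_0: float
    k_inf: float
    covariance: np.ndarray  # 2x2, ordered (k_0, k_inf)
    rss: float = 0.0
    dof: int = 0
    n_obs: int = 0
    f_pvalue: float | None = None
    intercept_log_s0: float | None = None
    intercept_se: float | None = None

    @property
    def k(self) -> float:
        if self.model != "constant":
            raise AttributeError("k is defined for the constant model only")
        return self.k_0

    @property
    def stderr(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """t-based confidence intervals, rows (k_0, k_inf)."""
        t = stats.t.ppf(0.5 + level / 2.0, max(self.dof, 1))
        centers = np.array([self.k_0, self.k_inf])
        half = t * self.stderr
        return np.column_stack([centers - half, centers + half])


def log_gamma(s0_water: float, s0_at_I: float) -> float:
    """log10 activity coefficient from the neutral-solubility ratio."""
    if s0_water <= 0 or s0_at_I <= 0:
        raise ValueError("neutral-species solubilities must be positive")
    return float(np.log10(s0_water / s0_at_I))


def _log_gamma_curve(m, k_0: float, k_inf: float):
    m = np.asarray(m, dtype=float)
    return (k_inf + (k_0 - k_inf) / (1.0 + m)) * m


def predict_log_gamma(
    fit: SetschenowFit, m, printed_form: bool = False
) -> np.ndarray | float:
    """Predicted log10 gamma at salt molality ``m``.

    ``printed_form=True`` evaluates the historical variant
    ``k_inf + [k_inf + (k_0 - k_inf)/(1+m)]*m`` instead; it does not obey
    ``log gamma(0) = 0`` and exists only for forensic comparison.
    """
    m_arr = np.asarray(m, dtype=float)
    if np.any(m_arr < 0):
        raise ValueError("molality must be non-negative")
    if printed_form:
        out = fit.k_inf + (fit.k_inf + (fit.k_0 - fit.k_inf) / (1.0 + m_arr)) * m_arr
    else:
        out = _log_gamma_curve(m_arr, fit.k_0, fit.k_inf)
    return float(out) if np.isscalar(m) else out


def effective_k(fit: SetschenowFit, m) -> np.ndarray | float:
    """Ionic-strength-dependent Setschenow coefficient k(m) = log gamma / m.

    Continuously extended to ``k_0`` at m = 0.
    """
    m_arr = np.asarray(m, dtype=float)
    out = fit.k_inf + (fit.k_0 - fit.k_inf) / (1.0 + m_arr)
    return float(out) if np.isscalar(m) else out


def _select(rss_con_w, rss_ext_w, dof_ext, alpha, scale):
    if rss_ext_w <= 1e-24 * scale:
        chosen = "constant" if rss_con_w <= 1e-24 * scale else "extended"
        return chosen, (0.0 if chosen == "extended" else 1.0)
    F = (rss_con_w - rss_ext_w) / (rss_ext_w / dof_ext)
    p = float(stats.f.sf(max(F, 0.0), 1, dof_ext))
    return ("extended" if p < alpha else "constant"), p


def _wls(X, y, w):
    sw = np.sqrt(w)
    coef, _, rank, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    if rank < X.shape[1]:
        raise DegenerateFitError("singular design in Setschenow fit")
    resid = y - X @ coef
    rss_w = float(np.sum(w * resid**2))
    dof = len(y) - X.shape[1]
    sigma2 = rss_w / dof if dof > 0 else 0.0
    Xw = X * sw[:, None]
    cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
    return coef, cov, float(np.sum(resid**2)), rss_w, dof


def fit_setschenow(
    points: list[ActivityPoint],
    model: str = "auto",
    alpha: float = 0.05,
    weights: np.ndarray | None = None,
) -> SetschenowFit:
    """Origin-constrained fit of log10 gamma versus salt molality.

    The reference state pins the curve at (0, 0); points at ``m = 0``
    therefore carry no information and at least 2 (constant) or 3
    (extended) distinct positive molalities are required.
    """
    if model not in ("constant", "extended", "auto"):
        raise ValueError(f"unknown model {model!r}")
    m = np.asarray([p.m_salt for p in points], dtype=float)
    y = np.asarray([p.log_gamma for p in points], dtype=float)
    if np.any(m < 0):
        raise ValueError("molalities must be non-negative")
    n_pos = len({mm for mm in m if mm > 0})
    if n_pos == 0:
        raise DegenerateFitError("all points at m = 0: nothing to fit")
    need = 2 if model == "constant" else 3
    if n_pos < need:
        raise InsufficientDataError(
            f"need >= {need} distinct positive molalities, got {n_pos}"
        )
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)

    X_con = m[:, None]
    X_ext = np.column_stack([m, m / (1.0 + m)])
    con = _wls(X_con, y, w)
    ext = _wls(X_ext, y, w)

    f_p = None
    if model == "auto":
        scale = max(float(np.max(np.abs(y))), 1.0) ** 2
        chosen, f_p = _select(con[3], ext[3], ext[4], alpha, scale)
    else:
        chosen = model
    return _package(chosen, con, ext, f_p, len(y))


def _package(chosen, con, ext, f_p, n_obs, intercept=None, intercept_se=None):
    if chosen == "constant":
        coef, cov_b, rss, _, dof = con
        # coefficient order in the design: (k,) [+ intercept last]
        k0 = kinf = float(coef[0])
        var = cov_b[0, 0]
        cov = np.array([[var, var], [var, var]])
    else:
        coef, cov_b, rss, _, dof = ext
        # basis (m, m/(1+m)) -> k_inf = b0, k_0 = b0 + b1
        kinf, k0 = float(coef[0]), float(coef[0] + coef[1])
        T = np.array([[1.0, 1.0], [1.0, 0.0]])  # rows (k_0, k_inf)
        cov = T @ cov_b[:2, :2] @ T.T
    return SetschenowFit(
        model=chosen,
        k_0=k0,
        k_inf=kinf,
        covariance=cov,
        rss=rss,
        dof=dof,
        n_obs=n_obs,
        f_pvalue=f_p,
        intercept_log_s0=intercept,
        intercept_se=intercept_se,
    )


def fit_setschenow_solubility(
    m: np.ndarray,
    log_s0: np.ndarray,
    model: str = "auto",
    alpha: float = 0.05,
) -> SetschenowFit:
    """Joint fit of the salting model and the pure-water neutral solubility.

    Fits ``log10 s0 = c - [k_inf + (k_0 - k_inf)/(1+m)]*m`` with the
    intercept ``c = log10 s0_water`` as a free parameter, so replicate
    scatter of the water point propagates into the parameter covariance
    instead of being conditioned on.  Equivalent to the origin-constrained
    gamma fit when the water solubility is known exactly.
    """
    if model not in ("constant", "extended", "auto"):
        raise ValueError(f"unknown model {model!r}")
    m = np.asarray(m, dtype=float)
    y = np.asarray(log_s0, dtype=float)
    if np.any(m < 0):
        raise ValueError("molalities must be non-negative")
    n_pos = len({mm for mm in m if mm > 0})
    need = 2 if model == "constant" else 3
    if n_pos < need:
        raise InsufficientDataError(
            f"need >= {need} distinct positive molalities, got {n_pos}"
        )
    w = np.ones_like(y)
    # design columns: -m, [-m/(1+m)], 1  (intercept last)
    X_con = np.column_stack([-m, np.ones_like(m)])
    X_ext = np.column_stack([-m, -m / (1.0 + m), np.ones_like(m)])
    con = _wls(X_con, y, w)
    ext = _wls(X_ext, y, w)

    f_p = None
    if model == "auto":
        scale = max(float(np.max(np.abs(y))), 1.0) ** 2
        chosen, f_p = _select(con[3], ext[3], ext[4], alpha, scale)
    else:
        chosen = model
    which = con if chosen == "constant" else ext
    coef, cov_b = which[0], which[1]
    intercept = float(coef[-1])
    intercept_se = float(np.sqrt(max(cov_b[-1, -1], 0.0)))
    return _package(chosen, con, ext, f_p, len(y), intercept, intercept_se)
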