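"""SIT ionization model and correction of total to neutral-species solubility.

The stoichiometric ionization constant of a monoprotic weak acid HA depends
on ionic strength through the specific ion interaction (SIT) relation

    pK(I) = pK0 - 2 D(I) + (b_plus + b_minus - k) I
    D(I)  = A sqrt(I) / (1 + B sqrt(I))

with the extended Debye term D (A = 0.4565, B = 1.11 kg^1/2 mol^-1/2 at
37 C), ``b_plus`` the H+/medium-anion and ``b_minus`` the A-/Na+ pairwise
interaction coefficients, and ``k`` the Setschenow coefficient of the
neutral acid.  In a saturated solution with no added acid or base the only
proton source is the dissolution itself, so charge balance gives
[H+] = [A-] (water autoprotolysis neglected; saturated solutions of these
acids sit well below pH 6) and [H+] is the positive root of

    h^2 + K h - K S_T = 0.

Ionic strength is identified with the background-salt molality (the
ionic-medium approximation; the mmol-level contribution of the dissolved
acid's own ions is neglected).

Because ``k`` appears inside pK(I) but is itself estimated from the
corrected solubilities, :func:`correct_total_solubility` iterates the SIT
correction with the Setschenow fit to a fixed point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .activity import (
    SetschenowFit,
    effective_k,
    fit_setschenow_solubility,
    ActivityPoint,
)
from .units import AcidSpec, Medium, SolubilityPoint

__all__ = [
    "SITParams",
    "IonizationResult",
    "SaturationSpeciation",
    "debye_term",
    "pK_at_I",
    "extrapolate_pK0",
    "solve_saturation",
    "correct_total_solubility",
    "NeutralSolubilityResult",
]

#: Debye slope (dimensionless) and denominator coefficient at 37 C.
DEBYE_A_37C = 0.4565
DEBYE_B_37C = 1.11


@dataclass(frozen=True)
class SITParams:
    """Constants of the SIT ionization model for one acid/medium pair."""

    b_plus: float = 0.0
    b_minus: float = 0.06
    k: float = 0.0
    debye_a: float = DEBYE_A_37C
    debye_b: float = DEBYE_B_37C
    z: int = 1

    def __post_init__(self) -> None:
        if self.debye_a <= 0 or self.debye_b <= 0:
            raise ValueError("Debye constants must be positive")


@dataclass(frozen=True)
class IonizationResult:
    """Ionization constant of the acid at one ionic strength."""

    ionic_strength: float
    pK_I: float
    pK0: float

    @property
    def K_I(self) -> float:
        return float(10.0**-self.pK_I)


@dataclass(frozen=True)
class SaturationSpeciation:
    """Species molalities in a saturated solution (mass/charge balanced)."""

    S_T: float
    h: float  # free [H+]
    a_minus: float  # [A-] = h by charge balance
    s0: float  # neutral-species solubility [HA]


def debye_term(I, params: SITParams | None = None):
    """Extended Debye term D(I); 0 at I = 0, -> A/B as I -> infinity."""
    a = params.debye_a if params is not None else DEBYE_A_37C
    b = params.debye_b if params is not None else DEBYE_B_37C
    I_arr = np.asarray(I, dtype=float)
    if np.any(I_arr < 0):
        raise ValueError("ionic strength must be non-negative")
    sq = np.sqrt(I_arr)
    out = a * sq / (1.0 + b * sq)
    return float(out) if np.isscalar(I) else out


def pK_at_I(pK0: float, I, params: SITParams):
    """Stoichiometric pK at ionic strength ``I`` from the SIT relation."""
    I_arr = np.asarray(I, dtype=float)
    d = debye_term(I_arr, params)
    out = pK0 - 2.0 * d + (params.b_plus + params.b_minus - params.k) * I_arr
    return float(out) if np.isscalar(I) else out


def extrapolate_pK0(pK_I: float, I: float, params: SITParams) -> float:
    """Infinite-dilution pK0 from a pK measured at ionic strength ``I``.

    Exact algebraic inverse of :func:`pK_at_I`.
    """
    return float(
        pK_I
        + 2.0 * debye_term(I, params)
        - (params.b_plus + params.b_minus - params.k) * I
    )


def solve_saturation(
    S_T: float, K_I: float, h: float | None = None
) -> SaturationSpeciation:
    """Speciation of a saturated weak-acid solution.

    With no measured pH, [H+] is the positive root of the charge/mass
    balance quadratic; a user-supplied ``h`` (e.g. from a pH reading)
    overrides it.  The neutral fraction is ``s0 = S_T * h / (h + K_I)``.
    """
    if S_T <= 0:
        raise ValueError("S_T must be positive")
    if K_I < 0:
        raise ValueError("K_I must be non-negative")
    if h is None:
        if K_I == 0.0:
            h = 0.0
        else:
            # positive root of h^2 + K h - K S_T = 0, written to avoid
            # cancellation when K << S_T
            h = 2.0 * K_I * S_T / (K_I + np.sqrt(K_I**2 + 4.0 * K_I * S_T))
    elif h < 0:
        raise ValueError("h must be non-negative")
    if 0.0 < h < 1e-6:
        warnings.warn(
            "free [H+] below 1e-6 mol/kg: neglecting water autoprotolysis "
            "is no longer safe",
            stacklevel=2,
        )
    s0 = S_T if K_I == 0.0 else S_T * h / (h + K_I)
    return SaturationSpeciation(S_T=S_T, h=float(h), a_minus=float(h), s0=float(s0))


@dataclass(frozen=True)
class NeutralSolubilityResult:
    """Outcome of the coupled SIT correction / Setschenow estimation."""

    pK0: float
    setschenow: SetschenowFit
    ionization: list[IonizationResult]
    speciation: list[tuple[float, SaturationSpeciation]]  # (m_salt, spec)
    activity: list[ActivityPoint]
    s0_water: float
    n_iter: int
    converged: bool
    pK0_spread: float | None = None  # diagnostic: spread of pK0 across
    # the measured-pK entries under the final SIT parameters


def _sit_with_k(base: SITParams, k: float) -> SITParams:
    return SITParams(
        b_plus=base.b_plus,
        b_minus=base.b_minus,
        k=k,
        debye_a=base.debye_a,
        debye_b=base.debye_b,
        z=base.z,
    )


def correct_total_solubility(
    points: list[SolubilityPoint],
    acid: AcidSpec,
    medium: Medium,
    model: str = "auto",
    sit: SITParams | None = None,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> NeutralSolubilityResult:
    """Correct total solubilities for ionization and fit the salting model.

    ``points`` must contain exactly one pure-water point (``m_salt = 0``)
    plus points in ``medium``.  The acid's measured pK at the highest
    tabulated ionic strength anchors the SIT extrapolation; ``k`` inside
    the SIT relation is iterated with the fitted Setschenow model (the
    ionic-strength-dependent effective k of the extended model, or the
    constant k) until successive estimates agree within ``tol``.

    When ``acid.pK_measured`` is empty the solute is treated as
    non-ionizing (K = 0, s0 = S_T) and a single Setschenow fit is done.
    """
    water = [p for p in points if p.m_salt == 0]
    if len(water) != 1:
        raise ValueError("need exactly one pure-water (m_salt = 0) point")
    salty = sorted((p for p in points if p.m_salt > 0), key=lambda p: p.m_salt)
    if sit is None:
        if medium.b_plus is None:
            raise ValueError(f"medium {medium.name!r} has no b_plus coefficient")
        sit = SITParams(b_plus=medium.b_plus, b_minus=acid.b_minus)

    # per-observation arrays (replicates expanded when present)
    obs_m, obs_ST = [], []
    for p in [water[0]] + salty:
        reps = p.replicates if p.replicates else [p.S_T]
        for r in reps:
            obs_m.append(p.m_salt)
            obs_ST.append(r)
    obs_m = np.asarray(obs_m)
    obs_ST = np.asarray(obs_ST)

    ionizing = bool(acid.pK_measured)
    if ionizing:
        I_ref, pK_ref = max(acid.pK_measured, key=lambda t: t[0])

    fit: SetschenowFit | None = None
    k_prev = np.array([0.0, 0.0])
    n_iter = 0
    converged = not ionizing
    pK0 = 0.0
    for n_iter in range(1, max_iter + 1):
        if ionizing:
            def keff(m):
                if fit is None:
                    return 0.0
                return effective_k(fit, m)

            pK0 = extrapolate_pK0(pK_ref, I_ref, _sit_with_k(sit, keff(I_ref)))
            K_obs = np.array(
                [10.0 ** -pK_at_I(pK0, m, _sit_with_k(sit, keff(m))) for m in obs_m]
            )
        else:
            K_obs = np.zeros_like(obs_m)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s0_obs = np.array(
                [solve_saturation(st, k).s0 for st, k in zip(obs_ST, K_obs)]
            )
        fit = fit_setschenow_solubility(obs_m, np.log10(s0_obs), model=model)
        k_now = np.array([fit.k_0, fit.k_inf])
        if not ionizing or np.max(np.abs(k_now - k_prev)) < tol:
            converged = True
            break
        k_prev = k_now

    # final per-point (mean-level) tables under the converged parameters
    ionization: list[IonizationResult] = []
    speciation: list[tuple[float, SaturationSpeciation]] = []
    activity: list[ActivityPoint] = []
    s0_water = 0.0
    pK0_spread = None
    for p in [water[0]] + salty:
        if ionizing:
            k_here = effective_k(fit, p.m_salt)
            pk_i = pK_at_I(pK0, p.m_salt, _sit_with_k(sit, k_here))
            K = 10.0**-pk_i
            ionization.append(
                IonizationResult(ionic_strength=p.m_salt, pK_I=pk_i, pK0=pK0)
            )
        else:
            K = 0.0
        spec = solve_saturation(p.S_T, K)
        speciation.append((p.m_salt, spec))
        if p.m_salt == 0:
            s0_water = spec.s0
    for m_salt, spec in speciation:
        if m_salt > 0:
            activity.append(
                ActivityPoint(
                    m_salt=m_salt,
                    log_gamma=float(np.log10(s0_water / spec.s0)),
                )
            )
    if ionizing and len(acid.pK_measured) > 1:
        pk0s = [
            extrapolate_pK0(pk, i, _sit_with_k(sit, effective_k(fit, i)))
            for i, pk in acid.pK_measured
        ]
        pK0_spread = float(max(pk0s) - min(pk0s))

    return NeutralSolubilityResult(
        pK0=pK0 if ionizing else float("nan"),
        setschenow=fit,
        ionization=ionization,
        speciation=speciation,
        activity=activity,
        s0_water=s0_water,
        n_iter=n_iter,
        converged=converged,
        pK0_spread=pK0_spread,
    )
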