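"""Self-validation studies: round trips, coverage, and numerical oracles.

These routines exercise the whole pipeline on synthetic experiments with
known ground truth.  They back both the test suite and the reproduction
script, and are ordinary library code: nothing here reads external data.
"""

from __future__ import annotations

import numpy as np

from .activity import fit_setschenow_solubility
from .calibration import aggregate_replicates, fit_calibration, quantify
from .ionization import solve_saturation
from .pipeline import analyze_dataset
from .solubility import fit_total_solubility
from .synthetic import (
    GroundTruth,
    PAPER_M_GRID,
    STANDARD_RANGES,
    make_paper_like_truth,
    simulate_experiment,
)
from .units import AcidSpec, NACL, SolubilityPoint, WATER

__all__ = [
    "zero_noise_roundtrip",
    "coverage_study",
    "speciation_oracle_check",
    "bisect_hydrogen",
]


def zero_noise_roundtrip(
    seed: int = 0, subclass: str = "hydroxycinnamic"
) -> dict[str, float]:
    """Relative recovery errors of every truth parameter at zero noise.

    Simulates a noise-free, unquantized experiment from a paper-like
    ground truth and runs the full analysis; returns the relative error of
    log_S_T0, a_0, a_inf, k_0, k_inf and pK0 (per medium where relevant).
    """
    truth = make_paper_like_truth(subclass, seed=seed)
    ds = simulate_experiment(
        truth, noise_rel=0.0, n_rep=1, seed=seed, quantize=False
    )
    res = analyze_dataset(ds, model="auto")

    def rel(est: float, tru: float) -> float:
        return abs(est - tru) / abs(tru)

    errors = {
        "log_S_T0": rel(float(np.log10(res.water_point.S_T)), truth.log_S_T0)
    }
    for med, corr in res.correction.items():
        f = corr.setschenow
        errors[f"k_0[{med}]"] = rel(f.k_0, truth.k_0)
        errors[f"k_inf[{med}]"] = rel(f.k_inf, truth.k_inf)
        errors[f"a_0[{med}]"] = rel(-f.k_0, truth.a_0)
        errors[f"a_inf[{med}]"] = rel(-f.k_inf, truth.a_inf)
        errors[f"pK0[{med}]"] = rel(corr.pK0, truth.pK0)
    return errors


def _non_ionizing_truth(rng: np.random.Generator, linear: bool) -> GroundTruth:
    """A hydroxycinnamic-like truth with ionization switched off."""
    k_inf = float(rng.uniform(0.08, 0.18))
    k_0 = k_inf if linear else float(rng.uniform(1.3, 2.2)) * k_inf
    acid = AcidSpec(
        name="synthetic-coverage",
        molar_mass=180.0,
        lambda_analytical=287.0,
    )
    return GroundTruth(
        acid=acid,
        log_S_T0=float(rng.uniform(-2.45, -1.95)),
        a_0=-k_0,
        a_inf=-k_inf,
        pK0=None,
        slope_cal=100.0,
        dilution=1.0,
        standard_range=STANDARD_RANGES["hydroxycinnamic"],
    )


def _fit_one_dataset(truth: GroundTruth, seed: int, model: str):
    """Calibrate, quantify and fit a single simulated dataset.

    Calibration is through-origin here (the simulated standards have no
    blank offset), so its slope error acts as a common multiplicative
    factor absorbed by the fitted intercepts.
    """
    ds = simulate_experiment(
        truth, media=[NACL], m_grid=PAPER_M_GRID, n_rep=3,
        noise_rel=0.02, seed=seed,
    )
    curve = fit_calibration(
        [(mol, a) for mol, a, _ in ds.standards], through_origin=True
    )
    points = []
    by_m: dict[float, list[float]] = {}
    for _, m_salt, _, a in ds.samples:
        by_m.setdefault(m_salt, []).append(
            quantify(a, curve, ds.dilution).value
        )
    for m_salt, vals in sorted(by_m.items()):
        mean, sd, _ = aggregate_replicates(vals)
        medium = WATER if m_salt == 0 else NACL
        points.append(
            SolubilityPoint(medium=medium, m_salt=m_salt, S_T=mean,
                            replicates=vals, sd=sd)
        )
    smooth = fit_total_solubility(points, model=model)
    obs_m = np.concatenate([[p.m_salt] * len(p.replicates) for p in points])
    obs_y = np.log10(np.concatenate([p.replicates for p in points]))
    sets = fit_setschenow_solubility(
        obs_m, obs_y, model="constant" if model == "linear" else "extended"
    )
    return smooth, sets


def coverage_study(
    n_datasets: int = 200,
    seed: int = 0,
    truth_model: str = "extended",
    level: float = 0.95,
) -> dict[str, float]:
    """Monte-Carlo CI coverage and bias of the empirical-fit stages.

    Simulates ``n_datasets`` triplicate experiments at 2% relative
    absorbance noise from non-ionizing ground truths (so the smoothing fit
    of total solubility targets a_0/a_inf exactly), fits each, and reports
    the fraction of nominal ``level`` confidence intervals containing the
    truth plus estimator bias and its Monte-Carlo standard error.
    """
    if truth_model not in ("extended", "linear"):
        raise ValueError("truth_model must be 'extended' or 'linear'")
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=n_datasets)
    linear = truth_model == "linear"

    cover = {"a_0": 0, "a_inf": 0, "k_0": 0, "k_inf": 0}
    err = {"a_0": [], "a_inf": [], "k_0": [], "k_inf": []}
    for s in seeds:
        rng = np.random.default_rng(int(s))
        truth = _non_ionizing_truth(rng, linear=linear)
        smooth, sets = _fit_one_dataset(truth, int(s), truth_model)
        ci_a = smooth.conf_int(level)
        ci_k = sets.conf_int(level)
        for name, est, tru, ci in (
            ("a_0", smooth.a_0, truth.a_0, ci_a[1]),
            ("a_inf", smooth.a_inf, truth.a_inf, ci_a[2]),
            ("k_0", sets.k_0, truth.k_0, ci_k[0]),
            ("k_inf", sets.k_inf, truth.k_inf, ci_k[1]),
        ):
            cover[name] += int(ci[0] <= tru <= ci[1])
            err[name].append(est - tru)

    out: dict[str, float] = {"n_datasets": float(n_datasets)}
    for name in cover:
        e = np.asarray(err[name])
        out[f"coverage_{name}"] = cover[name] / n_datasets
        out[f"bias_{name}"] = float(e.mean())
        out[f"mc_se_{name}"] = float(e.std(ddof=1) / np.sqrt(n_datasets))
    return out


def bisect_hydrogen(S_T: float, K_I: float, iters: int = 200) -> float:
    """Bisection oracle for [H+]: root of h^2 + K h - K S_T on [0, S_T].

    Deliberately independent of the closed-form quadratic solver.
    """
    if K_I == 0.0:
        return 0.0
    lo, hi = 0.0, S_T
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if mid * mid + K_I * mid - K_I * S_T <= 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 0.0:
            break
    return 0.5 * (lo + hi)


def speciation_oracle_check(n: int = 20) -> float:
    """Max relative disagreement of the quadratic [H+] vs bisection.

    Evaluated on an ``n x n`` log-grid of total solubilities (1e-4..1
    mol/kg) and ionization constants (1e-8..1e-1 mol/kg).
    """
    import warnings

    max_rel = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for S_T in np.logspace(-4, 0, n):
            for K in np.logspace(-8, -1, n):
                h_quad = solve_saturation(float(S_T), float(K)).h
                h_bis = bisect_hydrogen(float(S_T), float(K))
                max_rel = max(max_rel, abs(h_quad - h_bis) / h_bis)
    return max_rel
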