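"""Forward simulation of the saturation-shake-flask / UV-Vis experiment.

The generator emulates the study design: triplicate absorbance readings of
diluted saturated solutions in pure water and in NaCl/NaClO4 at salt
molalities {0.16, 0.5, 1.0, 2.0, 3.0}, together with calibration standards,
all quantized to the 0.001 instrument resolution, with multiplicative
Gaussian replicate noise.

Ground truth is parameterized on the neutral-species curve:

    log10 s0(m) = log10 s0_w + [a_inf + (a_0 - a_inf)/(1 + m)] * m

so the implied Setschenow truth is exactly k_0 = -a_0, k_inf = -a_inf.
Ionization is then added back on top: K(I) follows the SIT relation with
the local effective k(m), [H+] = sqrt(K * s0), and the simulated total
solubility is S_T = s0 + [H+].  ``log_S_T0`` in the ground truth is the
total solubility in pure water; the neutral water solubility s0_w is
recovered from it through the same speciation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .calibration import ABSORBANCE_RESOLUTION
from .ionization import SITParams, pK_at_I
from .units import AcidSpec, Medium, NACL, NACLO4

__all__ = [
    "GroundTruth",
    "SimulatedDataset",
    "simulate_experiment",
    "make_paper_like_truth",
    "PAPER_M_GRID",
]

#: Salt molalities of the emulated design (mol/kg).
PAPER_M_GRID = (0.16, 0.5, 1.0, 2.0, 3.0)

#: Calibration standard ranges (molal, cuvette scale) by acid subclass.
STANDARD_RANGES = {
    "hydroxybenzoic": (2.0e-3, 25.0e-3),
    "hydroxycinnamic": (1.0e-3, 10.0e-3),
}


@dataclass(frozen=True)
class GroundTruth:
    """Known parameters a simulated experiment is generated from."""

    acid: AcidSpec
    log_S_T0: float  # log10 total solubility in pure water, mol/kg
    a_0: float  # zero-ionic-strength slope of the neutral curve, kg/mol
    a_inf: float  # infinite-ionic-strength slope, kg/mol
    pK0: float | None  # None -> treated as non-ionizing
    slope_cal: float  # effective calibration slope, absorbance/(mol/kg)
    sit: dict[str, SITParams] = field(default_factory=dict)  # per medium name
    dilution: float = 1.0
    standard_range: tuple[float, float] = (1.0e-3, 10.0e-3)
    subclass: str = "hydroxycinnamic"

    def __post_init__(self) -> None:
        if self.slope_cal <= 0:
            raise ValueError("slope_cal must be positive")

    @property
    def k_0(self) -> float:
        """Setschenow coefficient at zero ionic strength implied by a_0."""
        return -self.a_0

    @property
    def k_inf(self) -> float:
        return -self.a_inf

    def effective_k(self, m) -> np.ndarray | float:
        m = np.asarray(m, dtype=float)
        return self.k_inf + (self.k_0 - self.k_inf) / (1.0 + m)

    def s0_water(self) -> float:
        """Neutral-species solubility in pure water.

        Solves ``S_T0 = s0 + sqrt(K0 * s0)`` (speciation with [H+]=[A-]).
        """
        S_T0 = 10.0**self.log_S_T0
        if self.pK0 is None:
            return S_T0
        K0 = 10.0**-self.pK0
        u = (-np.sqrt(K0) + np.sqrt(K0 + 4.0 * S_T0)) / 2.0
        return float(u**2)

    def curves(self, medium: Medium, m) -> dict[str, np.ndarray]:
        """Noiseless forward model on a molality grid.

        Returns arrays ``s0``, ``h``, ``S_T`` and ``pK_I`` (NaN where the
        acid is non-ionizing) for ``medium`` at salt molalities ``m``.
        """
        m = np.atleast_1d(np.asarray(m, dtype=float))
        log_s0 = np.log10(self.s0_water()) - self.effective_k(m) * m
        s0 = 10.0**log_s0
        if self.pK0 is None:
            h = np.zeros_like(s0)
            pk = np.full_like(s0, np.nan)
        else:
            pk = np.array(
                [
                    pK_at_I(
                        self.pK0,
                        mm,
                        self._sit_at(medium, float(self.effective_k(mm))),
                    )
                    for mm in m
                ]
            )
            K = 10.0**-pk
            h = np.sqrt(K * s0)
        return {"s0": s0, "h": h, "S_T": s0 + h, "pK_I": pk}

    def _sit_at(self, medium: Medium, k: float) -> SITParams:
        base = self.sit.get(medium.name)
        if base is None:
            if medium.b_plus is None:
                raise ValueError(f"no SIT parameters for medium {medium.name!r}")
            base = SITParams(b_plus=medium.b_plus, b_minus=self.acid.b_minus)
        return SITParams(
            b_plus=base.b_plus,
            b_minus=base.b_minus,
            k=k,
            debye_a=base.debye_a,
            debye_b=base.debye_b,
        )

    def measured_pK(
        self, medium: Medium, I_values=(0.16, 0.51)
    ) -> tuple[tuple[float, float], ...]:
        """Noiseless 'measured' pK values the SIT stage will consume."""
        if self.pK0 is None:
            return ()
        return tuple(
            (
                float(i),
                float(
                    pK_at_I(
                        self.pK0, i, self._sit_at(medium, float(self.effective_k(i)))
                    )
                ),
            )
            for i in I_values
        )


@dataclass(frozen=True)
class SimulatedDataset:
    """One simulated experiment: standards, samples and the truth sidecar."""

    truth: GroundTruth
    seed: int
    # (molality, absorbance, replicate)
    standards: tuple[tuple[float, float, int], ...]
    # (medium name, m_salt, replicate, absorbance)
    samples: tuple[tuple[str, float, int, float], ...]
    # per-medium "measured" pK pairs for the SIT stage
    pk_measured: dict[str, tuple[tuple[float, float], ...]]
    media: tuple[Medium, ...]
    dilution: float
    noise_rel: float
    quantized: bool

    def acid_with_pk(self, medium: Medium) -> AcidSpec:
        """The acid spec carrying this medium's measured pK values."""
        return AcidSpec(
            name=self.truth.acid.name,
            molar_mass=self.truth.acid.molar_mass,
            lambda_analytical=self.truth.acid.lambda_analytical,
            pK_measured=self.pk_measured.get(medium.name, ()),
            b_minus=self.truth.acid.b_minus,
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the pre-picked long-format CSV the calibration stage reads."""
        lines = [
            "acid,role,medium,ionic_strength_molal,replicate,absorbance_at_peak"
        ]
        name = self.truth.acid.name
        for mol, absorbance, rep in self.standards:
            lines.append(f"{name},standard,water,{mol!r},{rep},{absorbance!r}")
        for medium, m_salt, rep, absorbance in self.samples:
            lines.append(f"{name},sample,{medium},{m_salt!r},{rep},{absorbance!r}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    def truth_sidecar(self, path: str | Path) -> None:
        """Write the ground-truth JSON sidecar for test harnesses."""
        payload = {
            "seed": self.seed,
            "acid": self.truth.acid.name,
            "log_S_T0": self.truth.log_S_T0,
            "a_0": self.truth.a_0,
            "a_inf": self.truth.a_inf,
            "k_0": self.truth.k_0,
            "k_inf": self.truth.k_inf,
            "pK0": self.truth.pK0,
            "slope_cal": self.truth.slope_cal,
            "dilution": self.dilution,
            "sit": {
                name: asdict(p) for name, p in self.truth.sit.items()
            },
        }
        Path(path).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def _quantize(a: np.ndarray, enabled: bool) -> np.ndarray:
    if not enabled:
        return a
    return np.round(a / ABSORBANCE_RESOLUTION) * ABSORBANCE_RESOLUTION


def simulate_experiment(
    truth: GroundTruth,
    media: list[Medium] | None = None,
    m_grid=PAPER_M_GRID,
    n_rep: int = 3,
    noise_rel: float = 0.02,
    seed: int = 0,
    quantize: bool = True,
    n_standards: int = 8,
) -> SimulatedDataset:
    """Simulate standards and saturated-sample absorbances from ``truth``.

    Noise is multiplicative Gaussian on absorbance (relative sd
    ``noise_rel``); readings are then quantized to the 0.001 instrument
    step unless ``quantize=False``.  The same seed always reproduces the
    same dataset.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if noise_rel < 0:
        raise ValueError("noise_rel must be non-negative")
    if np.any(np.asarray(m_grid) < 0):
        raise ValueError("salt molalities must be non-negative")
    media = list(media) if media is not None else [NACL, NACLO4]
    rng = np.random.default_rng(seed)

    lo, hi = truth.standard_range
    std_m = np.linspace(lo, hi, n_standards)
    standards = []
    for mol in std_m:
        # standards are read undiluted at the cuvette concentration
        a_true = truth.slope_cal * mol
        noise = rng.normal(0.0, noise_rel, size=n_rep) if noise_rel else np.zeros(n_rep)
        a = _quantize(a_true * (1.0 + noise), quantize)
        for rep in range(1, n_rep + 1):
            standards.append((float(mol), float(a[rep - 1]), rep))

    samples = []
    grid = [("water", 0.0)] + [(md.name, float(mm)) for md in media for mm in m_grid]
    media_by_name = {md.name: md for md in media}
    for med_name, m_salt in grid:
        if med_name == "water":
            S_T = 10.0**truth.log_S_T0
        else:
            S_T = float(truth.curves(media_by_name[med_name], [m_salt])["S_T"][0])
        a_true = truth.slope_cal * S_T / truth.dilution
        noise = rng.normal(0.0, noise_rel, size=n_rep) if noise_rel else np.zeros(n_rep)
        a = _quantize(a_true * (1.0 + noise), quantize)
        for rep in range(1, n_rep + 1):
            samples.append((med_name, m_salt, rep, float(a[rep - 1])))

    pk_measured = {md.name: truth.measured_pK(md) for md in media}
    return SimulatedDataset(
        truth=truth,
        seed=seed,
        standards=tuple(standards),
        samples=tuple(samples),
        pk_measured=pk_measured,
        media=tuple(media),
        dilution=truth.dilution,
        noise_rel=noise_rel,
        quantized=quantize,
    )


#: Analytical wavelengths reported for each subclass (nm).
_WAVELENGTHS = {
    "hydroxybenzoic": (251.0, 258.0, 262.0),
    "hydroxycinnamic": (287.0, 288.0),
}
_MOLAR_MASSES = {
    "hydroxybenzoic": (150.0, 200.0),
    "hydroxycinnamic": (160.0, 200.0),
}
#: Target salting-out window (percent of S_T0 lost at m = 3) by subclass:
#: hydroxycinnamic acids lose 40-70% at the highest ionic strength, the
#: more soluble hydroxybenzoic acids somewhat less.
_SALTING_WINDOW = {
    "hydroxybenzoic": (18.0, 55.0),
    "hydroxycinnamic": (42.0, 68.0),
}
_LOG_S_RANGES = {
    "hydroxybenzoic": (-1.45, -0.95),
    "hydroxycinnamic": (-2.45, -1.95),
}


def make_paper_like_truth(
    subclass: str = "hydroxycinnamic",
    seed: int = 0,
    media: list[Medium] | None = None,
) -> GroundTruth:
    """Sample a plausible ground truth for one acid of the given subclass.

    The sampler encodes the study's qualitative structure: hydroxybenzoic
    acids are about a decade more soluble than hydroxycinnamic ones;
    all acids salt out (positive Setschenow coefficients with k_0 >= k_inf,
    i.e. log gamma flattening toward high ionic strength); the total
    solubility lost at the highest molality falls in the subclass's
    characteristic window (40-70% for the hydroxycinnamic acids).
    Sampling is by rejection against the exact forward model.
    """
    if subclass not in _SALTING_WINDOW:
        raise ValueError(f"unknown subclass {subclass!r}")
    media = list(media) if media is not None else [NACL, NACLO4]
    rng = np.random.default_rng(seed)
    lo_pct, hi_pct = _SALTING_WINDOW[subclass]

    wl = float(rng.choice(_WAVELENGTHS[subclass]))
    mm_lo, mm_hi = _MOLAR_MASSES[subclass]
    acid = AcidSpec(
        name=f"{subclass}-synthetic-{seed}",
        molar_mass=float(rng.uniform(mm_lo, mm_hi)),
        lambda_analytical=wl,
    )
    if subclass == "hydroxybenzoic":
        slope_cal, dilution = 40.0, 5.0
    else:
        slope_cal, dilution = 100.0, 1.0
    sit = {
        md.name: SITParams(b_plus=md.b_plus, b_minus=acid.b_minus)
        for md in media
    }

    for _ in range(1000):
        log_S_T0 = float(rng.uniform(*_LOG_S_RANGES[subclass]))
        # target fractional drop at m = 3 and curvature ratio k_0/k_inf
        drop = rng.uniform(lo_pct / 100.0, hi_pct / 100.0)
        ratio = rng.uniform(1.05, 2.2)
        # -log10(1 - drop) = 3 * (k_inf + (k_0 - k_inf)/4) to leading order
        k_inf = -np.log10(1.0 - drop) / (3.0 * (0.75 + 0.25 * ratio))
        k_0 = ratio * k_inf
        truth = GroundTruth(
            acid=acid,
            log_S_T0=log_S_T0,
            a_0=-float(k_0),
            a_inf=-float(k_inf),
            pK0=float(rng.uniform(4.0, 4.6)),
            slope_cal=slope_cal,
            sit=sit,
            dilution=dilution,
            standard_range=STANDARD_RANGES[subclass],
            subclass=subclass,
        )
        S_T0 = 10.0**truth.log_S_T0
        ok = True
        for md in media:
            S_T3 = float(truth.curves(md, [3.0])["S_T"][0])
            pct = (S_T0 - S_T3) * 100.0 / S_T0
            if not (lo_pct < pct < hi_pct):
                ok = False
                break
        if ok:
            return truth
    raise RuntimeError("rejection sampler failed to find a valid truth")
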