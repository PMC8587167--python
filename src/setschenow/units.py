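"""Concentration-scale semantics and shared containers.

Everything downstream works on the molal scale (mol per kg of water): the
ionization and activity models are written in molality, and molality is
temperature-independent.  Molar inputs are converted only when the user
supplies solution densities; mass fractions are provided for comparison
with literature solubility tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .exceptions import InvalidDensityError

__all__ = [
    "Medium",
    "AcidSpec",
    "SolubilityPoint",
    "WATER",
    "NACL",
    "NACLO4",
    "molar_to_molal",
    "molal_to_mass_fraction",
    "mass_fraction_to_molal",
]

#: Recorded spectral window of the UV instrument, nm.
SPECTRAL_WINDOW = (200.0, 300.0)


@dataclass(frozen=True)
class Medium:
    """An aqueous ionic medium (or pure water).

    Parameters
    ----------
    name:
        Identifier, e.g. ``"NaCl"``, ``"NaClO4"`` or ``"water"``.
    b_plus:
        SIT interaction coefficient of H+ with the medium anion,
        kg mol^-1.  ``None`` for pure water (unused there).
    salt_molar_mass:
        Molar mass of the background salt, g mol^-1 (0 for water).
    """

    name: str
    b_plus: float | None = None
    salt_molar_mass: float = 0.0

    def __post_init__(self) -> None:
        if self.name != "water" and self.b_plus is None:
            raise ValueError(
                f"medium {self.name!r} needs a b_plus SIT coefficient"
            )
        if self.salt_molar_mass < 0:
            raise ValueError("salt_molar_mass must be non-negative")

    @property
    def is_water(self) -> bool:
        return self.name == "water"


WATER = Medium("water")
NACL = Medium("NaCl", b_plus=0.12, salt_molar_mass=58.44)
NACLO4 = Medium("NaClO4", b_plus=0.14, salt_molar_mass=122.44)


@dataclass(frozen=True)
class AcidSpec:
    """A weak (monoprotic) acid analyte.

    ``pK_measured`` holds stoichiometric ionization constants measured at
    known ionic strengths (molal), used by the SIT extrapolation; it may be
    empty for a solute treated as non-ionizing.
    """

    name: str
    molar_mass: float
    lambda_analytical: float
    pK_measured: tuple[tuple[float, float], ...] = ()
    b_minus: float = 0.06  # A-/Na+ SIT coefficient, kg/mol

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")
        lo, hi = SPECTRAL_WINDOW
        if not (lo <= self.lambda_analytical <= hi):
            raise ValueError(
                f"analytical wavelength {self.lambda_analytical} nm outside "
                f"the recorded window [{lo}, {hi}] nm"
            )
        object.__setattr__(self, "pK_measured", tuple(
            (float(i), float(pk)) for i, pk in self.pK_measured
        ))
        for ionic_strength, pk in self.pK_measured:
            if ionic_strength < 0:
                raise ValueError("pK_measured ionic strength must be >= 0")
            if not (0.0 < pk < 14.0):
                raise ValueError(f"pK {pk} outside (0, 14)")


@dataclass
class SolubilityPoint:
    """Total solubility of an acid at one salt molality.

    ``S_T`` is the saturation molality of all solute forms; when replicate
    values are given, ``S_T`` must be their mean and ``sd`` their sample
    standard deviation.
    """

    medium: Medium
    m_salt: float
    S_T: float
    replicates: list[float] = field(default_factory=list)
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.S_T <= 0:
            raise ValueError("S_T must be positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.m_salt < 0:
            raise ValueError("m_salt must be non-negative")
        if self.medium.is_water and self.m_salt != 0:
            raise ValueError("water points must have m_salt == 0")
        if self.replicates:
            mean = sum(self.replicates) / len(self.replicates)
            if not math.isclose(mean, self.S_T, rel_tol=1e-9, abs_tol=1e-15):
                raise ValueError("S_T must equal the mean of replicates")


def molar_to_molal(
    c: float, density: float, salt_molar_mass: float
) -> float:
    """Convert molarity (mol/L) to molality (mol/kg water).

    Uses ``m = c / (density - c * M / 1000)`` with ``density`` in g/mL and
    ``M`` in g/mol: the denominator is the mass of water per mL of solution.
    """
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if c == 0:
        return 0.0
    denom = density - c * salt_molar_mass / 1000.0
    if denom <= 0:
        raise InvalidDensityError(
            f"density {density} g/mL leaves no solvent mass at c={c} mol/L"
        )
    return c / denom


def molal_to_mass_fraction(
    m_solute: float,
    M_solute: float,
    m_salt: float = 0.0,
    M_salt: float = 0.0,
) -> float:
    """Mass fraction of the solute on the per-kg-of-water basis.

    chi = m*M / (1000 + m*M + m_salt*M_salt); dimensionless, in [0, 1).
    """
    if min(m_solute, M_solute, m_salt, M_salt) < 0:
        raise ValueError("all arguments must be non-negative")
    grams = m_solute * M_solute
    return grams / (1000.0 + grams + m_salt * M_salt)


def mass_fraction_to_molal(
    chi: float,
    M_solute: float,
    m_salt: float = 0.0,
    M_salt: float = 0.0,
) -> float:
    """Inverse of :func:`molal_to_mass_fraction` at fixed salt content."""
    if not (0.0 <= chi < 1.0):
        raise ValueError("mass fraction must be in [0, 1)")
    if M_solute <= 0:
        raise ValueError("M_solute must be positive")
    return chi * (1000.0 + m_salt * M_salt) / (M_solute * (1.0 - chi))
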