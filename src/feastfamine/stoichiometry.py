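"""Cmol arithmetic for mixed-culture PHB stoichiometry.

All compounds are expressed per carbon atom (Cmol basis), the standard
bookkeeping unit in mixed-culture PHA work: active biomass is CH1.8O0.5N0.2
(24.6 g/Cmol), PHB monomer C4H6O2 normalises to CH1.5O0.5 (21.5 g/Cmol) and
acetate C2H4O2 to CH2O.  Degrees of reduction (electron equivalents per
Cmol, ammonia as nitrogen reference) close the oxygen balance:
one mol O2 accepts 4 electron equivalents.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ElementalFormula",
    "BIOMASS",
    "PHB",
    "ACETATE",
    "BIOMASS_G_PER_CMOL",
    "PHB_G_PER_CMOL",
    "GAMMA_ACETATE",
    "GAMMA_PHB",
    "GAMMA_BIOMASS",
    "cmol_mass",
    "degree_of_reduction",
    "mass_to_cmol",
    "cmol_to_mass",
    "active_biomass",
    "phb_weight_fraction",
]

#: IUPAC 2021 standard atomic weights (g/mol).
ATOMIC_WEIGHTS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}


class InvalidFormulaError(ValueError):
    """Raised for elemental formulas with negative coefficients."""


class InconsistentMeasurementError(ValueError):
    """Raised when reported PHB exceeds reported VSS."""


@dataclass(frozen=True)
class ElementalFormula:
    """Per-carbon-atom elemental composition CH(h)O(o)N(n).

    Coefficients are dimensionless stoichiometric ratios relative to one
    carbon atom; construct from an arbitrary C(c)H(h)O(o)N(n) formula with
    :meth:`from_counts`, which scales carbon to exactly 1.
    """

    h: float
    o: float
    n: float = 0.0

    def __post_init__(self) -> None:
        if self.h < 0 or self.o < 0 or self.n < 0:
            raise InvalidFormulaError(
                f"negative stoichiometric coefficient in CH{self.h}O{self.o}N{self.n}"
            )

    @classmethod
    def from_counts(cls, c: float, h: float, o: float, n: float = 0.0) -> "ElementalFormula":
        """Normalise C(c)H(h)O(o)N(n) to one carbon, e.g. C4H6O2 -> CH1.5O0.5."""
        if c <= 0:
            raise InvalidFormulaError("carbon count must be positive")
        if h < 0 or o < 0 or n < 0:
            raise InvalidFormulaError("negative stoichiometric coefficient")
        return cls(h / c, o / c, n / c)


#: Active biomass, the conventional mixed-culture composition CH1.8O0.5N0.2.
BIOMASS = ElementalFormula(1.8, 0.5, 0.2)
#: PHB monomer C4H6O2 on a per-carbon basis (CH1.5O0.5).
PHB = ElementalFormula.from_counts(4, 6, 2)
#: Acetate C2H4O2 on a per-carbon basis (CH2O).
ACETATE = ElementalFormula.from_counts(2, 4, 2)


def cmol_mass(formula: ElementalFormula) -> float:
    """Grams per carbon-mole of a per-carbon formula.

    Sum of coefficient x standard atomic weight; CH1.8O0.5N0.2 gives 24.63
    (24.6 at the 1-decimal precision used for reporting), CH1.5O0.5 gives
    21.52.
    """
    w = ATOMIC_WEIGHTS
    return w["C"] + formula.h * w["H"] + formula.o * w["O"] + formula.n * w["N"]


def degree_of_reduction(formula: ElementalFormula, nitrogen_source: str = "ammonia") -> float:
    """Electron equivalents per Cmol: gamma = 4 C + 1 H - 2 O - 3 N.

    The nitrogen valence (-3) takes ammonia as the reference nitrogen
    source; no other reference is supported.  Acetate (CH2O) gives exactly
    4.0, PHB (CH1.5O0.5) 4.5 and biomass (CH1.8O0.5N0.2) 4.2.
    """
    if nitrogen_source != "ammonia":
        raise ValueError(f"unsupported nitrogen source: {nitrogen_source!r}")
    return 4.0 + formula.h - 2.0 * formula.o - 3.0 * formula.n


BIOMASS_G_PER_CMOL = cmol_mass(BIOMASS)  # 24.63
PHB_G_PER_CMOL = cmol_mass(PHB)  # 21.52
GAMMA_ACETATE = degree_of_reduction(ACETATE)  # 4.0
GAMMA_PHB = degree_of_reduction(PHB)  # 4.5
GAMMA_BIOMASS = degree_of_reduction(BIOMASS)  # 4.2


def mass_to_cmol(concentration_g_per_l: float, mass_g_per_cmol: float) -> float:
    """Convert g/L to Cmmol/L given the compound's Cmol mass."""
    if mass_g_per_cmol <= 0:
        raise ValueError("Cmol mass must be strictly positive")
    if concentration_g_per_l < 0:
        raise ValueError("concentration must be non-negative")
    return concentration_g_per_l / mass_g_per_cmol * 1000.0


def cmol_to_mass(concentration_cmmol_per_l: float, mass_g_per_cmol: float) -> float:
    """Convert Cmmol/L to g/L; inverse of :func:`mass_to_cmol`."""
    if mass_g_per_cmol <= 0:
        raise ValueError("Cmol mass must be strictly positive")
    if concentration_cmmol_per_l < 0:
        raise ValueError("concentration must be non-negative")
    return concentration_cmmol_per_l * mass_g_per_cmol / 1000.0


def active_biomass(vss_g_per_l: float, phb_g_per_l: float | None = None,
                   phb_fraction: float | None = None) -> float:
    """Active biomass X = VSS - PHB (g/L).

    Either the PHB concentration (g/L) or the PHB weight fraction of VSS
    may be given; with a fraction, PHB = VSS x PHB%.
    """
    if phb_g_per_l is None:
        if phb_fraction is None:
            raise ValueError("give either phb_g_per_l or phb_fraction")
        if not 0.0 <= phb_fraction <= 1.0:
            raise ValueError("phb_fraction must be within [0, 1]")
        phb_g_per_l = vss_g_per_l * phb_fraction
    if phb_g_per_l > vss_g_per_l:
        raise InconsistentMeasurementError(
            f"PHB ({phb_g_per_l} g/L) exceeds VSS ({vss_g_per_l} g/L)"
        )
    return vss_g_per_l - phb_g_per_l


def phb_weight_fraction(phb_cmmol_per_l: float, x_cmmol_per_l: float) -> float:
    """PHB weight fraction of total solids, TSS = X*24.6 + PHB*21.5 (g basis)."""
    phb_g = cmol_to_mass(phb_cmmol_per_l, PHB_G_PER_CMOL)
    x_g = cmol_to_mass(x_cmmol_per_l, BIOMASS_G_PER_CMOL)
    tss = phb_g + x_g
    if tss <= 0:
        return 0.0
    return phb_g / tss
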