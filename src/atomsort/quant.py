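"""Internal-standard qNMR: integrals → concentrations → masses → titers.

Quantification compares an analyte's 1D-¹H integral per proton against that
of a species of known concentration in the same tube — here the residual
CHD₂ methyl resonance of the CD₃OD solvent:

    c_analyte = (I_a / n_a) / (I_s / n_s) · c_s

From the in-tube concentration, mass in the NMR tube follows from the tube
volume and molecular weight, and the culture titer (mg product per litre of
culture) follows by scaling the tube mass up through the extraction chain
(crude-extract aliquot fraction and the dissolved/loaded volume ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "IntegralMeasurement",
    "InternalStandard",
    "QuantRecord",
    "SampleChain",
    "concentration_from_integrals",
    "mass_in_tube",
    "equivalent_volume",
    "titer_from_tube",
    "isolated_yield",
    "DEFAULT_STANDARD_CONCENTRATION_MM",
]

# Residual CHD2OD concentration in nominally 99.8 atom % D methanol-d4:
# neat CD3OD is ~24.6 M; with 0.2% 1H per site the singly protonated methyl
# isotopologue is ~3 x 0.002 x 24.6 M ~= 0.15 M.
DEFAULT_STANDARD_CONCENTRATION_MM = 150.0


@dataclass(frozen=True)
class IntegralMeasurement:
    """A 1D-¹H integral for one analyte resonance.

    ``n_protons`` is the number of protons under the integrated resonance
    and must be supplied by the caller for each measurement.
    """

    compound_name: str
    integral: float
    n_protons: int = 1

    def __post_init__(self) -> None:
        if self.integral < 0:
            raise ValueError("integral must be >= 0")
        if self.n_protons < 1:
            raise ValueError("n_protons must be >= 1")


@dataclass(frozen=True)
class InternalStandard:
    """The reference species of known concentration in the same tube."""

    integral: float
    n_protons: int = 1  # CHD2 isotopologue: one proton
    concentration: float = DEFAULT_STANDARD_CONCENTRATION_MM  # mM

    def __post_init__(self) -> None:
        if self.integral <= 0:
            raise ValueError("standard integral must be > 0")
        if self.concentration <= 0:
            raise ValueError("standard concentration must be > 0")


@dataclass(frozen=True)
class QuantRecord:
    """Quantification of one compound in one culture."""

    compound_name: str
    concentration: float  # mM in tube
    mass_tube: float  # µg
    mol_weight: float  # g/mol
    titer: float | None = None  # mg/L of culture


@dataclass(frozen=True)
class SampleChain:
    """The sample-preparation chain linking the NMR tube back to the culture.

    Defaults follow the microscale protocol: the crude extract aliquot
    (``aliquot_fraction``, 2% m/m) is dissolved in ``dissolved_volume``
    (200 µL) of CD₃OD of which ``tube_volume`` (50 µL) is loaded.  The
    culture volume equivalent to the tube contents is then
    aliquot_fraction · (tube/dissolved) · culture_volume; an explicit
    ``equivalent_volume_override`` (mL) takes precedence when the effective
    aliquot fraction was calibrated rather than assumed.
    """

    tube_volume: float = 50.0  # µL
    dissolved_volume: float = 200.0  # µL
    aliquot_fraction: float = 0.02
    culture_volume: float = 1000.0  # mL
    equivalent_volume_override: float | None = None  # mL

    def __post_init__(self) -> None:
        if not (0 < self.tube_volume <= self.dissolved_volume):
            raise ValueError("require 0 < tube_volume <= dissolved_volume")
        if not (0 < self.aliquot_fraction <= 1):
            raise ValueError("aliquot_fraction must be in (0, 1]")
        if self.culture_volume <= 0:
            raise ValueError("culture_volume must be > 0")


def concentration_from_integrals(
    analyte: IntegralMeasurement, standard: InternalStandard
) -> float:
    """In-tube analyte concentration (mM) by per-proton integral ratio."""
    if standard.integral <= 0:
        raise ValueError("standard integral must be > 0")
    per_proton_analyte = analyte.integral / analyte.n_protons
    per_proton_standard = standard.integral / standard.n_protons
    return per_proton_analyte / per_proton_standard * standard.concentration


def mass_in_tube(concentration: float, tube_volume: float, mol_weight: float) -> float:
    """Mass (µg) in the tube: concentration (mM) × volume (µL) × MW (g/mol).

    mM·µL = nmol; nmol × g/mol = ng; ×10⁻³ → µg.
    """
    if concentration < 0 or tube_volume < 0 or mol_weight < 0:
        raise ValueError("inputs must be >= 0")
    return concentration * tube_volume * mol_weight * 1e-3


def equivalent_volume(chain: SampleChain) -> float:
    """Culture volume (mL) whose product ends up in the NMR tube."""
    if chain.equivalent_volume_override is not None:
        return chain.equivalent_volume_override
    return (
        chain.aliquot_fraction
        * (chain.tube_volume / chain.dissolved_volume)
        * chain.culture_volume
    )


def titer_from_tube(mass_tube: float, equivalent_volume_ml: float) -> float:
    """Culture titer (mg/L) from in-tube mass (µg) and equivalent culture
    volume (mL): µg/mL ≡ mg/L."""
    if equivalent_volume_ml <= 0:
        raise ValueError("equivalent volume must be > 0")
    return mass_tube / equivalent_volume_ml


def isolated_yield(mass_mg: float, culture_volume_l: float) -> float:
    """Isolated yield (mg/L), reported to one decimal."""
    if culture_volume_l <= 0:
        raise ValueError("culture volume must be > 0")
    return round(mass_mg / culture_volume_l, 1)
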