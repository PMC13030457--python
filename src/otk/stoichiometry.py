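"""Surface-saturation dosing and concentration conversions.

The saturation formula S = 6*C / (rho * d) uses a deliberately mixed unit
convention (C in mg/m^2, rho in g/cm^3, d in um, giving S in mg protein
per g of microspheres). Because silent unit mix-ups are the main failure
mode here, inputs are checked against plausibility bands and SI-coherent
values passed by mistake are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CoatingSpec", "saturation_amount", "molar_concentration", "coating_plan"]

# plausibility bands for the mixed-unit convention
_CAPACITY_BAND = (1e-3, 100.0)    # mg/m^2
_DENSITY_BAND = (0.1, 25.0)       # g/cm^3
_DIAMETER_BAND = (0.01, 1000.0)   # um


@dataclass(frozen=True)
class CoatingSpec:
    """Monolayer-dosing inputs.

    capacity_C : protein binding capacity of the surface, mg/m^2
    particle_density : g/cm^3
    particle_diameter : um
    excess_factor : dose multiplier over the theoretical saturation amount
    """

    capacity_C: float
    particle_density: float
    particle_diameter: float
    excess_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.capacity_C < 0:
            raise ValueError("CoatingSpec.capacity_C must be non-negative")
        for name in ("particle_density", "particle_diameter", "excess_factor"):
            if not getattr(self, name) > 0:
                raise ValueError(f"CoatingSpec.{name} must be strictly positive")
        checks = (
            ("capacity_C", self.capacity_C, _CAPACITY_BAND, "mg/m^2"),
            ("particle_density", self.particle_density, _DENSITY_BAND, "g/cm^3"),
            ("particle_diameter", self.particle_diameter, _DIAMETER_BAND, "um"),
        )
        for name, value, (lo, hi), unit in checks:
            if value > 0 and not lo <= value <= hi:
                raise ValueError(
                    f"{name} = {value:g} {unit} outside plausible band "
                    f"[{lo:g}, {hi:g}] {unit}; check that the value is in {unit}, "
                    "not SI base units"
                )


def saturation_amount(spec: CoatingSpec) -> float:
    """Protein mass saturating one gram of microspheres, mg/g.

    S = 6 * C / (rho * d) with C in mg/m^2, rho in g/cm^3 and d in um;
    the mixed units cancel to mg protein per g of particles.
    """
    return 6.0 * spec.capacity_C / (spec.particle_density * spec.particle_diameter)


def molar_concentration(mass_conc_ug_per_ml: float, molecular_weight_kda: float) -> float:
    """Convert a mass concentration (ug/mL) to molarity (mol/L)."""
    if mass_conc_ug_per_ml < 0:
        raise ValueError("mass concentration must be non-negative")
    if molecular_weight_kda <= 0:
        raise ValueError("molecular weight must be positive")
    grams_per_liter = mass_conc_ug_per_ml * 1e-3
    return grams_per_liter / (molecular_weight_kda * 1e3)


def coating_plan(spec: CoatingSpec, particle_mass_g: float) -> dict:
    """Dose summary: saturation amount, total protein for the given particle
    mass, and the excess-multiplied dose (all in mg except S in mg/g)."""
    if particle_mass_g <= 0:
        raise ValueError("particle mass must be positive")
    s = saturation_amount(spec)
    total = s * particle_mass_g
    return {
        "saturation_mg_per_g": s,
        "particle_mass_g": particle_mass_g,
        "protein_needed_mg": total,
        "excess_factor": spec.excess_factor,
        "dose_mg": total * spec.excess_factor,
    }
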