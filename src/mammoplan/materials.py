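"""Tissue material parameters.

Units follow the package convention: Young's modulus in kPa, density in
kg/m^3, Poisson's ratio dimensionless.  Soft glandular/fat tissue sits
around 1 kPa; invasive lesions are roughly an order of magnitude stiffer.
The near-incompressibility of hydrated tissue is modelled with nu close to,
but numerically below, 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Material", "DEFAULT_MATERIALS"]


@dataclass(frozen=True)
class Material:
    young_modulus: float  # kPa
    poisson_ratio: float  # dimensionless, in [0, 0.5)
    density: float = 1000.0  # kg/m^3

    def __post_init__(self):
        if not self.young_modulus > 0:
            raise ValueError("young_modulus must be positive")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must lie in [0, 0.5)")
        if not self.density > 0:
            raise ValueError("density must be positive")

    @property
    def mu_kpa(self) -> float:
        """Shear modulus (kPa)."""
        return self.young_modulus / (2.0 * (1.0 + self.poisson_ratio))

    @property
    def lambda_kpa(self) -> float:
        """First Lamé parameter (kPa)."""
        e, nu = self.young_modulus, self.poisson_ratio
        return e * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))


#: Default breast/tumor pair: soft tissue ~1 kPa, lesion 10x stiffer,
#: near-incompressible but numerically stable.
DEFAULT_MATERIALS = {
    "breast": Material(young_modulus=1.0, poisson_ratio=0.45, density=1000.0),
    "tumor": Material(young_modulus=10.0, poisson_ratio=0.45, density=1000.0),
}
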