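"""Material library: isotropic linear-elastic constants per tissue/implant.

Healing-tissue moduli follow the long-bone-healing literature convention
(granulation 1 MPa ... newly formed bone 1000 MPa); implants are PEEK
(3.5 GPa) or titanium (110 GPa).  Units: MPa, dimensionless Poisson ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .construct import CAGE, CORTICAL, FIXATION, TRABECULAR
from .errors import ParameterError

DEFAULT_MATERIALS: dict[str, tuple[float, float]] = {
    "granulation": (1.0, 0.167),
    "fibrous": (2.0, 0.167),
    "cartilage": (10.0, 0.167),
    "bone": (1000.0, 0.325),          # newly formed bone
    "cortical": (10000.0, 0.3),
    "trabecular": (100.0, 0.3),
    "endplate": (23.0, 0.4),          # cartilaginous endplate
    "peek": (3500.0, 0.3),
    "titanium": (110000.0, 0.3),
}


@dataclass
class MaterialLibrary:
    """Map material name -> (Young's modulus E in MPa, Poisson ratio nu)."""

    table: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MATERIALS)
    )

    def __post_init__(self):
        for name, (E, nu) in self.table.items():
            if not E > 0:
                raise ParameterError(f"E must be > 0 for {name!r}, got {E}")
            if not (0 <= nu < 0.5):
                raise ParameterError(f"nu must be in [0, 0.5) for {name!r}, got {nu}")

    def E(self, name: str) -> float:
        return self.table[name][0]

    def nu(self, name: str) -> float:
        return self.table[name][1]

    def region_constants(self, cage_material: str = "peek") -> dict[int, tuple[float, float]]:
        """(E, nu) for the non-healing regions of a construct run."""
        if cage_material not in self.table:
            raise ParameterError(f"unknown cage material {cage_material!r}")
        return {
            CORTICAL: self.table["cortical"],
            TRABECULAR: self.table["trabecular"],
            CAGE: self.table[cage_material],
            FIXATION: self.table["titanium"],
        }
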