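"""Tissue and electrode material properties.

Conductivities are stated per direction because skeletal muscle conducts
roughly three times better along the fibre direction than across it; all
other tissues are isotropic.  Relative permittivities are carried for
completeness but not used by the resistive quasi-static solver.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MaterialSpec:
    """Electrical properties of one homogeneous layer.

    Parameters
    ----------
    name:
        Layer name (``skin``, ``fat``, ``muscle``, ``bone``, ``hydrogel``).
    sigma_axial, sigma_radial:
        Conductivity along / across the arm axis in S/m.  Equal for
        isotropic tissues.
    epsilon_r:
        Relative permittivity (dimensionless, >= 1).  Stored for future
        extension to the capacitive term; the resistive solve ignores it.
    """

    name: str
    sigma_axial: float
    sigma_radial: float
    epsilon_r: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_axial <= 0 or self.sigma_radial <= 0:
            raise ValueError(
                f"material {self.name!r}: conductivities must be > 0"
            )
        if self.epsilon_r < 1:
            raise ValueError(f"material {self.name!r}: epsilon_r must be >= 1")

    @property
    def isotropic(self) -> bool:
        return self.sigma_axial == self.sigma_radial

    @classmethod
    def iso(cls, name: str, sigma: float, epsilon_r: float = 1.0) -> "MaterialSpec":
        """Convenience constructor for isotropic materials."""
        return cls(name, sigma, sigma, epsilon_r)


def default_materials() -> dict[str, MaterialSpec]:
    """Shipped standard materials (see :mod:`festwin.fixtures`)."""
    from . import fixtures

    return fixtures.load_materials()
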