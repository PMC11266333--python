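"""511-keV material constants for the photon transport model.

The table ships as ``data/materials.yaml`` with provenance notes; values
are linear attenuation coefficients at 511 keV (mm^-1, coherent
scattering excluded) and the fraction of interactions treated as Compton
scattering.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import yaml

from .errors import ConfigurationError

_DATA = Path(__file__).parent / "data" / "materials.yaml"


@dataclass(frozen=True)
class Material:
    name: str
    mu_511_mm: float
    compton_fraction: float

    def __post_init__(self) -> None:
        if self.mu_511_mm < 0:
            raise ConfigurationError(f"mu_511_mm must be >= 0 for {self.name}")
        if not 0.0 <= self.compton_fraction <= 1.0:
            raise ConfigurationError(f"compton_fraction must be in [0, 1] for {self.name}")


@lru_cache(maxsize=1)
def material_table() -> dict[str, Material]:
    raw = yaml.safe_load(_DATA.read_text())
    return {
        name: Material(name=name, mu_511_mm=float(v["mu_511_mm"]),
                       compton_fraction=float(v["compton_fraction"]))
        for name, v in raw.items()
    }


def get_material(name: str) -> Material:
    table = material_table()
    try:
        return table[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown material {name!r}; known: {sorted(table)}"
        ) from None
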