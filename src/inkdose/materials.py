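"""Mixture rules and transport-ready materials.

Two rules define every mixture in the study. Densities mix by volume
fraction,

    rho_mix = v_ink * rho_ink + (1 - v_ink) * rho_dermis,

and the mass fraction of component *i* in the mixture follows from the
volume fractions and component densities,

    w_i = v_i * rho_i / sum_j(v_j * rho_j).

Tattoo-dermis blends at 0-100 vol% pigment loading are built from the dry
pigment material (see :mod:`inkdose.chemistry`) and the reticular dermis
at 1.1 g/cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import chemistry
from .errors import DomainError, InkdoseError
from .reference import ReferenceTables, load_reference_tables

__all__ = [
    "Material",
    "MixtureSpec",
    "mix_density",
    "mixture_mass_fractions",
    "blend_materials",
    "skin_material",
    "ink_material",
    "tattoo_mixture",
    "water",
    "table1_densities",
]

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class Material:
    """A named medium: mass density plus normalized elemental fractions."""

    name: str
    density: float  # g/cm^3
    elemental_fractions: Mapping[str, float]

    def __post_init__(self):
        if self.density <= 0:
            raise DomainError(f"material {self.name}: density must be > 0")
        fr = self.elemental_fractions
        if any(v < 0 for v in fr.values()):
            raise DomainError(f"material {self.name}: negative mass fraction")
        s = sum(fr.values())
        if abs(s - 1.0) > _FRACTION_TOL:
            raise DomainError(
                f"material {self.name}: fractions sum to {s}, not 1"
            )

    # -- plain-text material card (common MC material-definition style) --
    def to_card(self) -> str:
        lines = [f"material {self.name}", f"density {float(self.density)!r}"]
        lines += [
            f"{el} {float(frac)!r}"
            for el, frac in sorted(self.elemental_fractions.items())
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_card(cls, text: str) -> "Material":
        name = None
        density = None
        fractions = {}
        for line in text.strip().splitlines():
            key, val = line.split(None, 1)
            if key == "material":
                name = val.strip()
            elif key == "density":
                density = float(val)
            else:
                fractions[key] = float(val)
        if name is None or density is None:
            raise InkdoseError("malformed material card")
        return cls(name=name, density=density, elemental_fractions=fractions)


@dataclass(frozen=True)
class MixtureSpec:
    """Components with volume fractions; the unit fed to blend_materials."""

    components: Sequence  # (Material, volume fraction) pairs
    loading: str = ""

    def __post_init__(self):
        vols = [v for _, v in self.components]
        if any(v < 0 for v in vols):
            raise DomainError("volume fractions must be >= 0")
        if abs(sum(vols) - 1.0) > 1e-12:
            raise DomainError(f"volume fractions sum to {sum(vols)}, not 1")


def mix_density(v_ink: float, rho_ink: float, rho_dermis: float) -> float:
    """Volume-weighted density of an ink-dermis blend (g/cm^3)."""
    if not (0 <= v_ink <= 1):
        raise DomainError(f"ink volume fraction {v_ink} outside [0, 1]")
    if rho_ink <= 0 or rho_dermis <= 0:
        raise DomainError("component densities must be > 0")
    return v_ink * rho_ink + (1 - v_ink) * rho_dermis


def mixture_mass_fractions(volumes, densities) -> np.ndarray:
    """Mass fractions w_i = v_i rho_i / sum_j v_j rho_j."""
    v = np.asarray(volumes, dtype=float)
    rho = np.asarray(densities, dtype=float)
    if abs(v.sum() - 1.0) > 1e-12:
        raise DomainError("volume fractions must sum to 1")
    if np.any(rho <= 0):
        raise DomainError("densities must be > 0")
    mass = v * rho
    total = mass.sum()
    if total <= 0:
        raise DomainError("degenerate mixture: zero total mass")
    return mass / total


def blend_materials(spec: MixtureSpec, name: str | None = None) -> Material:
    """Blend component materials into one transport-ready Material.

    Density follows the volume rule; elemental fractions are the
    mass-fraction-weighted sum of the component vectors.
    """
    mats = [m for m, _ in spec.components]
    vols = [v for _, v in spec.components]
    rhos = [m.density for m in mats]
    w = mixture_mass_fractions(vols, rhos)
    density = float(np.dot(vols, rhos))
    fractions: dict[str, float] = {}
    for wi, m in zip(w, mats):
        for el, f in m.elemental_fractions.items():
            fractions[el] = fractions.get(el, 0.0) + wi * f
    # components are individually normalized, so the sum is 1 up to rounding
    total = sum(fractions.values())
    fractions = {el: f / total for el, f in fractions.items()}
    label = name or "+".join(
        f"{m.name}@{v:g}" for m, v in spec.components if v > 0
    )
    return Material(name=label, density=density, elemental_fractions=fractions)


def skin_material(
    layer_name: str, tables: ReferenceTables | None = None
) -> Material:
    """Material for a named skin layer: printed density, shared composition."""
    t = tables or load_reference_tables()
    for name, _thick, dens in t.skin_layers:
        if name == layer_name:
            return Material(
                name=layer_name,
                density=dens,
                elemental_fractions=dict(t.skin_elemental_fractions),
            )
    raise KeyError(f"unknown skin layer {layer_name!r}")


def ink_material(
    color: str, tables: ReferenceTables | None = None
) -> Material:
    """Dry-pigment material for one packaged ink (100 vol% loading)."""
    ink = chemistry.packaged_ink(color, tables)
    fractions, density = chemistry.dry_mass_fractions(ink)
    return Material(
        name=f"{color}_pigment", density=density, elemental_fractions=fractions
    )


def water() -> Material:
    from .elements import WATER_FRACTIONS

    return Material(name="water", density=1.0, elemental_fractions=dict(WATER_FRACTIONS))


def tattoo_mixture(
    color: str,
    loading_vol_percent: float,
    tables: ReferenceTables | None = None,
) -> Material:
    """Tattoo-sublayer material at the given pigment loading (vol%)."""
    t = tables or load_reference_tables()
    v = loading_vol_percent / 100.0
    if not (0 <= v <= 1):
        raise DomainError("loading must be within 0-100 vol%")
    dermis = skin_material("reticular_dermis", t)
    if v == 0:
        return dermis
    pigment = ink_material(color, t)
    spec = MixtureSpec(
        components=[(pigment, v), (dermis, 1 - v)],
        loading=f"{loading_vol_percent:g} vol%",
    )
    return blend_materials(spec, name=f"{color}@{loading_vol_percent:g}vol%")


def table1_densities(tables: ReferenceTables | None = None) -> pd.DataFrame:
    """Mixture densities for all inks x loadings, full precision and rounded.

    The ``rounded`` column applies Python's builtin round-to-one-decimal
    (correct nearest-even on the computed double), which reproduces the
    printed mixture-density table cell for cell.
    """
    t = tables or load_reference_tables()
    rho_dermis = float(t.constants["reticular_dermis_density"])
    loadings = list(t.constants["loadings_vol_percent"])
    rows = []
    for color in t.ink_compositions:
        rho_ink = t.compound_densities[t.ink_compounds[color]]
        for pct in loadings:
            rho = mix_density(pct / 100.0, rho_ink, rho_dermis)
            rows.append(
                {
                    "color": color,
                    "loading_vol_percent": pct,
                    "density_g_cm3": rho,
                    "rounded": round(rho, 1),
                }
            )
    return pd.DataFrame(rows)
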