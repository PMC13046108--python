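"""Packaged reference tables and synthetic-input generators.

Everything the rest of the package consumes as a constant lives here: the
three commercial ink elemental compositions (wet basis, ppm), the EU REACH
concentration limits, the layered-skin anatomy (sublayer thicknesses and
densities), the shared skin elemental composition, pigment compound
densities, and the dry-matter fraction. The tables ship as plain CSV/YAML
under ``inkdose/data`` and are validated on load.

Two synthetic generators support property tests without any external data:
random ink compositions (:func:`make_random_ink`) and tiny deterministic
dose grids with analytically known profiles (:func:`make_toy_dose_grid`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, IntegrityError

__all__ = [
    "ReferenceTables",
    "load_reference_tables",
    "make_random_ink",
    "make_toy_dose_grid",
]


def _data_path(name: str):
    return resources.files("inkdose") / "data" / name


def _read_csv(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p, comment="#")


@dataclass(frozen=True)
class ReferenceTables:
    """Validated bundle of every packaged in-study constant.

    Supports mapping-style access (``tables["reach_limits"]["Pb"]``) in
    addition to attribute access.
    """

    ink_compositions: Mapping[str, Mapping[str, float]]
    below_loq: Mapping[str, frozenset]
    reach_limits: Mapping[str, float]
    skin_layers: tuple  # ordered (name, thickness_um, density_g_cm3)
    skin_elemental_fractions: Mapping[str, float]  # normalized to 1
    skin_elemental_fractions_raw: Mapping[str, float]  # as printed (~0.999)
    dry_matter_fraction: float
    dry_matter_range: tuple
    compound_densities: Mapping[str, float]
    ink_compounds: Mapping[str, str]  # color -> compound
    constants: Mapping[str, object] = field(default_factory=dict)

    def __getitem__(self, key):
        if key not in {f.name for f in dataclasses.fields(self)}:
            raise KeyError(key)
        return getattr(self, key)

    # -- serialization round trip -------------------------------------
    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, frozenset):
                return sorted(v)
            if isinstance(v, tuple):
                return [conv(x) for x in v]
            if isinstance(v, Mapping):
                return {k: conv(x) for k, x in v.items()}
            return v

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceTables":
        def tup(rows):
            return tuple(tuple(r) if isinstance(r, list) else r for r in rows)

        return cls(
            ink_compositions={c: dict(v) for c, v in d["ink_compositions"].items()},
            below_loq={c: frozenset(v) for c, v in d["below_loq"].items()},
            reach_limits=dict(d["reach_limits"]),
            skin_layers=tup(d["skin_layers"]),
            skin_elemental_fractions=dict(d["skin_elemental_fractions"]),
            skin_elemental_fractions_raw=dict(d["skin_elemental_fractions_raw"]),
            dry_matter_fraction=d["dry_matter_fraction"],
            dry_matter_range=tuple(d["dry_matter_range"]),
            compound_densities=dict(d["compound_densities"]),
            ink_compounds=dict(d["ink_compounds"]),
            constants=dict(d["constants"]),
        )


_EPIDERMAL = (
    "upper_SC",
    "middle_SC",
    "lower_SC",
    "stratum_granulosum",
    "stratum_spinosum",
    "stratum_basale",
)


def _validate(t: ReferenceTables) -> None:
    epi = [th for (n, th, _d) in t.skin_layers if n in _EPIDERMAL]
    if abs(sum(epi) - 100.1) > 1e-9:
        raise IntegrityError(
            f"epidermal sublayer thicknesses sum to {sum(epi)} um, expected 100.1"
        )
    s = sum(t.skin_elemental_fractions.values())
    if abs(s - 1.0) > 1e-12:
        raise IntegrityError(f"normalized skin elemental fractions sum to {s}, not 1")
    raw = sum(t.skin_elemental_fractions_raw.values())
    if not (0.99 < raw < 1.01):
        raise IntegrityError(f"raw skin elemental fractions sum to {raw}")
    for el in t.reach_limits:
        if not any(el in comp for comp in t.ink_compositions.values()):
            raise IntegrityError(f"REACH-limited element {el} absent from every ink")
    expected = {"Al", "V", "Cr", "Fe", "Co", "Ni", "Cu", "Cd", "Ba", "Hg", "Pb"}
    for color, comp in t.ink_compositions.items():
        missing = expected - set(comp)
        if missing:
            raise IntegrityError(f"ink {color} missing elements {sorted(missing)}")
    for color in t.ink_compositions:
        if color not in t.ink_compounds:
            raise IntegrityError(f"ink {color} has no dominant compound assigned")
        if t.ink_compounds[color] not in t.compound_densities:
            raise IntegrityError(f"compound for {color} has no packaged density")
    if not (0 < t.dry_matter_fraction <= 1):
        raise IntegrityError("dry matter fraction outside (0, 1]")


def load_reference_tables() -> ReferenceTables:
    """Load and validate the complete packaged constant set.

    Raises :class:`IntegrityError` naming the failing invariant if the
    packaged data is corrupted.
    """
    inks = _read_csv("ink_compositions.csv")
    comps: dict[str, dict[str, float]] = {}
    loq: dict[str, set] = {}
    for color, g in inks.groupby("color", sort=False):
        comps[color] = dict(zip(g["element"], g["wet_ppm"].astype(float)))
        loq[color] = frozenset(g.loc[g["below_loq"] == 1, "element"])

    limits = dict(
        zip(
            (df := _read_csv("reach_limits.csv"))["element"],
            df["limit_ppm"].astype(float),
        )
    )
    layers_df = _read_csv("skin_layers.csv")
    layers = tuple(
        (r["name"], float(r["thickness_um"]), float(r["density_g_cm3"]))
        for _, r in layers_df.iterrows()
    )
    skin_df = _read_csv("skin_elemental.csv")
    raw = dict(zip(skin_df["element"], skin_df["mass_fraction"].astype(float)))
    tot = sum(raw.values())
    norm = {k: v / tot for k, v in raw.items()}
    # guard against accumulated floating error in the normalization itself
    norm[max(norm, key=norm.get)] += 1.0 - sum(norm.values())

    cmpd_df = _read_csv("ink_compounds.csv")
    compounds = dict(zip(cmpd_df["compound"], cmpd_df["density_g_cm3"].astype(float)))
    ink_compounds = dict(zip(cmpd_df["color"], cmpd_df["compound"]))

    with resources.as_file(_data_path("constants.yaml")) as p:
        consts = yaml.safe_load(p.read_text())

    tables = ReferenceTables(
        ink_compositions=comps,
        below_loq=loq,
        reach_limits=limits,
        skin_layers=layers,
        skin_elemental_fractions=norm,
        skin_elemental_fractions_raw=raw,
        dry_matter_fraction=float(consts["dry_matter_fraction"]),
        dry_matter_range=tuple(consts["dry_matter_range"]),
        compound_densities=compounds,
        ink_compounds=ink_compounds,
        constants=consts,
    )
    _validate(tables)
    return tables


def make_random_ink(seed: int, n_elements: int):
    """Generate a random but valid ink composition for property tests.

    Trace elements are drawn log-uniformly over 0.01-10^4 ppm (wet basis)
    from the Table-style element set, the dry-matter fraction uniformly
    over the surveyed 0.31-0.62 range, and the dominant compound from the
    packaged compound list. Deterministic for a fixed seed.
    """
    from .chemistry import InkComposition

    if n_elements < 1:
        raise DomainError("n_elements must be >= 1")
    tables = load_reference_tables()
    rng = np.random.default_rng(seed)
    pool = sorted(tables.ink_compositions["brown"])
    chosen = rng.choice(pool, size=min(n_elements, len(pool)), replace=False)
    ppm = {el: float(10 ** rng.uniform(-2, 4)) for el in sorted(chosen)}
    f_dry = float(rng.uniform(*tables.dry_matter_range))
    color = str(rng.choice(sorted(tables.ink_compounds)))
    compound = tables.ink_compounds[color]
    return InkComposition(
        color=f"random-{seed}",
        wet_ppm=ppm,
        dry_matter_fraction=f_dry,
        dominant_compound=compound,
        bulk_density=tables.compound_densities[compound],
        below_loq=frozenset(),
    )


def make_toy_dose_grid(shape, pattern: str, value: float = 1.0):
    """Build a tiny deterministic dose grid with an analytically known profile.

    Patterns: ``uniform`` (constant ``value``), ``ramp`` (dose equal to the
    1-based z-bin index times ``value``), ``quadrant`` (constant ``value``
    with the x<center, y<center quadrant doubled). Uncertainty is zero.
    """
    from .transport import DoseGrid

    nx, ny, nz = (int(s) for s in shape)
    if min(nx, ny, nz) < 1:
        raise DomainError("toy grid shape entries must be >= 1")
    dose = np.full((nx, ny, nz), float(value))
    if pattern == "uniform":
        pass
    elif pattern == "ramp":
        dose *= np.arange(1, nz + 1)[None, None, :]
    elif pattern == "quadrant":
        dose[: max(nx // 2, 1), : max(ny // 2, 1), :] *= 2.0
    else:
        raise DomainError(f"unknown toy pattern {pattern!r}")
    # 2 mm lateral bins centred on the beam axis, 0.1 mm depth bins from 0
    x_edges = 2.0 * (np.arange(nx + 1) - nx / 2)
    y_edges = 2.0 * (np.arange(ny + 1) - ny / 2)
    z_edges = 0.1 * np.arange(nz + 1)
    return DoseGrid(
        dose=dose,
        rel_uncertainty=np.zeros_like(dose),
        x_edges=x_edges,
        y_edges=y_edges,
        z_edges=z_edges,
        n_histories=0,
        seed=0,
        dose_medium=dose.copy(),
    )
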