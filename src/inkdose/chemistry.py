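"""Ink chemistry: wet/dry conversion, pigment closure, REACH compliance.

Commercial ink assays report elemental content per kilogram of *wet* ink
(solvent included). The pigment retained in the dermis is the dry solid
fraction, so transport materials are built on a dry basis: every wet
concentration is divided by the dry-matter fraction (0.47 by default).

The dry pigment is closed to unit mass around the dominant compound
(Fe2O3 for brown, Al(OH)3 for orange, carbon black for black): trace
metals stay elemental at their dry-basis concentration and the remaining
mass is the compound itself, split stoichiometrically — the reading
under which the brown pigment really is Fe2O3-dominant, matching the
compound-density assignment. An alternative "binder" closure (compound
amount fixed by the assayed metal, residue modeled as carbon) is kept
selectable; the choice is flagged in run provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import pandas as pd

from .elements import ELEMENTS, MOLAR_MASS
from .errors import CompositionError, DomainError
from .reference import ReferenceTables, load_reference_tables

__all__ = [
    "InkComposition",
    "ComplianceReport",
    "Verdict",
    "wet_to_dry",
    "reach_compliance",
    "dry_mass_fractions",
    "packaged_ink",
    "ink_to_csv",
    "ink_from_csv",
]


@dataclass(frozen=True)
class InkComposition:
    """One commercial ink: wet-basis elemental ppm plus pigment identity."""

    color: str
    wet_ppm: Mapping[str, float]  # element -> mg per kg wet ink
    dry_matter_fraction: float
    dominant_compound: str  # Fe2O3 | Al(OH)3 | carbon-black
    bulk_density: float  # g/cm^3, the dominant compound's density
    below_loq: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if any(v < 0 for v in self.wet_ppm.values()):
            raise DomainError(f"ink {self.color}: negative ppm entry")
        if not (0 < self.dry_matter_fraction <= 1):
            raise DomainError(
                f"ink {self.color}: dry-matter fraction "
                f"{self.dry_matter_fraction} outside (0, 1]"
            )
        if self.bulk_density <= 0:
            raise DomainError(f"ink {self.color}: nonpositive bulk density")


class Verdict(str, Enum):
    EXCEEDS = "exceeds"
    WITHIN = "within"
    NOT_APPLICABLE = "not_applicable"
    BELOW_LOQ = "below_loq"


@dataclass(frozen=True)
class ComplianceReport:
    """Per-element regulatory verdicts for one ink (wet-basis comparison)."""

    color: str
    verdicts: Mapping[str, Verdict]
    limits: Mapping[str, float]  # only elements with a limit
    measured: Mapping[str, float]  # wet ppm

    def exceeding(self) -> list:
        return sorted(e for e, v in self.verdicts.items() if v is Verdict.EXCEEDS)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "element": e,
                "measured_wet_ppm": self.measured[e],
                "limit_ppm": self.limits.get(e),
                "verdict": v.value,
            }
            for e, v in self.verdicts.items()
        ]
        return pd.DataFrame(rows)


def wet_to_dry(c_wet: float, f_dry: float) -> float:
    """Convert a wet-basis concentration (ppm) to a dry basis.

    The solid pigment carries all of the assayed metal, so the dry-basis
    concentration is ``c_wet / f_dry``.
    """
    if c_wet < 0:
        raise DomainError("wet concentration must be >= 0")
    if not (0 < f_dry <= 1):
        raise DomainError(f"dry-matter fraction {f_dry} outside (0, 1]")
    return c_wet / f_dry


def reach_compliance(
    ink: InkComposition, limits: Mapping[str, float] | None = None
) -> ComplianceReport:
    """Evaluate EU REACH concentration limits for one ink.

    Comparisons use wet-basis ppm, matching how the assayed values are
    reported against the limits. Elements without a packaged limit are
    ``not_applicable``; entries below the limit of quantification get a
    ``below_loq`` verdict.
    """
    if limits is None:
        limits = load_reference_tables().reach_limits
    verdicts = {}
    for el, c in ink.wet_ppm.items():
        if el in ink.below_loq:
            verdicts[el] = Verdict.BELOW_LOQ
        elif el not in limits:
            verdicts[el] = Verdict.NOT_APPLICABLE
        elif c > limits[el]:
            verdicts[el] = Verdict.EXCEEDS
        else:
            verdicts[el] = Verdict.WITHIN
    return ComplianceReport(
        color=ink.color,
        verdicts=verdicts,
        limits={e: limits[e] for e in ink.wet_ppm if e in limits},
        measured=dict(ink.wet_ppm),
    )


# stoichiometric companions bound to the compound-forming metal,
# expressed as mass per unit mass of that metal
def _bound_companions(compound: str) -> tuple[str, dict]:
    if compound == "Fe2O3":
        m = MOLAR_MASS["Fe2O3"]
        fe = 2 * ELEMENTS["Fe"].A
        return "Fe", {"O": (m - fe) / fe}
    if compound == "Al(OH)3":
        al = ELEMENTS["Al"].A
        return "Al", {
            "O": 3 * ELEMENTS["O"].A / al,
            "H": 3 * ELEMENTS["H"].A / al,
        }
    if compound == "carbon-black":
        return "C", {}
    raise DomainError(f"unknown dominant compound {compound!r}")


def dry_mass_fractions(
    ink: InkComposition, closure: str = "compound"
) -> tuple[dict, float]:
    """Close the dry pigment to a normalized elemental mass-fraction vector.

    Returns ``(fractions, density)`` ready for building a transport
    material; the density is the ink's packaged bulk density. Two
    closures are available for the unassayed mass balance:

    * ``"compound"`` (default): the dry mass not accounted for by trace
      metals is the dominant compound itself, split into its elements
      stoichiometrically. This is the reading consistent with the
      pigment being compound-dominant (and with assigning the compound's
      bulk density to the ink): brown becomes essentially Fe2O3 with
      trace metals, orange Al(OH)3, black carbon.
    * ``"binder"``: the dominant compound's amount is derived from its
      metal's dry-basis assay via stoichiometry, and the residual mass
      is a generic organic binder modeled as carbon.
    """
    if closure not in ("compound", "binder"):
        raise DomainError(f"unknown closure {closure!r}")
    f = ink.dry_matter_fraction
    fractions: dict[str, float] = {}
    for el, c_wet in ink.wet_ppm.items():
        if c_wet <= 0:
            continue
        if el not in ELEMENTS:
            raise CompositionError(f"no elemental data for {el}")
        fractions[el] = fractions.get(el, 0.0) + wet_to_dry(c_wet, f) * 1e-6

    metal, companions = _bound_companions(ink.dominant_compound)
    if closure == "binder":
        for el, ratio in companions.items():
            fractions[el] = (
                fractions.get(el, 0.0) + fractions.get(metal, 0.0) * ratio
            )
        residual = 1.0 - sum(fractions.values())
        if residual < 0:
            raise CompositionError(
                f"ink {ink.color}: trace metals plus compound stoichiometry "
                f"exceed unit mass by {-residual:.3g}"
            )
        fractions["C"] = fractions.get("C", 0.0) + residual
        # exact unit sum (binder absorbs rounding)
        fractions["C"] += 1.0 - sum(fractions.values())
        return fractions, ink.bulk_density

    # compound closure: the assayed dominant metal is subsumed by the
    # compound; every other element stays at its dry-basis concentration
    fractions.pop(metal, None)
    compound_mass = 1.0 - sum(fractions.values())
    if compound_mass < 0:
        raise CompositionError(
            f"ink {ink.color}: trace metals alone exceed unit mass by "
            f"{-compound_mass:.3g}"
        )
    total_ratio = 1.0 + sum(companions.values())  # compound mass per metal mass
    metal_mass = compound_mass / total_ratio
    fractions[metal] = fractions.get(metal, 0.0) + metal_mass
    for el, ratio in companions.items():
        fractions[el] = fractions.get(el, 0.0) + metal_mass * ratio
    fractions[metal] += 1.0 - sum(fractions.values())
    return fractions, ink.bulk_density


def ink_to_csv(ink: InkComposition, path) -> None:
    """Write an ink definition as CSV (element rows + a header comment)."""
    from pathlib import Path

    header = (
        f"# color={ink.color} dry_matter_fraction={ink.dry_matter_fraction!r}"
        f" compound={ink.dominant_compound} density={ink.bulk_density!r}"
        + (f" below_loq={','.join(sorted(ink.below_loq))}" if ink.below_loq else "")
    )
    rows = ["element,wet_ppm"] + [
        f"{el},{ppm!r}" for el, ppm in sorted(ink.wet_ppm.items())
    ]
    Path(path).write_text("\n".join([header] + rows) + "\n")


def ink_from_csv(path) -> InkComposition:
    """Read an ink definition written by :func:`ink_to_csv` (or by hand)."""
    from pathlib import Path

    lines = Path(path).read_text().strip().splitlines()
    meta = {}
    for line in lines:
        if line.startswith("#"):
            for tok in line.lstrip("# ").split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
    ppm = {}
    for line in lines:
        if line.startswith("#") or line.startswith("element"):
            continue
        el, val = line.split(",")
        ppm[el.strip()] = float(val)
    return InkComposition(
        color=meta.get("color", "user"),
        wet_ppm=ppm,
        dry_matter_fraction=float(meta.get("dry_matter_fraction", 0.47)),
        dominant_compound=meta.get("compound", "carbon-black"),
        bulk_density=float(meta.get("density", 1.8)),
        below_loq=frozenset(
            x for x in meta.get("below_loq", "").split(",") if x
        ),
    )


def packaged_ink(
    color: str, tables: ReferenceTables | None = None
) -> InkComposition:
    """Construct one of the three packaged commercial inks by color."""
    t = tables or load_reference_tables()
    if color not in t.ink_compositions:
        raise DomainError(f"unknown packaged ink {color!r}")
    compound = t.ink_compounds[color]
    return InkComposition(
        color=color,
        wet_ppm=dict(t.ink_compositions[color]),
        dry_matter_fraction=t.dry_matter_fraction,
        dominant_compound=compound,
        bulk_density=t.compound_densities[compound],
        below_loq=t.below_loq[color],
    )
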