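"""Interaction physics for the simplified megavoltage transport engine.

Photon interactions are modeled with three channels:

* incoherent (Compton) scattering — exact Klein–Nishina total cross
  section per electron times the medium's electron density;
* photoelectric absorption — a fitted Z^4.5/E^3 power law anchored to the
  packaged water reference value at 0.1 MeV (negligible above ~1 MeV but
  kept for low-energy scattered photons);
* pair production — zero below the 1.022 MeV threshold, above it a
  Bethe–Heitler-style Z(Z+1)/A scaling whose energy shape is anchored to
  the packaged water attenuation reference.

Coherent (Rayleigh) scattering is deliberately omitted: it transfers no
energy and contributes <4% to attenuation at the energies of interest.

Electron transport uses Berger–Seltzer (Møller) collision stopping power
with Bragg-additivity mean excitation energies and an asymptotic
density-effect correction, an approximate radiative loss term, and
Highland/Rossi multiple-scattering theory via mixture radiation lengths.
All mixture coefficients are mass-fraction (Bragg) additive over elements.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .elements import ELEMENTS
from .errors import DomainError
from .materials import Material

__all__ = [
    "CrossSectionSet",
    "build_cross_sections",
    "kn_total_cross_section",
    "mass_attenuation",
    "collision_stopping_power",
    "restricted_stopping_power",
    "radiative_stopping_power",
    "csda_range",
    "radiation_length",
    "scattering_theta0",
    "water_reference",
]

MEC2 = 0.51099895  # electron rest energy, MeV
R_E = 2.8179403262e-13  # classical electron radius, cm
N_A = 6.02214076e23
ENERGY_MIN, ENERGY_MAX = 0.01, 30.0  # model validity, MeV
PAIR_THRESHOLD = 2 * MEC2  # 1.022 MeV


def _check_energy(energy):
    e = np.asarray(energy, dtype=float)
    if np.any(e < ENERGY_MIN) or np.any(e > ENERGY_MAX):
        raise DomainError(
            f"energy outside model validity [{ENERGY_MIN}, {ENERGY_MAX}] MeV"
        )
    return e


def water_reference() -> dict:
    """Packaged water attenuation / CSDA reference tables (oracle data)."""
    import pandas as pd

    out = {}
    for key, fname in [
        ("attenuation", "water_attenuation_reference.csv"),
        ("csda", "water_csda_reference.csv"),
    ]:
        with resources.as_file(resources.files("inkdose") / "data" / fname) as p:
            out[key] = pd.read_csv(p, comment="#")
    return out


# ---------------------------------------------------------------------------
# per-element / per-material mixture sums
# ---------------------------------------------------------------------------

def _frac_items(material: Material):
    return [
        (ELEMENTS[el], w)
        for el, w in material.elemental_fractions.items()
        if w > 0
    ]


def electrons_per_gram(material: Material) -> float:
    return N_A * sum(w * e.Z / e.A for e, w in _frac_items(material))


def _z_over_a(material: Material) -> float:
    return sum(w * e.Z / e.A for e, w in _frac_items(material))


def _zz1_over_a(material: Material) -> float:
    return sum(w * e.Z * (e.Z + 1) / e.A for e, w in _frac_items(material))


def _z45_over_a(material: Material) -> float:
    return sum(w * e.Z**4.5 / e.A for e, w in _frac_items(material))


def _z2_over_a(material: Material) -> float:
    return sum(w * e.Z**2 / e.A for e, w in _frac_items(material))


def mean_excitation_energy(material: Material) -> float:
    """Bragg-additivity I value (eV): ln I = sum(w Z/A ln I_i) / sum(w Z/A)."""
    num = sum(w * e.Z / e.A * np.log(e.I_eV) for e, w in _frac_items(material))
    return float(np.exp(num / _z_over_a(material)))


def _water() -> Material:
    from .materials import water

    return water()


# ---------------------------------------------------------------------------
# photon cross sections
# ---------------------------------------------------------------------------

def kn_total_cross_section(energy_mev):
    """Klein–Nishina total cross section per free electron (cm^2)."""
    k = np.asarray(energy_mev, dtype=float) / MEC2
    t1 = (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log(1 + 2 * k) / k)
    t2 = np.log(1 + 2 * k) / (2 * k)
    t3 = -(1 + 3 * k) / (1 + 2 * k) ** 2
    return 2 * np.pi * R_E**2 * (t1 + t2 + t3)


def mu_compton(material: Material, energy_mev) -> np.ndarray:
    """Incoherent mass attenuation coefficient (cm^2/g)."""
    e = _check_energy(energy_mev)
    return electrons_per_gram(material) * kn_total_cross_section(e)


_PE_ANCHOR_E = 0.1  # MeV


def _pe_constant() -> float:
    ref = water_reference()["attenuation"]
    row = ref.loc[np.isclose(ref["energy_mev"], _PE_ANCHOR_E)].iloc[0]
    return float(row["photoelectric"]) * _PE_ANCHOR_E**3 / _z45_over_a(_water())


_PE_C = None


def mu_photoelectric(material: Material, energy_mev) -> np.ndarray:
    """Photoelectric mass attenuation via the anchored Z^4.5/E^3 law."""
    global _PE_C
    if _PE_C is None:
        _PE_C = _pe_constant()
    e = _check_energy(energy_mev)
    return _PE_C * _z45_over_a(material) / e**3


_PAIR_SHAPE = None  # (energies, g-values) for water-anchored pair shape


def _pair_shape() -> tuple:
    """Water-anchored pair energy shape g(E): pair mu/rho per unit Z(Z+1)/A."""
    global _PAIR_SHAPE
    if _PAIR_SHAPE is None:
        w = _water()
        ref = water_reference()["attenuation"]
        mask = ref["energy_mev"] > PAIR_THRESHOLD
        e = ref.loc[mask, "energy_mev"].to_numpy()
        total = ref.loc[mask, "total"].to_numpy()
        kn = mu_compton(w, e)
        pe = mu_photoelectric(w, e)
        pair_w = np.clip(total - kn - pe, 0.0, None)
        e = np.concatenate([[PAIR_THRESHOLD], e])
        g = np.concatenate([[0.0], pair_w / _zz1_over_a(w)])
        _PAIR_SHAPE = (e, g)
    return _PAIR_SHAPE


def mu_pair(material: Material, energy_mev) -> np.ndarray:
    """Pair-production mass attenuation (cm^2/g); 0 below 1.022 MeV."""
    e = _check_energy(energy_mev)
    eg, g = _pair_shape()
    # linear interpolation; log-linear extrapolation above the last anchor
    gv = np.interp(e, eg, g)
    hi = e > eg[-1]
    if np.any(hi):
        slope = (g[-1] - g[-2]) / np.log(eg[-1] / eg[-2])
        gv = np.where(hi, g[-1] + slope * np.log(e / eg[-1]), gv)
    gv = np.where(e <= PAIR_THRESHOLD, 0.0, gv)
    return gv * _zz1_over_a(material)


def mass_attenuation(material: Material, energy_mev, component: str = "total"):
    """Mass attenuation coefficient (cm^2/g) for one channel or the total."""
    funcs = {
        "photoelectric": mu_photoelectric,
        "compton": mu_compton,
        "pair": mu_pair,
    }
    if component == "total":
        return sum(f(material, energy_mev) for f in funcs.values())
    try:
        return funcs[component](material, energy_mev)
    except KeyError:
        raise DomainError(f"unknown attenuation component {component!r}") from None


# ---------------------------------------------------------------------------
# electron stopping powers, ranges, scattering
# ---------------------------------------------------------------------------

_K_COL = 0.1535374  # 2 pi r_e^2 mc^2 N_A, MeV cm^2/mol


def _density_effect(material: Material, tau: float) -> float:
    """Asymptotic Sternheimer density-effect correction (clipped at 0)."""
    gamma = tau + 1.0
    beta2 = 1.0 - 1.0 / gamma**2
    if beta2 <= 0:
        return 0.0
    hw_p = 28.8159e-6 * np.sqrt(material.density * _z_over_a(material))  # MeV
    i_mev = mean_excitation_energy(material) * 1e-6
    delta = 2 * np.log(hw_p / i_mev) + np.log(beta2 * gamma**2) - 1.0
    return max(delta, 0.0)


def restricted_stopping_power(
    material: Material, energy_mev, delta_mev: float | None = None
) -> np.ndarray:
    """Restricted (or unrestricted) collision stopping power, MeV cm^2/g.

    ``delta_mev`` is the knock-on production threshold; ``None`` (or any
    value >= T/2) gives the unrestricted Møller stopping power.
    """
    e = np.atleast_1d(np.asarray(energy_mev, dtype=float))
    out = np.empty_like(e)
    i_mev = mean_excitation_energy(material) * 1e-6
    za = _z_over_a(material)
    for i, t in enumerate(e):
        tau = t / MEC2
        gamma = tau + 1.0
        beta2 = 1.0 - 1.0 / gamma**2
        eta = 0.5 if delta_mev is None else min(delta_mev / t, 0.5)
        eta = max(eta, 1e-9)
        lead = np.log(tau**2 * (tau + 2) / 2.0) - 2 * np.log(i_mev / MEC2)
        g = (
            -1.0
            - beta2
            + np.log(4 * (1 - eta) * eta)
            + 1.0 / (1 - eta)
            + (1 - beta2)
            * (tau**2 * eta**2 / 2.0 + (2 * tau + 1) * np.log(1 - eta))
        )
        delta_corr = _density_effect(material, tau)
        out[i] = _K_COL / beta2 * za * (lead + g - delta_corr)
    out = np.clip(out, 1e-6, None)
    return out if np.ndim(energy_mev) else float(out[0])


def collision_stopping_power(material: Material, energy_mev):
    """Unrestricted Møller collision stopping power (MeV cm^2/g)."""
    return restricted_stopping_power(material, energy_mev, None)


def radiative_stopping_power(material: Material, energy_mev):
    """Approximate radiative stopping power (MeV cm^2/g).

    Uses the rule-of-thumb ratio S_rad/S_col ~ E * Zeff / 700 with
    Zeff = sum(w Z^2/A)/sum(w Z/A); adequate for the few-percent radiative
    contribution below 20 MeV.
    """
    e = np.asarray(energy_mev, dtype=float)
    zeff = _z2_over_a(material) / _z_over_a(material)
    return collision_stopping_power(material, e) * e * zeff / 700.0


def total_stopping_power(material: Material, energy_mev):
    return np.asarray(
        collision_stopping_power(material, energy_mev)
    ) + radiative_stopping_power(material, energy_mev)


def csda_range(material: Material, energy_mev: float) -> float:
    """CSDA range (g/cm^2) by quadrature of 1/S_total from 10 keV."""
    if energy_mev <= ENERGY_MIN:
        return 0.0
    e = np.geomspace(ENERGY_MIN, energy_mev, 400)
    s = np.asarray(total_stopping_power(material, e))
    return float(np.trapezoid(1.0 / s, e))


def radiation_length(material: Material) -> float:
    """Mixture radiation length X0 in g/cm^2 (Tsai-style elemental fit)."""
    inv = 0.0
    for e, w in _frac_items(material):
        x0_el = 716.408 * e.A / (e.Z * (e.Z + 1) * np.log(287.0 / np.sqrt(e.Z)))
        inv += w / x0_el
    return 1.0 / inv


def scattering_theta0(
    material: Material, energy_mev: float, step_g_cm2: float
) -> float:
    """Highland multiple-scattering angle (rad, projected RMS) for one step."""
    tau = energy_mev / MEC2
    gamma = tau + 1.0
    beta2 = 1.0 - 1.0 / gamma**2
    pbeta = energy_mev * (tau + 2) / (tau + 1)  # p*v = T(T+2mc^2)/(T+mc^2)
    x_over_x0 = step_g_cm2 / radiation_length(material)
    if x_over_x0 <= 0:
        return 0.0
    corr = 1.0 + 0.038 * np.log(max(x_over_x0, 1e-7))
    return 13.6 / pbeta * np.sqrt(x_over_x0) * max(corr, 0.25)


def stopping_power_ratio_water(
    material: Material, reference_energy_mev: float = 1.0
) -> float:
    """Water/medium unrestricted mass collision stopping-power ratio."""
    w = _water()
    return float(
        collision_stopping_power(w, reference_energy_mev)
        / collision_stopping_power(material, reference_energy_mev)
    )


# ---------------------------------------------------------------------------
# tabulated cross-section set for the transport kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossSectionSet:
    """Per-material interaction tables on a shared log energy grid.

    Mass coefficients are cm^2/g; linear coefficients (computed by the
    kernel) scale by density. ``restricted_stopping`` is evaluated at each
    material's own knock-on threshold ``delta_mev``.
    """

    materials: tuple
    energy_grid: np.ndarray  # MeV, log-spaced
    mu_photoelectric: np.ndarray  # (n_mat, n_e) cm^2/g
    mu_compton: np.ndarray
    mu_pair: np.ndarray
    restricted_stopping: np.ndarray  # MeV cm^2/g at delta_mev[i]
    radiative_stopping: np.ndarray
    delta_mev: np.ndarray  # knock-on / transport cutoff per material
    electrons_per_gram: np.ndarray
    radiation_length: np.ndarray  # g/cm^2
    spr_water: np.ndarray  # water/medium stopping ratio at 1 MeV
    density: np.ndarray  # g/cm^3
    mean_excitation_ev: np.ndarray

    @property
    def mu_total(self) -> np.ndarray:
        return self.mu_photoelectric + self.mu_compton + self.mu_pair


def build_cross_sections(
    materials,
    energy_grid=None,
    delta_mev=None,
) -> CrossSectionSet:
    """Tabulate all interaction coefficients for a list of materials.

    ``delta_mev`` may be a scalar or a per-material sequence of knock-on
    production thresholds (default 0.05 MeV).
    """
    mats = tuple(materials)
    if energy_grid is None:
        energy_grid = np.geomspace(ENERGY_MIN, 25.0, 160)
    e = _check_energy(energy_grid)
    if e[0] > ENERGY_MIN + 1e-12 or e[-1] < 20.0:
        raise DomainError("energy grid must span at least 0.01-20 MeV")
    n = len(mats)
    if delta_mev is None:
        deltas = np.full(n, 0.05)
    else:
        deltas = np.broadcast_to(np.asarray(delta_mev, dtype=float), (n,)).copy()

    shape = (n, len(e))
    pe = np.empty(shape)
    co = np.empty(shape)
    pr = np.empty(shape)
    lcol = np.empty(shape)
    lrad = np.empty(shape)
    npg = np.empty(n)
    x0 = np.empty(n)
    spr = np.empty(n)
    rho = np.empty(n)
    iev = np.empty(n)
    for i, m in enumerate(mats):
        pe[i] = mu_photoelectric(m, e)
        co[i] = mu_compton(m, e)
        pr[i] = mu_pair(m, e)
        lcol[i] = restricted_stopping_power(m, e, deltas[i])
        lrad[i] = radiative_stopping_power(m, e)
        npg[i] = electrons_per_gram(m)
        x0[i] = radiation_length(m)
        spr[i] = stopping_power_ratio_water(m)
        rho[i] = m.density
        iev[i] = mean_excitation_energy(m)
    return CrossSectionSet(
        materials=mats,
        energy_grid=e,
        mu_photoelectric=pe,
        mu_compton=co,
        mu_pair=pr,
        restricted_stopping=lcol,
        radiative_stopping=lrad,
        delta_mev=deltas,
        electrons_per_gram=npg,
        radiation_length=x0,
        spr_water=spr,
        density=rho,
        mean_excitation_ev=iev,
    )
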