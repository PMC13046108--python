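"""Beams, dose grids, and the simulation driver.

``run_simulation`` transports a megavoltage photon or electron beam
through a :class:`~inkdose.phantom.PhantomGrid` and scores dose on the
0.1 mm x 2 mm (or 2.5 mm) mesh. Scoring is dose-to-medium with a
parallel dose-to-water channel (each energy deposit weighted by the
water/medium mass collision stopping-power ratio at the depositing
electron's energy); the water channel is the default ``dose`` array,
matching standard skin-dosimetry convention. Per-voxel statistical
uncertainty comes from the batch method (10 batches).

Electron histories are terminated 10 mm below the surface and outside
the 3x3 cm lateral extent: electrons deeper than several backscatter
depths cannot re-enter the 2.4 mm scoring slab. Photons are tracked
through the full water backing so backscattered photons are retained.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernel, physics
from .errors import ConfigurationError, DomainError
from .materials import Material
from .phantom import PhantomGrid

__all__ = [
    "BeamSpec",
    "DoseGrid",
    "ElectronState",
    "run_simulation",
    "sample_photon_interaction",
    "step_electron",
    "first_interaction_depths",
]

MEV_TO_J = 1.602176634e-13
N_BATCH = 10
ELECTRON_KILL_DEPTH_MM = 10.0
FINE_STEP_DEPTH_MM = 3.0
DELTA_CUT_MEV = 0.05  # knock-on / transport threshold outside the tattoo
DELTA_CUT_TATTOO_MEV = 0.01  # finer production threshold in the pigment layer


@dataclass(frozen=True)
class BeamSpec:
    """Clinical beam description.

    "6 MV"/"18 MV" photon beams are modeled as monoenergetic 6/18 MeV
    photons with a Gaussian energy spread (default sigma = 2% of
    nominal); electron beams likewise. The default source is a parallel
    beam collimated to the field at the surface — at SSD 100 cm the
    divergence across a 2.4 mm slab is negligible — with a
    point-divergent mode available.
    """

    particle: str  # "photon" | "electron"
    nominal_energy: float  # MeV
    energy_sigma: Optional[float] = None  # MeV; None -> 2% of nominal
    field_size: float = 1.0  # cm, square side at the surface
    ssd: float = 100.0  # cm
    source_model: str = "parallel"  # "parallel" | "point_divergent"

    def __post_init__(self):
        if self.particle not in ("photon", "electron"):
            raise ConfigurationError(f"unknown particle {self.particle!r}")
        if self.nominal_energy <= 0 or self.field_size <= 0 or self.ssd <= 0:
            raise ConfigurationError("energy, field size and SSD must be > 0")
        if self.source_model not in ("parallel", "point_divergent"):
            raise ConfigurationError(f"unknown source {self.source_model!r}")

    @property
    def sigma(self) -> float:
        return (
            self.energy_sigma
            if self.energy_sigma is not None
            else 0.02 * self.nominal_energy
        )


@dataclass
class DoseGrid:
    """Scored 3D dose (Gy per primary) with per-voxel 1-sigma uncertainty.

    ``dose`` is dose-to-water; ``dose_medium`` is dose-to-medium on the
    same mesh. ``rel_uncertainty`` is the fractional batch-method
    standard error of ``dose``.
    """

    dose: np.ndarray  # (nx, ny, nz)
    rel_uncertainty: np.ndarray
    x_edges: np.ndarray  # mm
    y_edges: np.ndarray
    z_edges: np.ndarray
    n_histories: int
    seed: int
    dose_medium: Optional[np.ndarray] = None
    emitted_energy_mev: float = 0.0
    deposited_energy_mev: float = 0.0

    def __post_init__(self):
        if np.any(self.dose < 0) or np.any(self.rel_uncertainty < 0):
            raise DomainError("dose and uncertainties must be >= 0")

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    def to_csv(self, path, extended: bool = False) -> None:
        """Export as ASCII CSV with X, Y, Z, Dose columns (mm, Gy/primary).

        ``extended=True`` adds a RelUncertainty column.
        """
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        zc = self.z_centers
        xx, yy, zz = np.meshgrid(xc, yc, zc, indexing="ij")
        df = pd.DataFrame(
            {
                "X": xx.ravel(),
                "Y": yy.ravel(),
                "Z": zz.ravel(),
                "Dose": self.dose.ravel(),
            }
        )
        if extended:
            df["RelUncertainty"] = self.rel_uncertainty.ravel()
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DoseGrid":
        """Read an X,Y,Z,Dose CSV (this package's or an external code's)."""
        df = pd.read_csv(path)

        def edges(centers):
            c = np.unique(np.asarray(centers, dtype=float))
            if len(c) == 1:
                return np.array([c[0] - 0.5, c[0] + 0.5])
            mid = 0.5 * (c[:-1] + c[1:])
            return np.concatenate(
                [[2 * c[0] - mid[0]], mid, [2 * c[-1] - mid[-1]]]
            )

        xe, ye, ze = edges(df["X"]), edges(df["Y"]), edges(df["Z"])
        nx, ny, nz = len(xe) - 1, len(ye) - 1, len(ze) - 1
        dose = np.zeros((nx, ny, nz))
        unc = np.zeros((nx, ny, nz))
        ix = np.searchsorted(xe, df["X"], side="right") - 1
        iy = np.searchsorted(ye, df["Y"], side="right") - 1
        iz = np.searchsorted(ze, df["Z"], side="right") - 1
        dose[ix, iy, iz] = df["Dose"]
        if "RelUncertainty" in df:
            unc[ix, iy, iz] = df["RelUncertainty"]
        return cls(
            dose=dose,
            rel_uncertainty=unc,
            x_edges=xe,
            y_edges=ye,
            z_edges=ze,
            n_histories=0,
            seed=0,
            dose_medium=dose.copy(),
        )


def _tables_for(phantom: PhantomGrid):
    mats = phantom.materials
    xs_out = physics.build_cross_sections(mats, delta_mev=DELTA_CUT_MEV)
    xs_tat = physics.build_cross_sections(mats, delta_mev=DELTA_CUT_TATTOO_MEV)
    rho = xs_out.density
    e = xs_out.energy_grid
    lin = rho[:, None]
    mu_pe = xs_out.mu_photoelectric * lin
    mu_c = xs_out.mu_compton * lin
    mu_pr = xs_out.mu_pair * lin
    mu_tot = mu_pe + mu_c + mu_pr
    mu_maj = mu_tot.max(axis=0)
    ld_out = xs_out.restricted_stopping * lin
    ld_tat = xs_tat.restricted_stopping * lin
    srad = xs_out.radiative_stopping * lin
    n_e_vol = xs_out.electrons_per_gram * rho
    moller_cm = (
        2.0 * np.pi * physics.R_E**2 * physics.MEC2 * n_e_vol
    )  # MeV/cm
    z2_vol = np.array(
        [physics._z2_over_a(m) * physics.N_A * m.density for m in mats]
    )  # atoms Z^2 per cm^3
    ruth_cm = 4.0 * np.pi * physics.R_E**2 * z2_vol  # cm^-1 prefactor
    # dose-to-water weights: water/medium unrestricted collision
    # stopping-power ratio at the energy of the depositing electron
    from .materials import water as _water_mat

    wmat = _water_mat()
    s_w = np.asarray(physics.collision_stopping_power(wmat, e))
    spr_e = np.empty_like(xs_out.restricted_stopping)
    ms_corr = np.empty_like(spr_e)
    theta_c = _kernel.THETA_HARD
    tau = e / physics.MEC2
    pbeta = e * (tau + 2.0) / (tau + 1.0)

    def _var_frac(x, ta):
        # angular-variance integral of screened Rutherford up to angle x
        r2 = (x / ta) ** 2
        return np.log1p(r2) - r2 / (1.0 + r2)

    for i, m in enumerate(mats):
        spr_e[i] = s_w / np.asarray(physics.collision_stopping_power(m, e))
        # residual CSDA-scale path in units of X0 for the Highland log term
        s_tot = np.asarray(physics.total_stopping_power(m, e))
        r_g = np.concatenate(
            [[0.0], np.cumsum(np.diff(e) * 0.5 * (1 / s_tot[1:] + 1 / s_tot[:-1]))]
        )
        corr = np.clip(
            1.0 + 0.038 * np.log(np.clip(r_g / xs_out.radiation_length[i], 1e-4, None)),
            0.3,
            1.1,
        )
        # Gaussian part restricted to soft collisions below the hard-event
        # split angle: scale the Highland variance by the soft fraction of
        # the screened-Rutherford angular variance so the explicit tail is
        # complementary rather than double counted
        zeff = physics._z2_over_a(m) / physics._z_over_a(m)
        theta_a = 1.13 / 137.036 * zeff ** (1.0 / 3.0) * physics.MEC2 / pbeta
        fsoft = _var_frac(theta_c, theta_a) / _var_frac(np.pi, theta_a)
        ms_corr[i] = corr * np.sqrt(np.clip(fsoft, 0.2, 1.0))
    return dict(
        loge0=float(np.log(e[0])),
        inv_dloge=float(1.0 / np.log(e[1] / e[0])),
        ne=len(e),
        mu_pe=mu_pe,
        mu_c=mu_c,
        mu_pr=mu_pr,
        mu_tot=mu_tot,
        mu_maj=mu_maj,
        ld_out=ld_out,
        ld_tat=ld_tat,
        srad=srad,
        rho=rho,
        x0_g=xs_out.radiation_length,
        spr=spr_e,
        moller_cm=moller_cm,
        ruth_cm=ruth_cm,
        ms_corr=ms_corr,
    )


def run_simulation(
    phantom: PhantomGrid,
    beam: BeamSpec,
    n_histories: int,
    seed: int,
    n_batches: int = N_BATCH,
) -> DoseGrid:
    """Run a seeded, reproducible simulation and return the scored dose.

    Identical (phantom, beam, n_histories, seed) give a bit-identical
    DoseGrid. Per-voxel uncertainty uses the batch method.
    """
    if n_histories < 1:
        raise ConfigurationError("n_histories must be >= 1")
    if beam.nominal_energy > 20.0:
        raise ConfigurationError("beam energy above 20 MeV model validity")
    if not isinstance(phantom, PhantomGrid):
        raise ConfigurationError("phantom must be a PhantomGrid")

    t = _tables_for(phantom)
    nx = len(phantom.x_edges) - 1
    ny = len(phantom.y_edges) - 1
    nz = len(phantom.z_edges) - 1
    dxy = float(phantom.x_edges[1] - phantom.x_edges[0])
    dzs = float(phantom.z_edges[1] - phantom.z_edges[0])
    edep_m = np.zeros((n_batches, nx, ny, nz))
    edep_w = np.zeros((n_batches, nx, ny, nz))
    totals = np.zeros(2)

    _kernel.simulate(
        n_histories,
        seed,
        n_batches,
        0 if beam.particle == "photon" else 1,
        beam.nominal_energy,
        beam.sigma,
        beam.field_size * 10.0 / 2.0,
        1 if beam.source_model == "point_divergent" else 0,
        beam.ssd * 10.0,
        phantom.z_bounds,
        phantom.layer_material_ids,
        phantom.tattoo_layer_index,
        phantom.quadrant_material_ids,
        phantom.lateral_extent / 2.0,
        float(phantom.tattoo_z[0]),
        float(phantom.tattoo_z[1]),
        ELECTRON_KILL_DEPTH_MM,
        FINE_STEP_DEPTH_MM,
        t["loge0"],
        t["inv_dloge"],
        t["ne"],
        t["mu_pe"],
        t["mu_c"],
        t["mu_pr"],
        t["mu_tot"],
        t["mu_maj"],
        t["ld_out"],
        t["ld_tat"],
        t["srad"],
        DELTA_CUT_MEV,
        DELTA_CUT_TATTOO_MEV,
        t["rho"],
        t["x0_g"],
        t["spr"],
        t["moller_cm"],
        t["ruth_cm"],
        t["ms_corr"],
        float(phantom.x_edges[0]),
        dxy,
        nx,
        ny,
        dzs,
        nz,
        edep_m,
        edep_w,
        totals,
    )

    mass_kg = phantom.scoring_mass_grid() * 1e-3
    scale = MEV_TO_J / (mass_kg * n_histories)
    dose_w = edep_w.sum(axis=0) * scale
    dose_m = edep_m.sum(axis=0) * scale

    batch = edep_w * (n_batches * scale[None, ...])
    mean = batch.mean(axis=0)
    std = batch.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, std / (np.sqrt(n_batches) * mean), 0.0)

    return DoseGrid(
        dose=dose_w,
        rel_uncertainty=rel,
        x_edges=phantom.x_edges.copy(),
        y_edges=phantom.y_edges.copy(),
        z_edges=phantom.z_edges.copy(),
        n_histories=n_histories,
        seed=seed,
        dose_medium=dose_m,
        emitted_energy_mev=float(totals[0]),
        deposited_energy_mev=float(totals[1]),
    )


# ---------------------------------------------------------------------------
# single-interaction / single-step reference APIs (used by physics tests)
# ---------------------------------------------------------------------------

@dataclass
class Secondary:
    particle: str
    energy: float
    direction: np.ndarray


@dataclass
class InteractionOutcome:
    kind: str  # "photoelectric" | "compton" | "pair"
    secondaries: list
    scattered_photon_energy: float = 0.0
    local_deposit: float = 0.0


def sample_photon_interaction(
    energy: float, material: Material, rng: np.random.Generator
) -> InteractionOutcome:
    """Sample one photon interaction in ``material`` at ``energy`` (MeV).

    Channel probabilities follow the partial attenuation coefficients;
    Compton kinematics conserve energy and momentum exactly.
    """
    e = float(energy)
    parts = {
        "photoelectric": float(physics.mu_photoelectric(material, e)),
        "compton": float(physics.mu_compton(material, e)),
        "pair": float(physics.mu_pair(material, e)),
    }
    total = sum(parts.values())
    r = rng.uniform(0, total)
    kind = "photoelectric"
    for k, v in parts.items():
        if r < v:
            kind = k
            break
        r -= v

    if kind == "photoelectric":
        return InteractionOutcome(
            kind,
            [Secondary("electron", e, np.array([0.0, 0.0, 1.0]))],
        )
    if kind == "compton":
        eps, ct = _compton_python(e, rng)
        t_e = e * (1 - eps)
        st = np.sqrt(max(1 - ct**2, 0.0))
        # electron polar angle from momentum conservation
        ct_e = (1 - eps * ct) / np.hypot(1 - eps * ct, eps * st)
        return InteractionOutcome(
            kind,
            [
                Secondary(
                    "electron",
                    t_e,
                    np.array([np.sqrt(max(1 - ct_e**2, 0)), 0.0, ct_e]),
                )
            ],
            scattered_photon_energy=e * eps,
        )
    avail = e - 2 * physics.MEC2
    if avail <= 0:
        raise DomainError("pair production below threshold")
    t1 = avail * rng.uniform()
    fwd = np.array([0.0, 0.0, 1.0])
    return InteractionOutcome(
        kind,
        [
            Secondary("electron", t1, fwd.copy()),
            Secondary("positron", avail - t1, fwd.copy()),
        ],
    )


def _compton_python(e: float, rng: np.random.Generator):
    k = e / physics.MEC2
    eps0 = 1.0 / (1.0 + 2.0 * k)
    a1 = np.log(1.0 / eps0)
    a2 = 0.5 * (1.0 - eps0**2)
    while True:
        u1, u2, u3 = rng.uniform(size=3)
        if u1 < a1 / (a1 + a2):
            eps = eps0 * np.exp(a1 * u2)
        else:
            eps = np.sqrt(eps0**2 + (1 - eps0**2) * u2)
        t = (1 - eps) / (k * eps)
        if u3 <= 1 - eps * t * (2 - t) / (1 + eps**2):
            return eps, 1 - t


@dataclass
class ElectronState:
    position: np.ndarray  # mm
    direction: np.ndarray  # unit vector
    energy: float  # MeV


def step_electron(
    state: ElectronState,
    material: Material,
    max_step: float,
    rng: np.random.Generator,
) -> tuple[ElectronState, float]:
    """One condensed-history step: CSDA energy loss + Gaussian deflection.

    Returns ``(new_state, deposit)``. ``max_step`` in mm; the step is
    additionally limited to a 5% fractional energy loss. A zero-length
    step returns the state unchanged with zero deposit.
    """
    if max_step <= 0:
        return state, 0.0
    e = state.energy
    s_tot = float(physics.total_stopping_power(material, e)) * material.density
    s_mm = min(max_step, 0.05 * e / s_tot * 10.0)
    s_cm = s_mm / 10.0
    de = float(physics.total_stopping_power(material, max(e - 0.5 * s_tot * s_cm, 1e-3))) \
        * material.density * s_cm
    de = min(de, e)
    theta0 = physics.scattering_theta0(material, e, s_cm * material.density)
    theta = theta0 * np.sqrt(-2.0 * np.log(max(rng.uniform(), 1e-300)))
    phi = rng.uniform(0, 2 * np.pi)
    d = state.direction / np.linalg.norm(state.direction)
    new_pos = state.position + d * s_mm
    new_dir = _rotate_py(d, np.cos(min(theta, 1.5)), phi)
    return ElectronState(new_pos, new_dir, e - de), de


def _rotate_py(d, ct, phi):
    u, v, w = d
    st = np.sqrt(max(1 - ct**2, 0.0))
    sz = np.sqrt(max(1 - w**2, 0.0))
    if sz < 1e-10:
        return np.array(
            [st * np.cos(phi), np.sign(w) * st * np.sin(phi), np.sign(w) * ct]
        )
    un = u * ct + st * (u * w * np.cos(phi) - v * np.sin(phi)) / sz
    vn = v * ct + st * (v * w * np.cos(phi) + u * np.sin(phi)) / sz
    wn = w * ct - sz * st * np.cos(phi)
    out = np.array([un, vn, wn])
    return out / np.linalg.norm(out)


def first_interaction_depths(
    material: Material, energy: float, n: int, seed: int
) -> np.ndarray:
    """Depths (cm) of first photon interactions in a homogeneous medium.

    Exercises the engine's attenuation sampling; the analytic oracle is
    the exponential law with the total attenuation coefficient.
    """
    mu = float(physics.mass_attenuation(material, energy)) * material.density
    rng = np.random.default_rng(seed)
    # Woodcock tracking in a homogeneous medium with a 1.3x majorant
    maj = 1.3 * mu
    depths = np.empty(n)
    for i in range(n):
        z = 0.0
        while True:
            z += -np.log(rng.uniform()) / maj
            if rng.uniform() < mu / maj:
                depths[i] = z
                break
    return depths
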