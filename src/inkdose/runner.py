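"""Config-driven experiment scenarios.

Composes materials, phantom, transport and analysis into the four study
scenarios: DEF-versus-depth curves per modality, depth-dose profiles per
ink, four-quadrant lateral maps, and regeneration of the mixture-density
and compliance tables. Every run writes a machine-readable provenance
record (config hash, seed, package versions).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from . import analysis, chemistry, materials, phantom, transport
from .errors import ConfigurationError
from .reference import load_reference_tables

__all__ = ["RunConfig", "ResultBundle", "run_scenario"]

SCENARIOS = ("def_curves", "depth_dose", "quadrant_maps", "tables")
ALLOWED_LOADINGS = (0, 5, 10, 25, 50, 75, 100)
# guard against accidental cluster-scale jobs on a workstation
MAX_HISTORY_VOXEL_PRODUCT = 5e13


@dataclass(frozen=True)
class RunConfig:
    scenario: str
    inks: tuple = ("brown",)
    loadings: tuple = (100,)
    beam: Optional[transport.BeamSpec] = None
    n_histories: int = 1_000_000
    seed: int = 1
    output_dir: Optional[str] = None
    custom_loading: bool = False
    quadrant_loading: float = 100.0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if not self.custom_loading and not set(self.loadings) <= set(
            ALLOWED_LOADINGS
        ):
            raise ConfigurationError(
                f"loadings {self.loadings} outside the study levels "
                f"{ALLOWED_LOADINGS}; pass custom_loading=True to override"
            )
        if self.scenario != "tables":
            if self.beam is None:
                raise ConfigurationError(f"{self.scenario} requires a beam")
            if self.n_histories * 24 * 25 > MAX_HISTORY_VOXEL_PRODUCT:
                raise ConfigurationError(
                    "projected histories x voxels exceeds the configured budget"
                )

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ResultBundle:
    config: RunConfig
    dose_grids: dict = field(default_factory=dict)
    profiles: dict = field(default_factory=dict)
    def_results: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    lateral_maps: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _provenance(config: RunConfig) -> dict:
    return {
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "inkdose_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "def_tattoo_band_mm": list(analysis.TATTOO_BAND_MM),
        "def_sub_layer_band_mm": list(analysis.SUBLAYER_BAND_MM),
        "dry_mass_closure": "compound (residual dry mass = dominant compound)",
    }


def _write_provenance(bundle: ResultBundle) -> None:
    out = bundle.config.output_dir
    if out is None:
        return
    path = Path(out)
    path.mkdir(parents=True, exist_ok=True)
    (path / "provenance.json").write_text(
        json.dumps(bundle.provenance, indent=2, default=str)
    )


def _seed_for(base: int, tag: str) -> int:
    h = hashlib.sha256(f"{base}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def run_scenario(config: RunConfig) -> ResultBundle:
    """Execute one scenario; deterministic per (config, seed)."""
    bundle = ResultBundle(config=config, provenance=_provenance(config))
    t = load_reference_tables()

    if config.scenario == "tables":
        dens = materials.table1_densities(t)
        from importlib import resources

        with resources.as_file(
            resources.files("inkdose") / "data" / "table1_printed.csv"
        ) as p:
            printed = pd.read_csv(p, comment="#")
        merged = dens.merge(printed, on=["color", "loading_vol_percent"])
        merged["match"] = np.isclose(merged["rounded"], merged["printed_density"])
        bundle.tables["mixture_densities"] = merged

        rows = []
        for color in t.ink_compositions:
            rep = chemistry.reach_compliance(chemistry.packaged_ink(color, t))
            df = rep.to_frame()
            df.insert(0, "color", color)
            rows.append(df)
        comp = pd.concat(rows, ignore_index=True)
        with resources.as_file(
            resources.files("inkdose") / "data" / "compliance_printed.csv"
        ) as p:
            printed_c = pd.read_csv(p, comment="#")
        exceeds = {
            e: sorted(
                comp.loc[
                    (comp["element"] == e) & (comp["verdict"] == "exceeds"),
                    "color",
                ]
            )
            for e in printed_c["element"]
        }
        printed_c["regenerated_exceeds_in"] = [
            ",".join(exceeds[e]) if exceeds[e] else "-"
            for e in printed_c["element"]
        ]
        printed_c["match"] = [
            set(a.split(",")) == set(b.split(","))
            for a, b in zip(
                printed_c["exceeds_in"], printed_c["regenerated_exceeds_in"]
            )
        ]
        bundle.tables["compliance"] = printed_c
        _write_provenance(bundle)
        _export_tables(bundle)
        return bundle

    beam = config.beam
    if config.scenario in ("def_curves", "depth_dose"):
        control = phantom.build_phantom(tables=t)
        g_control = transport.run_simulation(
            control, beam, config.n_histories, _seed_for(config.seed, "control")
        )
        bundle.dose_grids["control"] = g_control
        p_control = analysis.depth_profile(g_control)
        bundle.profiles["control"] = p_control
        for ink in config.inks:
            for pct in config.loadings:
                tag = f"{ink}@{pct:g}"
                if pct == 0:
                    bundle.profiles[tag] = p_control
                    continue
                mat = materials.tattoo_mixture(ink, pct, t)
                ph = phantom.build_phantom(tattoo_material=mat, tables=t)
                g = transport.run_simulation(
                    ph, beam, config.n_histories, _seed_for(config.seed, tag)
                )
                bundle.dose_grids[tag] = g
                prof = analysis.depth_profile(g)
                bundle.profiles[tag] = prof
                if config.scenario == "def_curves":
                    bundle.def_results[tag] = analysis.def_statistics(
                        prof, p_control
                    )
        _export_def_tables(bundle)

    elif config.scenario == "quadrant_maps":
        pct = config.quadrant_loading
        quad = {
            "top_left": None,
            "top_right": materials.tattoo_mixture("black", pct, t)
            if pct > 0
            else None,
            "bottom_left": materials.tattoo_mixture("orange", pct, t)
            if pct > 0
            else None,
            "bottom_right": materials.tattoo_mixture("brown", pct, t)
            if pct > 0
            else None,
        }
        ph = phantom.build_phantom(layout="quadrant", quadrant_inks=quad, tables=t)
        g = transport.run_simulation(
            ph, beam, config.n_histories, _seed_for(config.seed, "quadrant")
        )
        bundle.dose_grids["quadrant"] = g
        bundle.lateral_maps["quadrant"] = analysis.lateral_map(
            g, quadrant_map=ph.quadrant_map
        )
        uni = phantom.build_phantom(layout="quadrant", quadrant_inks={
            q: None for q in phantom.QUADRANTS
        }, tables=t)
        g_uni = transport.run_simulation(
            uni, beam, config.n_histories, _seed_for(config.seed, "uniform-control")
        )
        bundle.dose_grids["uniform_control"] = g_uni
        bundle.lateral_maps["uniform_control"] = analysis.lateral_map(g_uni)

    _write_provenance(bundle)
    return bundle


def _export_tables(bundle: ResultBundle) -> None:
    out = bundle.config.output_dir
    if out is None:
        return
    path = Path(out)
    path.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables.items():
        df.to_csv(path / f"{name}.csv", index=False)


def _export_def_tables(bundle: ResultBundle) -> None:
    out = bundle.config.output_dir
    if out is None:
        return
    path = Path(out)
    path.mkdir(parents=True, exist_ok=True)
    for tag, prof in bundle.profiles.items():
        prof.to_frame().to_csv(
            path / f"depth_dose_{tag.replace('@', '_')}.csv", index=False
        )
    for tag, res in bundle.def_results.items():
        res.to_frame().to_csv(
            path / f"def_{tag.replace('@', '_')}.csv", index=False
        )
    for tag, g in bundle.dose_grids.items():
        g.to_csv(path / f"dose_{tag.replace('@', '_')}.csv", extended=True)


def headline_summary(
    n_histories: int = 1_000_000,
    seed: int = 1,
    modalities=("photon6", "photon18", "electron6", "electron18"),
) -> dict:
    """Run the headline brown-ink comparison set and summarize it.

    For each requested modality a no-ink control and a 100 vol% brown run
    are simulated (plus orange and black under 6 MeV electrons, which
    feed the integrated-dose comparison); the returned dict carries the
    DEF summary statistics on their natural scales, with percentages in
    percent. Deterministic per (n_histories, seed).
    """
    t = load_reference_tables()
    beams = {
        "photon6": transport.BeamSpec("photon", 6.0),
        "photon18": transport.BeamSpec("photon", 18.0),
        "electron6": transport.BeamSpec("electron", 6.0),
        "electron18": transport.BeamSpec("electron", 18.0),
    }
    control = phantom.build_phantom(tables=t)
    brown = phantom.build_phantom(
        tattoo_material=materials.tattoo_mixture("brown", 100, t), tables=t
    )
    out: dict = {
        "n_histories": n_histories,
        "seed": seed,
        "_results": {},
        "_timings": {},
    }
    band = analysis.TATTOO_BAND_MM

    import time as _time

    def _timed_run(ph, beam, tag):
        t0 = _time.perf_counter()
        g = transport.run_simulation(
            ph, beam, n_histories, _seed_for(seed, tag)
        )
        out["_timings"][tag] = _time.perf_counter() - t0
        return g

    def band_mean(profile):
        sel = (profile.z_centers > band[0]) & (profile.z_centers < band[1])
        return float(profile.mean_dose[sel].mean())

    for key in modalities:
        beam = beams[key]
        g_c = _timed_run(control, beam, f"{key}-control")
        g_b = _timed_run(brown, beam, f"{key}-brown")
        p_c = analysis.depth_profile(g_c)
        p_b = analysis.depth_profile(g_b)
        r = analysis.def_statistics(p_b, p_c)
        out["_results"][key] = r
        out[f"peak_def_{key}"] = r.peak_def
        out[f"tattoo_mean_def_rise_pct_{key}"] = 100 * (r.tattoo_mean_def - 1)
        out[f"tattoo_mean_dose_rise_pct_{key}"] = 100 * (
            band_mean(p_b) / band_mean(p_c) - 1
        )
        out[f"sub_layer_min_def_{key}"] = r.sub_layer_min_def
        out[f"integrated_dose_change_pct_{key}"] = 100 * (r.integrated_def - 1)

        if key == "electron6":
            devs = [abs(r.integrated_def - 1)]
            for ink in ("orange", "black"):
                ph = phantom.build_phantom(
                    tattoo_material=materials.tattoo_mixture(ink, 100, t),
                    tables=t,
                )
                g = _timed_run(ph, beam, f"{key}-{ink}")
                ri = analysis.def_statistics(analysis.depth_profile(g), p_c)
                out["_results"][f"{key}-{ink}"] = ri
                devs.append(abs(ri.integrated_def - 1))
            out["max_integrated_dose_change_pct_electron6"] = 100 * max(devs)
    return out


def make_figures(bundle: ResultBundle, out_dir) -> list:
    """Standard figures for a bundle (DEF curves / profiles / maps)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if bundle.def_results:
        fig, ax = plt.subplots(figsize=(5, 4))
        for tag, r in bundle.def_results.items():
            ax.errorbar(r.z_centers, r.def_curve, yerr=r.def_sd, label=tag)
        ax.axhline(1.0, color="k", lw=0.5)
        ax.axvspan(1.25, 1.55, color="0.85", label="tattoo layer")
        ax.set_xlabel("depth (mm)")
        ax.set_ylabel("DEF")
        ax.legend(fontsize=7)
        f = out / "def_curves.png"
        fig.savefig(f, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(f)
    if bundle.profiles:
        fig, ax = plt.subplots(figsize=(5, 4))
        for tag, p in bundle.profiles.items():
            ax.plot(p.z_centers, p.mean_dose, label=tag)
        ax.set_xlabel("depth (mm)")
        ax.set_ylabel("dose (Gy / primary)")
        ax.legend(fontsize=7)
        f = out / "depth_dose.png"
        fig.savefig(f, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(f)
    for tag, lm in bundle.lateral_maps.items():
        fig, ax = plt.subplots(figsize=(4.5, 4))
        im = ax.pcolormesh(
            lm.x_centers, lm.y_centers, lm.map.T, shading="nearest"
        )
        fig.colorbar(im, ax=ax, label="dose (Gy / primary)")
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        f = out / f"lateral_map_{tag}.png"
        fig.savefig(f, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(f)
    return written
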