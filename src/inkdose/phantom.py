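"""Voxelized multilayer tattooed-skin phantom.

Depth axis: z increases downward from the skin surface (z = 0), in mm.
The stack is six epidermal sublayers (100.1 um total), a 0.4 mm papillary
dermis, and a 1.9 mm reticular dermis with a 0.3 mm tattoo sublayer
embedded at 1.25-1.55 mm, followed by a thick water slab that supplies
backscatter. Laterally the phantom spans 3x3 cm (wider than the 1x1 cm
field) and the tattoo sublayer is either uniform or split into four
0.5x0.5 cm quadrants holding different inks.

Voxel intervals are half-open [lower, upper): a point on a shared
boundary belongs to the deeper layer. The geometry grid follows exact
layer boundaries and is independent of (and finer than) the 0.1 mm
dose-scoring mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import GeometryError
from .materials import Material, skin_material, water
from .reference import ReferenceTables, load_reference_tables

__all__ = ["LayerSpec", "PhantomGrid", "build_phantom", "material_at"]

QUADRANTS = ("top_left", "top_right", "bottom_left", "bottom_right")


@dataclass(frozen=True)
class LayerSpec:
    """One depth slab: [z_top, z_bottom) mm below the surface."""

    name: str
    z_top: float
    z_bottom: float
    material: Material

    def __post_init__(self):
        if not self.z_bottom > self.z_top:
            raise GeometryError(f"layer {self.name}: z_bottom <= z_top")

    @property
    def thickness(self) -> float:
        return self.z_bottom - self.z_top


@dataclass(frozen=True)
class PhantomGrid:
    """Layer stack plus lateral tattoo layout and the scoring mesh."""

    layers: tuple  # LayerSpec, tiling [0, total_depth)
    tattoo_z: tuple  # (1.25, 1.55) mm
    tattoo_layer_index: int
    layout: str  # "uniform" | "quadrant"
    quadrant_map: Mapping[str, Optional[str]]  # quadrant -> ink label/None
    quadrant_materials: tuple  # Material per QUADRANTS entry (tattoo slab)
    lateral_extent: float  # full width, mm
    x_edges: np.ndarray  # scoring mesh, mm
    y_edges: np.ndarray
    z_edges: np.ndarray  # scoring depth bins (0-2.4 mm)

    # -- derived -------------------------------------------------------
    @property
    def z_bounds(self) -> np.ndarray:
        return np.array(
            [l.z_top for l in self.layers] + [self.layers[-1].z_bottom]
        )

    @property
    def materials(self) -> tuple:
        """Unique materials, id order used by material_ids."""
        seen: dict[str, Material] = {}
        for l in self.layers:
            seen.setdefault(l.material.name, l.material)
        for m in self.quadrant_materials:
            seen.setdefault(m.name, m)
        return tuple(seen.values())

    def _mat_id(self, m: Material) -> int:
        names = [x.name for x in self.materials]
        return names.index(m.name)

    @property
    def layer_material_ids(self) -> np.ndarray:
        return np.array([self._mat_id(l.material) for l in self.layers])

    @property
    def quadrant_material_ids(self) -> np.ndarray:
        return np.array([self._mat_id(m) for m in self.quadrant_materials])

    @property
    def material_index(self) -> np.ndarray:
        """(2, 2, n_layers) material-id array over quadrants and depth."""
        n = len(self.layers)
        idx = np.tile(self.layer_material_ids, (2, 2, 1))
        ti = self.tattoo_layer_index
        # (ix, iy): x<0 -> 0, y<0 -> 0 ; top = +y
        idx[0, 1, ti] = self.quadrant_material_ids[QUADRANTS.index("top_left")]
        idx[1, 1, ti] = self.quadrant_material_ids[QUADRANTS.index("top_right")]
        idx[0, 0, ti] = self.quadrant_material_ids[QUADRANTS.index("bottom_left")]
        idx[1, 0, ti] = self.quadrant_material_ids[QUADRANTS.index("bottom_right")]
        return idx

    def material_at(self, x: float, y: float, z: float) -> Material:
        return material_at(self, x, y, z)

    def quadrant_of(self, x: float, y: float) -> str:
        return QUADRANTS[(0 if y >= 0 else 2) + (0 if x < 0 else 1)]

    def voxel_summary(self) -> pd.DataFrame:
        rows = []
        for i, l in enumerate(self.layers):
            rows.append(
                {
                    "layer": l.name,
                    "z_top_mm": l.z_top,
                    "z_bottom_mm": l.z_bottom,
                    "material": l.material.name,
                    "density_g_cm3": l.material.density,
                    "is_tattoo": i == self.tattoo_layer_index,
                }
            )
        return pd.DataFrame(rows)

    def scoring_mass_grid(self) -> np.ndarray:
        """Mass (g) of phantom material in each scoring voxel.

        Integrates layer densities over each depth bin; lateral scoring
        bins nest inside quadrants by construction, so each voxel sees a
        single material column.
        """
        nx, ny, nz = len(self.x_edges) - 1, len(self.y_edges) - 1, len(self.z_edges) - 1
        mass = np.zeros((nx, ny, nz))
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        area_cm2 = (
            np.diff(self.x_edges)[:, None] * np.diff(self.y_edges)[None, :] / 100.0
        )
        for k in range(nz):
            z0, z1 = self.z_edges[k], self.z_edges[k + 1]
            for l_i, l in enumerate(self.layers):
                dz = min(z1, l.z_bottom) - max(z0, l.z_top)
                if dz <= 0:
                    continue
                if l_i == self.tattoo_layer_index:
                    for ix, x in enumerate(xc):
                        for iy, y in enumerate(yc):
                            q = self.quadrant_of(x, y)
                            rho = self.quadrant_materials[
                                QUADRANTS.index(q)
                            ].density
                            mass[ix, iy, k] += rho * dz / 10.0 * area_cm2[ix, iy]
                else:
                    mass[:, :, k] += l.material.density * dz / 10.0 * area_cm2
        return mass

    def total_mass(self) -> float:
        """Mass (g) of the full 3x3 cm phantom column over all layers."""
        area = (self.lateral_extent / 10.0) ** 2
        m = 0.0
        for i, l in enumerate(self.layers):
            if i == self.tattoo_layer_index:
                qa = area / 4.0
                m += sum(
                    qm.density * l.thickness / 10.0 * qa
                    for qm in self.quadrant_materials
                )
            else:
                m += l.material.density * l.thickness / 10.0 * area
        return m


def material_at(grid: PhantomGrid, x: float, y: float, z: float) -> Material:
    """Constant-time material lookup; boundary points go to the deeper layer."""
    half = grid.lateral_extent / 2.0
    if not (-half <= x <= half and -half <= y <= half):
        raise GeometryError(f"point ({x}, {y}) outside lateral extent")
    zb = grid.z_bounds
    if z < zb[0] or z >= zb[-1]:
        raise GeometryError(f"depth {z} outside [0, {zb[-1]}) mm")
    i = int(np.searchsorted(zb, z, side="right") - 1)
    if i == grid.tattoo_layer_index:
        q = grid.quadrant_of(x, y)
        return grid.quadrant_materials[QUADRANTS.index(q)]
    return grid.layers[i].material


def build_phantom(
    tattoo_material: Optional[Material] = None,
    layout: str = "uniform",
    quadrant_inks: Optional[Mapping[str, Optional[Material]]] = None,
    tables: Optional[ReferenceTables] = None,
) -> PhantomGrid:
    """Assemble the layered tattooed-skin phantom and its scoring mesh.

    ``layout="uniform"`` fills the whole 1.25-1.55 mm sublayer with
    ``tattoo_material`` (or leaves it as reticular dermis for a control
    phantom when ``None``). ``layout="quadrant"`` splits the tattoo plane
    into four 0.5x0.5 cm quadrants assigned from ``quadrant_inks``
    (quadrant label -> Material or None for control).
    """
    t = tables or load_reference_tables()
    consts = t.constants
    tattoo_z = tuple(consts["tattoo_z_mm"])

    dermis = skin_material("reticular_dermis", t)
    stack: list[LayerSpec] = []
    z = 0.0
    for name, thick_um, _dens in t.skin_layers:
        z1 = z + thick_um / 1000.0
        stack.append(LayerSpec(name, z, z1, skin_material(name, t)))
        z = z1
    skin_bottom = z

    # locate the reticular dermis and carve out the tattoo sublayer
    ret = next(l for l in stack if l.name == "reticular_dermis")
    if not (ret.z_top < tattoo_z[0] and tattoo_z[1] < ret.z_bottom):
        raise GeometryError(
            f"tattoo sublayer {tattoo_z} not strictly inside the reticular "
            f"dermis ({ret.z_top}, {ret.z_bottom})"
        )
    i = stack.index(ret)
    stack[i : i + 1] = [
        LayerSpec("reticular_dermis_upper", ret.z_top, tattoo_z[0], dermis),
        LayerSpec("tattoo_sublayer", tattoo_z[0], tattoo_z[1], dermis),
        LayerSpec("reticular_dermis_lower", tattoo_z[1], ret.z_bottom, dermis),
    ]
    tattoo_idx = i + 1

    backing = float(consts["water_backing_mm"])
    stack.append(
        LayerSpec("water_backing", skin_bottom, skin_bottom + backing, water())
    )

    if layout == "uniform":
        tat = tattoo_material if tattoo_material is not None else dermis
        quad_mats = (tat, tat, tat, tat)
        quad_map = {q: (tat.name if tattoo_material is not None else None) for q in QUADRANTS}
        dxy = float(consts["scoring_dxy_mm"])
    elif layout == "quadrant":
        if quadrant_inks is None or set(quadrant_inks) != set(QUADRANTS):
            raise GeometryError(
                "quadrant layout requires assignments for all four quadrants"
            )
        quad_mats = tuple(
            quadrant_inks[q] if quadrant_inks[q] is not None else dermis
            for q in QUADRANTS
        )
        quad_map = {
            q: (quadrant_inks[q].name if quadrant_inks[q] is not None else None)
            for q in QUADRANTS
        }
        dxy = float(consts["scoring_dxy_quadrant_mm"])
    else:
        raise GeometryError(f"unknown layout {layout!r}")

    if tattoo_material is not None and layout == "uniform":
        stack[tattoo_idx] = LayerSpec(
            "tattoo_sublayer", tattoo_z[0], tattoo_z[1], tattoo_material
        )

    field_mm = float(consts["field_cm"]) * 10.0
    nxy = int(round(field_mm / dxy))
    xy_edges = -field_mm / 2.0 + dxy * np.arange(nxy + 1)
    dz = float(consts["scoring_dz_mm"])
    depth = float(consts["scoring_depth_mm"])
    z_edges = dz * np.arange(int(round(depth / dz)) + 1)

    return PhantomGrid(
        layers=tuple(stack),
        tattoo_z=tattoo_z,
        tattoo_layer_index=tattoo_idx,
        layout=layout,
        quadrant_map=quad_map,
        quadrant_materials=quad_mats,
        lateral_extent=float(consts["lateral_extent_mm"]),
        x_edges=xy_edges,
        y_edges=xy_edges.copy(),
        z_edges=z_edges,
    )
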