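"""Surface areas, interface statistics and assembly-pathway energetics.

Solvent-accessible surface area (SASA) is computed with the Shrake-Rupley
sphere-point method on Bondi radii (probe 1.4 A, 960 points per atom by
default).  From SASA follow the interface quantities used to reason about
ring assembly: buried surface area (BSA) on complexation, the contact%
statistic BSA/(ASA + BSA) of a subunit within an oligomer, and an atomic
solvation-parameter estimate of the solvation free-energy gain.

The assembly-pathway model treats per-oligomer dissociation free energies
(into monomers) as input data and derives formation free energies of any
stoichiometrically balanced step by the thermodynamic cycle
dG0_f = -(dG0_diss(product) - sum dG0_diss(parts)); negative values are
favourable.  The shipped defaults are the published dG0_diss table for the
(ab)_n states n = 2, 3, 4, 6, 8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import VDW_RADII
from .structure import Atom

__all__ = [
    "SASAResult",
    "InterfaceReport",
    "AssemblyEnergyModel",
    "shrake_rupley_sasa",
    "interface_report",
    "contact_percent",
    "solvation_energy_estimate",
    "formation_energy",
    "pathway_graph",
    "DEFAULT_DG_DISS",
    "DEFAULT_ASP",
    "DEFAULT_ROUTES",
]

# Published dissociation free energies into monomers, kcal/mol, by oligomer
# order n of the (alpha-beta)_n state.  The monomer itself is the reference.
DEFAULT_DG_DISS: dict[int, float] = {1: 0.0, 2: 4.8, 3: 20.9, 4: 16.0,
                                     6: 54.6, 8: 20.9}

# Atomic solvation parameters, kcal/(mol A^2) (Eisenberg-McLachlan-type
# values); configurable, used only for the documented dG approximation.
DEFAULT_ASP: dict[str, float] = {"C": 0.016, "N": -0.006, "O": -0.006,
                                 "S": 0.021, "P": 0.016}


@dataclass
class SASAResult:
    per_atom_area: np.ndarray   # A^2
    total: float                # A^2
    probe_radius: float
    n_sphere_points: int
    radii_set: str = "bondi"


@dataclass
class InterfaceReport:
    part_a: str
    part_b: str
    asa_a: float                # isolated ASA of part A, A^2
    asa_b: float
    asa_complex: float          # ASA of the union
    buried: float               # per part: (asa_a + asa_b - asa_complex)/2
    buried_a: float             # part-attributable burial
    buried_b: float
    contact_percent_a: float    # 100 * buried_a / asa_a
    contact_percent_b: float


def _unit_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform sphere points (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radii_for(atoms: list[Atom], radii: dict[str, float]) -> np.ndarray:
    out = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        key = a.element.upper()
        if key not in radii:
            raise ValueError(f"no van der Waals radius for element {a.element!r}")
        out[i] = radii[key]
    return out


def shrake_rupley_sasa(atoms: list[Atom], probe: float = 1.4,
                       n_points: int = 960,
                       radii_set: str = "bondi",
                       radii: dict[str, float] | None = None) -> SASAResult:
    """Per-atom solvent-accessible surface area by sphere-point sampling.

    Each atom's sphere of radius r_vdw + probe is sampled at ``n_points``
    quasi-uniform points; points inside any neighbour's expanded sphere are
    occluded.  Neighbour search uses a KD-tree at cutoff 2*(r_max + probe).
    Unknown elements raise (no silent default radius).
    """
    if not atoms:
        raise ValueError("SASA of an empty atom set is undefined")
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    rvdw = _radii_for(atoms, radii or VDW_RADII)
    R = rvdw + probe
    xyz = np.array([a.coords for a in atoms])
    sphere = _unit_sphere(n_points)
    tree = cKDTree(xyz)
    cutoff = 2.0 * (R.max())
    neigh = tree.query_ball_point(xyz, r=cutoff)
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        pts = xyz[i] + R[i] * sphere
        occluded = np.zeros(n_points, dtype=bool)
        for j in neigh[i]:
            if j == i:
                continue
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            occluded |= d2 < R[j] ** 2
        frac = 1.0 - occluded.mean()
        areas[i] = 4.0 * math.pi * R[i] ** 2 * frac
    return SASAResult(per_atom_area=areas, total=float(areas.sum()),
                      probe_radius=probe, n_sphere_points=n_points,
                      radii_set=radii_set)


def interface_report(part_a: list[Atom], part_b: list[Atom],
                     label_a: str = "A", label_b: str = "B",
                     probe: float = 1.4, n_points: int = 960,
                     radii: dict[str, float] | None = None) -> InterfaceReport:
    """ASA/BSA/contact% for two disjoint atom sets and their complex."""
    ids_a = {(a.chain_id, a.residue_number, a.name) for a in part_a}
    ids_b = {(b.chain_id, b.residue_number, b.name) for b in part_b}
    if ids_a & ids_b:
        raise ValueError("parts overlap: "
                         f"{len(ids_a & ids_b)} shared atom identities")
    sa = shrake_rupley_sasa(part_a, probe, n_points, radii=radii)
    sb = shrake_rupley_sasa(part_b, probe, n_points, radii=radii)
    sc = shrake_rupley_sasa(part_a + part_b, probe, n_points, radii=radii)
    asa_a_in_complex = float(sc.per_atom_area[:len(part_a)].sum())
    asa_b_in_complex = float(sc.per_atom_area[len(part_a):].sum())
    buried_a = sa.total - asa_a_in_complex
    buried_b = sb.total - asa_b_in_complex
    buried = (sa.total + sb.total - sc.total) / 2.0
    return InterfaceReport(
        part_a=label_a, part_b=label_b,
        asa_a=sa.total, asa_b=sb.total, asa_complex=sc.total,
        buried=buried, buried_a=buried_a, buried_b=buried_b,
        contact_percent_a=contact_percent(buried_a, asa_a_in_complex),
        contact_percent_b=contact_percent(buried_b, asa_b_in_complex),
    )


def contact_percent(buried: float, accessible: float) -> float:
    """contact% = 100 * BSA / (ASA + BSA).

    ``accessible`` is the area that remains solvent-exposed in the complex,
    so ASA + BSA equals the part's isolated surface area.
    """
    if buried < 0 and buried > -1e-6:
        buried = 0.0
    if buried < 0 or accessible < 0:
        raise ValueError("areas must be non-negative")
    if buried == 0 and accessible == 0:
        raise ValueError("contact% undefined for zero total area")
    return 100.0 * buried / (accessible + buried)


def solvation_energy_estimate(part_a: list[Atom], part_b: list[Atom],
                              asp: dict[str, float] | None = None,
                              probe: float = 1.4, n_points: int = 960) -> float:
    """Atomic-solvation-parameter estimate of the free-energy change on
    complexation, kcal/mol.

    Sum over atoms of ASP(element) x (area buried when the complex forms).
    This is an explicit approximation of interface solvation energetics; it
    is linear in buried area and is not expected to reproduce any particular
    reference program's parameterization.
    """
    asp = asp or DEFAULT_ASP
    sa = shrake_rupley_sasa(part_a, probe, n_points)
    sb = shrake_rupley_sasa(part_b, probe, n_points)
    sc = shrake_rupley_sasa(part_a + part_b, probe, n_points)
    iso = np.concatenate([sa.per_atom_area, sb.per_atom_area])
    buried = iso - sc.per_atom_area
    total = 0.0
    for atom, b in zip(part_a + part_b, buried):
        key = atom.element.upper()
        if key not in asp:
            raise ValueError(f"no atomic solvation parameter for {atom.element!r}")
        total += asp[key] * float(b)
    return total


# ---------------------------------------------------------------------------
# Assembly-pathway thermodynamics
# ---------------------------------------------------------------------------

@dataclass
class AssemblyEnergyModel:
    """Per-oligomer dG0_diss (into monomers) and derived route energetics."""

    dg_diss: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_DG_DISS))
    dg_int: dict[int, float] = field(default_factory=dict)

    def diss(self, n: int) -> float:
        if n not in self.dg_diss:
            raise KeyError(f"no dG0_diss entry for oligomer n={n}")
        return self.dg_diss[n]

    def ranking(self) -> list[int]:
        """Oligomer orders sorted by decreasing stability (dG0_diss)."""
        return sorted((n for n in self.dg_diss if n > 1),
                      key=lambda n: -self.dg_diss[n])


def formation_energy(parts: list[int], product: int,
                     model: AssemblyEnergyModel | None = None) -> float:
    """dG0_f (kcal/mol) of forming one product oligomer from parts.

    Monomer counts must balance; negative means favourable formation.
    """
    model = model or AssemblyEnergyModel()
    total_parts = sum(parts)
    if total_parts != product:
        raise ValueError(f"unbalanced stoichiometry: parts supply {total_parts} "
                         f"monomers but product needs {product}")
    return -(model.diss(product) - sum(model.diss(p) for p in parts))


# Route steps: (multiplicity, parts, product).  Each named route carries the
# full stoichiometry from monomers to the final oligomer so that the summed
# step energies telescope to -dG0_diss(final).
DEFAULT_ROUTES: dict[str, list[tuple[int, list[int], int]]] = {
    "monomer->trimer->hexamer": [(2, [1, 1, 1], 3), (1, [3, 3], 6)],
    "monomer->dimer->octamer": [(4, [1, 1], 2), (1, [2, 2, 2, 2], 8)],
    "monomer->dimer->tetramer->octamer": [(4, [1, 1], 2), (2, [2, 2], 4),
                                          (1, [4, 4], 8)],
}


def pathway_graph(model: AssemblyEnergyModel | None = None,
                  routes: dict[str, list[tuple[int, list[int], int]]] | None = None,
                  ) -> list[dict]:
    """Annotated per-step dG0_f table over assembly routes.

    Each step row carries the step dG0_f (per single product formed), its
    multiplicity within the route, and an ``unfavorable`` flag for positive
    steps; each route ends with a total row whose energy equals
    -dG0_diss(final product) exactly (telescoping identity).
    """
    model = model or AssemblyEnergyModel()
    routes = DEFAULT_ROUTES if routes is None else routes
    rows: list[dict] = []
    for name, steps in routes.items():
        total = 0.0
        final = None
        for mult, parts, product in steps:
            dg = formation_energy(parts, product, model)
            total += mult * dg
            final = product
            rows.append({
                "route": name, "step": f"{'+'.join(map(str, parts))}->{product}",
                "multiplicity": mult, "dg_f": dg,
                "unfavorable": dg > 0,
            })
        rows.append({"route": name, "step": "total(from monomers)",
                     "multiplicity": 1, "dg_f": total,
                     "unfavorable": total > 0, "final_n": final})
    return rows
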