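"""Ring symmetry detection and inter-protomer geometry.

The quantities implemented here characterise how the same (alpha-beta)
protomer closes into rings of different order: the monomer "bend" angle at
three published anchor residues, the anchor angle between adjacent monomers,
the rotation angle between superposed neighbouring protomers (360/n for an
ideal C_n ring), the order difference Delta-theta = 360/n - 360/m, and the
inner pore diameter of the ring.

The "dihedral angle of the monomer" quoted for these assemblies is defined
by three anchor residues; three points carry no torsion, so it is computed
as the planar angle at the middle (vertex) anchor on CA atoms, which is the
only reading that reproduces the published 110/123 degree values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure import Assembly, Protomer, match_ca, superpose

__all__ = [
    "AngleMeasurement",
    "SymmetryReport",
    "vertex_angle",
    "monomer_bend_angle",
    "adjacent_monomer_angle",
    "interface_rotation",
    "detect_symmetry",
    "delta_theta",
    "pore_diameter",
    "DEFAULT_BEND_ANCHORS",
    "DEFAULT_ADJACENT_ANCHORS",
    "VDW_RADII",
]

# Published anchor residues, author numbering: (alpha Gln70, alpha Arg30
# vertex, beta Gly70) for the monomer bend; (alpha Gln70, beta Pro69 vertex,
# adjacent beta Pro69) between monomers.
DEFAULT_BEND_ANCHORS = (70, 30, 70)
DEFAULT_ADJACENT_ANCHORS = (70, 69, 69)

# Bondi van der Waals radii, Angstrom.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "FE": 2.00, "ZN": 1.39, "MG": 1.73, "NA": 2.27, "K": 2.75,
}


@dataclass
class AngleMeasurement:
    label: str
    vertex_atoms: np.ndarray  # (3, 3) CA coordinates, vertex in the middle
    value: float              # degrees, [0, 180]
    protomer_pair: tuple[int, ...]
    per_copy: list[float] = field(default_factory=list)


@dataclass
class SymmetryReport:
    order_n: int
    sym_type: str             # "Cn" or "Dn"
    axis: np.ndarray          # unit 3-vector
    center: np.ndarray        # Angstrom
    per_interface_angle: list[float]
    mean_angle_residual: float
    delta_theta: float | None = None


def vertex_angle(p1, p2, p3) -> float:
    """Angle at vertex p2 between rays p2->p1 and p2->p3, degrees in [0, 180]."""
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    u, v = p1 - p2, p3 - p2
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("coincident points: angle undefined")
    c = float(u @ v) / (nu * nv)
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def _anchor_ca(assembly: Assembly, chain_id: str, resnum: int) -> np.ndarray:
    atom = assembly.find_ca(chain_id, resnum)
    if atom is None:
        raise ValueError(f"anchor residue {resnum} (CA) missing in chain {chain_id}")
    return atom.coords


def monomer_bend_angle(assembly: Assembly, protomer: Protomer,
                       anchors: tuple[int, int, int] = DEFAULT_BEND_ANCHORS,
                       ) -> AngleMeasurement:
    """Bend of one (alpha-beta) monomer at its three anchor CA atoms.

    Anchors are (alpha residue, alpha residue [vertex], beta residue);
    defaults are the published alpha-Gln70 / alpha-Arg30 / beta-Gly70.
    """
    a1 = _anchor_ca(assembly, protomer.alpha_chain, anchors[0])
    a2 = _anchor_ca(assembly, protomer.alpha_chain, anchors[1])
    a3 = _anchor_ca(assembly, protomer.beta_chain, anchors[2])
    val = vertex_angle(a1, a2, a3)
    label = f"alpha{anchors[0]}-alpha{anchors[1]}-beta{anchors[2]}"
    return AngleMeasurement(label, np.vstack([a1, a2, a3]), val,
                            (protomer.index,))


def layer_mask(rel: np.ndarray, axis: np.ndarray) -> np.ndarray | None:
    """Boolean mask of the upper layer, or None for a single-layer ring.

    Two layers are declared when the axial spread of the centroids exceeds
    half their mean in-plane radius -- robust against coordinate jitter on a
    flat single ring, where the axial spread is tiny.
    """
    axial = rel @ axis
    inplane = np.linalg.norm(rel - np.outer(axial, axis), axis=1)
    spread = axial.max() - axial.min()
    if spread > 0.5 * max(float(inplane.mean()), 1e-6):
        mid = (axial.max() + axial.min()) / 2.0
        mask = axial >= mid
        if mask.any() and (~mask).any():
            return mask
    return None


def _layers(assembly: Assembly) -> list[list[Protomer]]:
    """Split protomers into axial layers (one layer for Cn, two for Dn)."""
    if not assembly.protomers:
        raise ValueError("assembly has no protomers; call group_protomers first")
    cents = np.array([assembly.protomer_centroid(p) for p in assembly.protomers])
    center = cents.mean(axis=0)
    rel = cents - center
    # Use the axis chosen by symmetry detection (which tries both covariance
    # extremes); a lone eigen-extreme can point in-plane for squat stacks.
    axis = detect_symmetry(assembly).axis
    mask = layer_mask(rel, axis)
    if mask is not None:
        top = [p for p, m in zip(assembly.protomers, mask) if m]
        bottom = [p for p, m in zip(assembly.protomers, mask) if not m]
        return [top, bottom]
    return [list(assembly.protomers)]


def adjacent_monomer_angle(assembly: Assembly, i: int,
                           anchors: tuple[int, int, int] = DEFAULT_ADJACENT_ANCHORS,
                           ) -> AngleMeasurement:
    """Anchor angle between protomer i and its azimuthal neighbour.

    Anchors are (alpha residue of protomer i, beta residue of protomer i
    [vertex], beta residue of the next protomer in the same layer); defaults
    are the published alpha-Gln70 / beta-Pro69 / beta-Pro69'.
    """
    layers = _layers(assembly)
    layer = next((ly for ly in layers if any(p.index == i for p in ly)), None)
    if layer is None:
        raise ValueError(f"no protomer with index {i}")
    layer = sorted(layer, key=lambda p: p.index)
    pos = [p.index for p in layer].index(i)
    pi = layer[pos]
    if len(layer) < 2:
        raise ValueError("layer has a single protomer; no adjacent monomer")
    a1 = _anchor_ca(assembly, pi.alpha_chain, anchors[0])
    a2 = _anchor_ca(assembly, pi.beta_chain, anchors[1])
    # Of the two azimuthal neighbours, the interface partner is the one whose
    # beta anchor sits nearest this protomer's alpha anchor.
    candidates = [layer[(pos + 1) % len(layer)]]
    if layer[(pos - 1) % len(layer)].index != candidates[0].index:
        candidates.append(layer[(pos - 1) % len(layer)])
    pj = min(candidates, key=lambda p: float(np.linalg.norm(
        _anchor_ca(assembly, p.beta_chain, anchors[2]) - a1)))
    a3 = _anchor_ca(assembly, pj.beta_chain, anchors[2])
    val = vertex_angle(a1, a2, a3)
    label = f"alpha{anchors[0]}-beta{anchors[1]}-beta{anchors[2]}'"
    return AngleMeasurement(label, np.vstack([a1, a2, a3]), val,
                            (pi.index, pj.index))


def average_angle(assembly: Assembly, kind: str = "bend",
                  anchors: tuple[int, int, int] | None = None) -> AngleMeasurement:
    """Average a bend or adjacent angle over all symmetry-equivalent copies."""
    values: list[float] = []
    meas = None
    if kind == "bend":
        anc = anchors or DEFAULT_BEND_ANCHORS
        for p in assembly.protomers:
            meas = monomer_bend_angle(assembly, p, anc)
            values.append(meas.value)
    elif kind == "adjacent":
        anc = anchors or DEFAULT_ADJACENT_ANCHORS
        for p in assembly.protomers:
            meas = adjacent_monomer_angle(assembly, p.index, anc)
            values.append(meas.value)
    else:
        raise ValueError(f"unknown angle kind: {kind!r}")
    assert meas is not None
    out = AngleMeasurement(meas.label, meas.vertex_atoms,
                           float(np.mean(values)), (-1,), per_copy=values)
    return out


def interface_rotation(assembly: Assembly, i: int, j: int,
                       mode: str = "by_resnum") -> float:
    """Rotation angle (degrees) superposing protomer i onto protomer j."""
    pi = next(p for p in assembly.protomers if p.index == i)
    pj = next(p for p in assembly.protomers if p.index == j)
    arrays = []
    for ca, cb in ((pi.alpha_chain, pj.alpha_chain), (pi.beta_chain, pj.beta_chain)):
        A, B = match_ca(assembly, ca, assembly, cb, mode=mode)
        arrays.append((A, B))
    A = np.vstack([a for a, _ in arrays])
    B = np.vstack([b for _, b in arrays])
    return superpose(A, B).angle_deg


def delta_theta(n: int, m: int) -> float:
    """Inter-subunit rotation-angle difference (360/n - 360/m), degrees."""
    if n < 2 or m < 2:
        raise ValueError("ring orders must be >= 2")
    return 360.0 / n - 360.0 / m


def _best_axis(rel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Candidate principal axes (both covariance extremes) for a centroid cloud."""
    cov = rel.T @ rel
    w, v = np.linalg.eigh(cov)
    small, large = v[:, 0], v[:, 2]
    return (small if small[2] >= 0 else -small,
            large if large[2] >= 0 else -large)


def _ring_residual(rel: np.ndarray, axis: np.ndarray, n: int) -> tuple[float, list[float]]:
    """Mean |azimuthal gap - 360/n| for points expected at n-fold spacing."""
    axial = rel @ axis
    inplane = rel - np.outer(axial, axis)
    ref = inplane[0]
    if np.linalg.norm(ref) < 1e-9:
        return 1e9, []
    ref = ref / np.linalg.norm(ref)
    perp = np.cross(axis, ref)
    az = np.sort(np.mod(np.arctan2(inplane @ perp, inplane @ ref), 2 * math.pi))
    gaps = np.degrees(np.diff(np.concatenate([az, [az[0] + 2 * math.pi]])))
    ideal = 360.0 / n
    return float(np.mean(np.abs(gaps - ideal))), [float(g) for g in gaps]


def detect_symmetry(assembly: Assembly,
                    candidate_orders: list[int] | None = None) -> SymmetryReport:
    """Detect the cyclic order and Cn/Dn type of a ring assembly.

    Protomer centroids are tested against n-fold azimuthal spacing about a
    principal axis; both covariance-extreme eigenvectors are tried and the
    axis with the lower residual kept.  Two layers of equal size related by a
    perpendicular 2-fold give Dn, a single layer Cn.  Ties within 1e-3 degree
    residual prefer the larger (more specific) order.
    """
    if len(assembly.protomers) < 2:
        raise ValueError("symmetry detection needs at least 2 protomers")
    candidate_orders = candidate_orders or [2, 3, 4, 5, 6, 7, 8]
    cents = np.array([assembly.protomer_centroid(p) for p in assembly.protomers])
    center = cents.mean(axis=0)
    rel = cents - center

    best = None
    for axis in _best_axis(rel):
        mask = layer_mask(rel, axis)
        groups = [rel[mask], rel[~mask]] if mask is not None else [rel]
        for n in candidate_orders:
            if any(len(g) != n for g in groups):
                continue
            res, gaps = 0.0, []
            for g in groups:
                r, gp = _ring_residual(g, axis, n)
                res += r / len(groups)
                gaps += gp
            sym = "Dn" if len(groups) == 2 else "Cn"
            cand = (res, n, sym, axis, gaps)
            if best is None or res < best[0] - 1e-3 or \
                    (abs(res - best[0]) <= 1e-3 and n > best[1]):
                best = cand
    if best is None:
        raise ValueError(
            f"no candidate order in {candidate_orders} matches the "
            f"{len(assembly.protomers)} protomers")
    res, n, sym, axis, gaps = best
    return SymmetryReport(order_n=n, sym_type=sym, axis=axis, center=center,
                          per_interface_angle=gaps, mean_angle_residual=res)


def pore_diameter(assembly: Assembly, axis: np.ndarray, center: np.ndarray,
                  radii: dict[str, float] | None = None) -> dict[str, float]:
    """Inner pore diameter of a ring about its symmetry axis.

    Returns both the van der Waals diameter, 2*(min radial atom distance
    minus that atom's vdW radius), and the raw axis-to-nearest-atom diameter.
    A non-ring (axis passing through atoms) is flagged.
    """
    radii = radii or VDW_RADII
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    xyz = assembly.coords()
    rel = xyz - np.asarray(center, float)
    radial = np.linalg.norm(rel - np.outer(rel @ axis, axis), axis=1)
    rvdw = np.array([radii.get(a.element.upper(), radii.get(a.element, 1.7))
                     for a in assembly.atoms])
    vdw_clear = radial - rvdw
    i = int(np.argmin(vdw_clear))
    return {
        "diameter_vdw": float(2 * vdw_clear[i]),
        "diameter_raw": float(2 * radial.min()),
        "is_ring": bool(vdw_clear[i] > 0),
    }
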