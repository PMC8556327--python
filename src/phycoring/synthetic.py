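"""Synthetic ring assemblies and simulated sedimentation experiments.

Every input the analysis pipeline needs can be generated here with known
ground truth: idealized C_n / D_n rings built from a minimal two-chain toy
protomer (CA trace, anchor residues at the published author numbers, one
pseudo-chromophore per chain thioether-anchored to a cysteine), and
sedimentation-velocity scans of a known species mixture with seeded
Gaussian noise.

The toy protomer is intentionally minimal: enough structure to exercise
angle measurement, symmetry detection, surface-area and chromophore-network
code, with no pretence of biological realism.  The construction places the
three bend anchors and the three adjacent-monomer anchors so that the
requested angles hold exactly in the jitter-free ring, which makes every
downstream geometric estimate testable as parameter recovery.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .sedimentation import (DEFAULT_BUFFER, HydroParams, SedimentationDataset,
                            diffusion_from_s, lamm_simulate)
from .structure import Assembly, Atom, Protomer, write_structure

__all__ = ["RingSpec", "AUCSpec", "RingGroundTruth", "build_ring",
           "write_fixture", "simulate_auc", "HEXAMER_LIKE", "OCTAMER_LIKE",
           "DEFAULT_MIXTURE"]

_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase


@dataclass(frozen=True)
class RingSpec:
    """Construction parameters of an idealized symmetric ring."""

    n: int = 3                   # protomers per layer
    layers: int = 1              # 1 -> Cn, 2 -> Dn
    ring_radius: float = 35.0    # A, protomer anchor radius
    bend_angle: float = 110.0    # degrees, monomer-internal anchor angle
    adjacent_angle: float = 52.0  # degrees, inter-monomer anchor angle
    jitter_sigma: float = 0.0    # A, Gaussian coordinate noise
    seed: int = 0
    layer_offset: float = 14.0   # A, axial offset of each layer's base

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("ring order n must be >= 2")
        if self.layers not in (1, 2):
            raise ValueError("layers must be 1 or 2")
        if self.ring_radius <= 0:
            raise ValueError("ring_radius must be positive")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be non-negative")
        if not 0 < self.bend_angle < 180 or not 0 < self.adjacent_angle < 180:
            raise ValueError("construction angles must lie in (0, 180) degrees")


#: Hexamer-like geometry: two stacked trimer layers, published bend/adjacent angles.
HEXAMER_LIKE = RingSpec(n=3, layers=2, bend_angle=110.0, adjacent_angle=52.0)
#: Octamer-like geometry: two stacked tetramer layers, wider ring and angles.
OCTAMER_LIKE = RingSpec(n=4, layers=2, ring_radius=42.0,
                        bend_angle=123.0, adjacent_angle=90.0)


@dataclass
class RingGroundTruth:
    axis: np.ndarray
    center: np.ndarray
    order_n: int
    sym_type: str
    interface_rotation: float           # degrees, 360/n
    bend_angle: float
    adjacent_angle: float
    chromophore_centroids: dict[str, np.ndarray]  # site key -> jitter-free centroid
    min_radial_clearance: float         # A, min (radial distance - vdW) over atoms


# Anchor author numbers of the toy protomer (match the published anchors).
ALPHA_ANCHOR_OUTER = 70   # alpha Gln70 analogue
ALPHA_ANCHOR_VERTEX = 30  # alpha Arg30 analogue
BETA_ANCHOR_BEND = 70     # beta Gly70 analogue
BETA_ANCHOR_ADJ = 69      # beta Pro69 analogue
ALPHA_CYS = 84
BETA_CYS = 82


def _rot_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_ROT_X_PI = np.diag([1.0, -1.0, -1.0])


def _template(spec: RingSpec) -> tuple[list[tuple], list[tuple], dict[str, np.ndarray]]:
    """Atoms of protomer 0 (layer 0) in the global frame.

    Returns (alpha_atoms, beta_atoms, key_points) where atom tuples are
    (name, resname, resnum, xyz, is_het, element).
    """
    gamma = 2.0 * math.pi / spec.n
    h = spec.layer_offset
    R = spec.ring_radius
    adj = math.radians(spec.adjacent_angle)
    bend = math.radians(spec.bend_angle)
    zhat = np.array([0.0, 0.0, 1.0])

    b69 = np.array([R, 0.0, h])
    # unit vector toward the adjacent protomer's b69 (in-plane chord direction)
    v2 = np.array([-math.sin(gamma / 2.0), math.cos(gamma / 2.0), 0.0])
    # anchor lever arms of 16 / 12 A: long enough that 0.3 A coordinate
    # jitter propagates well under a degree into the measured angles
    a70 = b69 + 16.0 * (math.cos(adj) * v2 + math.sin(adj) * zhat)
    a30 = a70 + 12.0 * zhat
    b70 = a30 + 12.0 * (-math.cos(bend) * zhat + math.sin(bend) * v2)

    def outward(p):
        u = np.array([p[0], p[1], 0.0])
        nrm = np.linalg.norm(u)
        return u / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])

    alpha: list[tuple] = []
    beta: list[tuple] = []

    # alpha backbone: arc between the two alpha anchors with an outward bulge
    u_a = outward(a70)
    for i, resnum in enumerate(range(31, 46)):
        t = (i + 1) / 16.0
        p = a30 + t * (a70 - a30) + 3.0 * math.sin(math.pi * t) * u_a
        alpha.append(("CA", "ALA", resnum, p, False, "C"))
    alpha.append(("CA", "ARG", ALPHA_ANCHOR_VERTEX, a30, False, "C"))
    alpha.append(("CA", "GLN", ALPHA_ANCHOR_OUTER, a70, False, "C"))
    # bridge residues toward the beta chain (guarantee intra-protomer contacts)
    for i, resnum in enumerate(range(46, 52)):
        t = (i + 1) / 7.0
        alpha.append(("CA", "GLY", resnum, a70 + t * (b69 - a70), False, "C"))

    # beta backbone: arc between its anchors
    u_b = outward(b70)
    for i, resnum in enumerate(range(50, 66)):
        t = (i + 1) / 17.0
        p = b70 + t * (b69 - b70) + 3.0 * math.sin(math.pi * t) * u_b
        beta.append(("CA", "ALA", resnum, p, False, "C"))
    for i, resnum in enumerate(range(66, 69)):
        beta.append(("CA", "GLY", resnum,
                     b69 + (i + 1) * 0.8 * (b70 - b69) / np.linalg.norm(b70 - b69),
                     False, "C"))
    beta.append(("CA", "PRO", BETA_ANCHOR_ADJ, b69, False, "C"))
    beta.append(("CA", "GLY", BETA_ANCHOR_BEND, b70, False, "C"))

    key = {}
    # chromophores: Cys anchor (CA + SG) plus a 4-carbon pseudo-tetrapyrrole
    for chain_atoms, cys_num, base, u in ((alpha, ALPHA_CYS, a70, u_a),
                                          (beta, BETA_CYS, b70, u_b)):
        ca = base + 2.0 * u
        sg = ca + 1.5 * u
        chain_atoms.append(("CA", "CYS", cys_num, ca, False, "C"))
        chain_atoms.append(("SG", "CYS", cys_num, sg, False, "S"))
        ring_atoms = [sg + 1.8 * u,
                      sg + 1.8 * u + np.array([0.0, 0.0, 1.4]),
                      sg + 3.2 * u,
                      sg + 3.2 * u + np.array([0.0, 0.0, 1.4])]
        for j, p in enumerate(ring_atoms):
            chain_atoms.append((f"C{j + 1}", "CYC", 301, p, True, "C"))
        key[f"cys{cys_num}"] = np.mean(ring_atoms, axis=0)
    key.update(a70=a70, a30=a30, b70=b70, b69=b69)
    return alpha, beta, key


def build_ring(spec: RingSpec) -> tuple[Assembly, RingGroundTruth]:
    """Construct an idealized C_n or D_n ring with ground truth attached."""
    alpha0, beta0, key = _template(spec)
    gamma = 2.0 * math.pi / spec.n

    atoms: list[Atom] = []
    protomers: list[Protomer] = []
    truth_centroids: dict[str, np.ndarray] = {}
    chain_counter = 0
    index = 0
    for layer in range(spec.layers):
        flip = _ROT_X_PI if layer == 1 else np.eye(3)
        for k in range(spec.n):
            Rk = flip @ _rot_z(k * gamma)
            aid = _CHAIN_IDS[chain_counter]
            bid = _CHAIN_IDS[chain_counter + 1]
            chain_counter += 2
            for cid, template in ((aid, alpha0), (bid, beta0)):
                for name, resname, resnum, xyz, is_het, element in template:
                    atoms.append(Atom(element=element, name=name,
                                      coords=Rk @ xyz, residue_name=resname,
                                      residue_number=resnum, chain_id=cid,
                                      is_hetero=is_het))
            protomers.append(Protomer(aid, bid, index))
            truth_centroids[f"{index}:a{ALPHA_CYS}PCB"] = Rk @ key[f"cys{ALPHA_CYS}"]
            truth_centroids[f"{index}:b{BETA_CYS}PCB"] = Rk @ key[f"cys{BETA_CYS}"]
            index += 1

    assembly = Assembly(atoms, protomers,
                        label=f"{'D' if spec.layers == 2 else 'C'}{spec.n}_ring")
    vdw = {"C": 1.70, "S": 1.80}
    xyz = assembly.coords()
    radial = np.hypot(xyz[:, 0], xyz[:, 1])
    clearance = float(np.min(radial - np.array(
        [vdw[a.element] for a in assembly.atoms])))

    if spec.jitter_sigma > 0:
        # One Gaussian offset per residue (not per atom): coordinate noise
        # displaces residues but never stretches covalent geometry such as
        # the chromophore thioether link.
        rng = np.random.default_rng(spec.seed)
        offsets: dict[tuple, np.ndarray] = {}
        jittered = []
        for a in atoms:
            key = (a.chain_id, a.residue_number, a.residue_name)
            if key not in offsets:
                offsets[key] = rng.normal(0.0, spec.jitter_sigma, size=3)
            jittered.append(Atom(element=a.element, name=a.name,
                                 coords=a.coords + offsets[key],
                                 residue_name=a.residue_name,
                                 residue_number=a.residue_number,
                                 chain_id=a.chain_id, is_hetero=a.is_hetero))
        atoms = jittered
        assembly = Assembly(atoms, protomers, label=assembly.label)

    truth = RingGroundTruth(
        axis=np.array([0.0, 0.0, 1.0]), center=np.zeros(3),
        order_n=spec.n, sym_type="Dn" if spec.layers == 2 else "Cn",
        interface_rotation=360.0 / spec.n,
        bend_angle=spec.bend_angle, adjacent_angle=spec.adjacent_angle,
        chromophore_centroids=truth_centroids,
        min_radial_clearance=clearance)
    return assembly, truth


def write_fixture(assembly: Assembly, path: str | Path,
                  format: str = "auto") -> Path:
    """Write a synthetic assembly as a PDB/mmCIF fixture file."""
    return write_structure(assembly, path, format=format)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Simulated sedimentation-velocity experiments
# ---------------------------------------------------------------------------

#: Species mixture emulating the observed solution: minor monomer, dominant
#: dimer, minor tetramer and hexamer, at the reported s values (Svedberg)
#: with one shared frictional ratio.
DEFAULT_MIXTURE: tuple[tuple[float, float, float], ...] = (
    (3.15, 1.195, 0.10),
    (5.24, 1.195, 0.55),
    (7.97, 1.195, 0.08),
    (11.32, 1.195, 0.12),
)


@dataclass(frozen=True)
class AUCSpec:
    """Ground-truth description of a simulated sedimentation experiment."""

    species: tuple[tuple[float, float, float], ...] = DEFAULT_MIXTURE
    noise_sigma: float = 0.005     # absorbance units (target residual level)
    times: tuple[float, ...] = tuple(float(t) for t in range(600, 6000, 400))
    seed: int = 0

    def __post_init__(self):
        for s, f, loading in self.species:
            if s <= 0 or f < 1.0 or loading < 0:
                raise ValueError("species need s > 0, f/f0 >= 1, loading >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def simulate_auc(spec: AUCSpec,
                 buffer: HydroParams = DEFAULT_BUFFER,
                 vbar: float | None = None,
                 geometry: tuple[float, float] = (6.0, 7.2),
                 n_cells: int = 600,
                 radial_step: float = 0.003,
                 ) -> tuple[SedimentationDataset, dict]:
    """Simulate noisy scans for a known species mixture.

    Per-species diffusion follows from its frictional ratio via the standard
    scaling; scans are the forward Lamm solution on a fine grid, resampled to
    an instrument-like radial step, plus i.i.d. Gaussian noise with the given
    seed.  Returns the dataset and a ground-truth record.
    """
    r_m, r_b = geometry
    species_sdl = [(s, diffusion_from_s(s, f, buffer, vbar), loading)
                   for s, f, loading in spec.species]
    radii = np.arange(r_m + radial_step / 2.0, r_b, radial_step)
    if species_sdl:
        data = lamm_simulate(species_sdl, buffer, geometry, spec.times,
                             n_cells=n_cells, radii_out=radii)
    else:
        data = SedimentationDataset(radii=radii, times=np.asarray(spec.times),
                                    scans=np.zeros((len(spec.times), radii.size)),
                                    meniscus=r_m, bottom=r_b)
    rng = np.random.default_rng(spec.seed)
    noisy = data.scans + rng.normal(0.0, spec.noise_sigma, size=data.scans.shape)
    dataset = SedimentationDataset(radii=data.radii, times=data.times,
                                   scans=noisy, meniscus=r_m, bottom=r_b)
    truth = {
        "species": [{"s": s, "f_ratio": f, "loading": loading, "D": D}
                    for (s, f, loading), (_, D, _) in zip(spec.species, species_sdl)],
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "geometry": geometry,
    }
    return dataset, truth
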