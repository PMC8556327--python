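"""Coordinate data model, structure file I/O and rigid-body superposition.

Assemblies of phycobiliprotein rings are handled as flat atom lists grouped
into author-labelled chains; chains are paired into (alpha, beta) protomers,
the repeating heterodimer unit of the ring.  All coordinates are in Angstrom
and author (auth_) chain IDs / residue numbers are preserved exactly, because
published anchor residues (e.g. alpha-Arg30, beta-Pro69) are quoted in author
numbering.

Rigid superposition uses the Kabsch algorithm restricted to proper rotations
(det = +1): biological assemblies are chiral, so reflections are never
admitted even when they would fit better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Protomer",
    "Assembly",
    "RigidTransform",
    "StructureParseError",
    "read_structure",
    "write_structure",
    "group_protomers",
    "superpose",
    "match_ca",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "MEN": "N",
}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed or is degenerate."""


@dataclass(frozen=True)
class Atom:
    """A single heavy atom with author-numbered provenance."""

    element: str
    name: str
    coords: np.ndarray  # shape (3,), Angstrom
    residue_name: str
    residue_number: int
    chain_id: str
    is_hetero: bool = False

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if not self.element:
            raise ValueError("atom element symbol must be non-empty")


@dataclass
class Protomer:
    """An (alpha-beta) heterodimer unit, referenced by chain IDs."""

    alpha_chain: str
    beta_chain: str
    index: int

    def __post_init__(self):
        if self.alpha_chain == self.beta_chain:
            raise ValueError("alpha and beta chains must be distinct")


@dataclass
class Assembly:
    """A ring assembly: atoms plus an optional protomer decomposition."""

    atoms: list[Atom]
    protomers: list[Protomer] = field(default_factory=list)
    label: str = ""

    @property
    def n(self) -> int:
        """Oligomer order: number of (alpha-beta) units assigned."""
        return len(self.protomers)

    def chain_ids(self, protein_only: bool = False) -> list[str]:
        seen: dict[str, bool] = {}
        for a in self.atoms:
            if a.chain_id not in seen:
                seen[a.chain_id] = True
        if protein_only:
            return [c for c in seen if any(
                not a.is_hetero for a in self.atoms if a.chain_id == c)]
        return list(seen)

    def chain(self, chain_id: str, hetero: bool | None = None) -> list[Atom]:
        out = [a for a in self.atoms if a.chain_id == chain_id]
        if hetero is not None:
            out = [a for a in out if a.is_hetero == hetero]
        return out

    def coords(self, atoms: Iterable[Atom] | None = None) -> np.ndarray:
        src = self.atoms if atoms is None else list(atoms)
        return np.array([a.coords for a in src], dtype=float).reshape(-1, 3)

    def ca_atoms(self, chain_id: str) -> list[Atom]:
        return [a for a in self.atoms
                if a.chain_id == chain_id and a.name == "CA" and not a.is_hetero]

    def find_ca(self, chain_id: str, residue_number: int) -> Atom | None:
        for a in self.ca_atoms(chain_id):
            if a.residue_number == residue_number:
                return a
        return None

    def protomer_atoms(self, protomer: Protomer, hetero: bool = False) -> list[Atom]:
        chains = {protomer.alpha_chain, protomer.beta_chain}
        return [a for a in self.atoms
                if a.chain_id in chains and a.is_hetero == hetero]

    def protomer_centroid(self, protomer: Protomer) -> np.ndarray:
        xyz = self.coords(self.protomer_atoms(protomer))
        return xyz.mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Assembly":
        """Return a copy with every atom mapped through x -> R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new_atoms = [replace(a, coords=R @ a.coords + t) for a in self.atoms]
        return Assembly(new_atoms, [replace(p) for p in self.protomers], self.label)


@dataclass
class RigidTransform:
    """Proper rigid-body transform y = R x + t with its residual."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def __post_init__(self):
        R = np.asarray(self.rotation, float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-8):
            raise ValueError("rotation must be proper (det +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")
        self.rotation = R
        self.translation = np.asarray(self.translation, float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    @property
    def angle_deg(self) -> float:
        """Rotation angle theta = arccos((tr(R) - 1)/2), degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return math.degrees(math.acos(min(1.0, max(-1.0, c))))


# ---------------------------------------------------------------------------
# File I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    head = path.read_text(errors="replace")[:2048]
    if head.lstrip().startswith("data_") or "_atom_site" in head:
        return "mmcif"
    return "pdb"


def read_structure(path: str | Path, format: Literal["mmcif", "pdb", "auto"] = "auto",
                   label: str | None = None) -> Assembly:
    """Read an mmCIF or PDB file into an :class:`Assembly`.

    All ATOM and HETATM records are kept (hydrogens dropped, alternate
    locations other than ' '/'A' dropped); protomers are left unassigned
    until :func:`group_protomers` is called.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    if format == "auto":
        format = _detect_format(path)
    try:
        if format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif format == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise StructureParseError(f"unknown structure format: {format!r}")
    except StructureParseError:
        raise
    except Exception as exc:  # gemmi raises RuntimeError/ValueError with context
        raise StructureParseError(f"cannot parse {path} as {format}: {exc}") from exc

    st.setup_entities()
    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for res in chain:
            is_het = res.het_flag == "H" and res.name != "MSE"
            for at in res:
                if at.element.name in ("H", "D"):
                    continue
                if at.altloc not in ("", "A", "\0"):
                    continue
                atoms.append(Atom(
                    element=at.element.name,
                    name=at.name,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    residue_name=res.name,
                    residue_number=res.seqid.num,
                    chain_id=chain.name,
                    is_hetero=is_het,
                ))
    if not atoms:
        raise StructureParseError(f"no atoms in {path}")
    return Assembly(atoms, label=label if label is not None else path.stem)


def write_structure(assembly: Assembly, path: str | Path,
                    format: Literal["mmcif", "pdb", "auto"] = "auto") -> Path:
    """Write an assembly as a minimal valid PDB or mmCIF file."""
    import gemmi

    path = Path(path)
    if format == "auto":
        format = _detect_format_from_name(path)
    st = gemmi.Structure()
    st.name = assembly.label or "assembly"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    serial = 0
    for a in assembly.atoms:
        if a.chain_id not in chains:
            chains[a.chain_id] = gemmi.Chain(a.chain_id)
        chain = chains[a.chain_id]
        res = None
        if len(chain) > 0:
            last = chain[-1]
            if last.seqid.num == a.residue_number and last.name == a.residue_name:
                res = last
        if res is None:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            res.het_flag = "H" if a.is_hetero else "A"
            chain.add_residue(res)
            res = chain[-1]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.coords)
        at.occ = 1.0
        at.b_iso = 0.0
        serial += 1
        at.serial = serial
        res.add_atom(at)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if format == "pdb":
        st.write_pdb(str(path))
    elif format == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise StructureParseError(f"unknown structure format: {format!r}")
    return path


def _detect_format_from_name(path: Path) -> str:
    return "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"


# ---------------------------------------------------------------------------
# Protomer grouping
# ---------------------------------------------------------------------------

def group_protomers(assembly: Assembly,
                    pairing: Literal["by_contact", "by_order"] = "by_contact",
                    contact_cutoff: float = 5.0) -> Assembly:
    """Pair protein chains into (alpha, beta) protomers.

    ``by_contact`` pairs each putative alpha chain (taken in file order) with
    the protein chain sharing the largest number of inter-chain atom contacts
    within ``contact_cutoff`` Angstrom; a tie within 5% between the two best
    candidates is an error.  ``by_order`` pairs chains in file order.  Protomer
    indices are assigned by layer (axial coordinate) and azimuth about the
    assembly's principal centroid axis, so index k and k+1 are azimuthal
    neighbours within one layer.
    """
    chain_ids = assembly.chain_ids(protein_only=True)
    if len(chain_ids) % 2 != 0:
        raise ValueError(f"odd number of protein chains ({len(chain_ids)}); "
                         "cannot pair into (alpha-beta) protomers")

    pairs: list[tuple[str, str]] = []
    if pairing == "by_order":
        for i in range(0, len(chain_ids), 2):
            pairs.append((chain_ids[i], chain_ids[i + 1]))
    elif pairing == "by_contact":
        coords = {c: assembly.coords([a for a in assembly.chain(c) if not a.is_hetero])
                  for c in chain_ids}
        trees = {c: cKDTree(coords[c]) for c in chain_ids}
        unassigned = list(chain_ids)
        while unassigned:
            a_chain = unassigned.pop(0)
            counts = []
            for other in unassigned:
                n = trees[a_chain].count_neighbors(trees[other], contact_cutoff)
                counts.append((n, other))
            counts.sort(reverse=True)
            if not counts or counts[0][0] == 0:
                raise ValueError(f"chain {a_chain} has no contact partner "
                                 f"within {contact_cutoff} A")
            if len(counts) > 1 and counts[1][0] > 0.95 * counts[0][0]:
                raise ValueError(
                    "ambiguous contact pairing for chain "
                    f"{a_chain}: candidates {counts[0][1]} ({counts[0][0]} contacts) "
                    f"and {counts[1][1]} ({counts[1][0]} contacts) within 5%")
            partner = counts[0][1]
            unassigned.remove(partner)
            pairs.append((a_chain, partner))
    else:
        raise ValueError(f"unknown pairing mode: {pairing!r}")

    # Order protomers by (layer, azimuth) about the principal centroid axis.
    centroids = np.array([
        np.vstack([assembly.coords([a for a in assembly.chain(c) if not a.is_hetero])
                   for c in pair]).mean(axis=0)
        for pair in pairs])
    center = centroids.mean(axis=0)
    rel = centroids - center
    from .geometry import _best_axis, _ring_residual, layer_mask
    # Try both covariance-extreme axes; keep the one with the more uniform
    # azimuthal spacing (squat double rings can be prolate along the ring axis).
    best = None
    for cand in _best_axis(rel):
        mask = layer_mask(rel, cand)
        groups = [rel[mask], rel[~mask]] if mask is not None else [rel]
        score = float(np.mean([_ring_residual(g, cand, len(g))[0]
                               for g in groups if len(g) > 0]))
        if best is None or score < best[0]:
            best = (score, cand, mask)
    _, axis, upper = best
    axial = rel @ axis
    ref = rel[0] - axial[0] * axis
    if np.linalg.norm(ref) < 1e-9:
        ref = np.array([1.0, 0.0, 0.0])
    ref = ref / np.linalg.norm(ref)
    perp = np.cross(axis, ref)
    order = []
    for i in range(len(pairs)):
        inplane = rel[i] - axial[i] * axis
        az = math.atan2(float(inplane @ perp), float(inplane @ ref)) % (2 * math.pi)
        layer = 0 if (upper is None or upper[i]) else 1
        order.append((layer, az, i))
    order.sort()
    protomers = [Protomer(pairs[i][0], pairs[i][1], k)
                 for k, (_, _, i) in enumerate(order)]
    return Assembly(assembly.atoms, protomers, assembly.label)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def superpose(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid superposition of paired coordinate sets.

    Kabsch with the reflection guard: the singular vector corresponding to the
    smallest singular value is negated when needed so that det(R) = +1.
    """
    P = np.asarray(moving, float).reshape(-1, 3)
    Q = np.asarray(fixed, float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise ValueError(f"coordinate sets differ in length: {P.shape[0]} vs {Q.shape[0]}")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 paired atoms for superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    resid = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((resid ** 2).sum() / P.shape[0]))
    return RigidTransform(rotation=R, translation=t, rmsd=rmsd, n_atoms=P.shape[0])


def chain_sequence(atoms: Sequence[Atom]) -> tuple[str, list[int]]:
    """One-letter sequence and residue numbers from a chain's CA atoms."""
    seq, nums = [], []
    for a in atoms:
        if a.name == "CA" and not a.is_hetero:
            seq.append(THREE_TO_ONE.get(a.residue_name, "X"))
            nums.append(a.residue_number)
    return "".join(seq), nums


def match_ca(assembly_a: Assembly, chain_a: str,
             assembly_b: Assembly, chain_b: str,
             mode: Literal["by_resnum", "by_alignment"] = "by_resnum",
             ) -> tuple[np.ndarray, np.ndarray]:
    """Pair CA atoms of two chains; returns two (N, 3) coordinate arrays.

    ``by_resnum`` pairs residues sharing author residue numbers.
    ``by_alignment`` pairs via global alignment of the one-letter sequences
    (match +1, mismatch 0, gap -1), keeping aligned non-gap columns.
    """
    cas_a = assembly_a.ca_atoms(chain_a)
    cas_b = assembly_b.ca_atoms(chain_b)
    if not cas_a or not cas_b:
        raise ValueError(f"chain {chain_a if not cas_a else chain_b} has no CA atoms")

    if mode == "by_resnum":
        map_a = {a.residue_number: a for a in cas_a}
        map_b = {b.residue_number: b for b in cas_b}
        common = sorted(set(map_a) & set(map_b))
        if not common:
            raise ValueError(f"chains {chain_a} and {chain_b} share no residue numbers")
        A = np.array([map_a[r].coords for r in common])
        B = np.array([map_b[r].coords for r in common])
        return A, B
    if mode == "by_alignment":
        from Bio import Align

        seq_a, _ = chain_sequence(cas_a)
        seq_b, _ = chain_sequence(cas_b)
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = 0
        aligner.open_gap_score = -1
        aligner.extend_gap_score = -1
        aln = aligner.align(seq_a, seq_b)[0]
        ia, ib = [], []
        for (a0, a1), (b0, b1) in zip(*aln.aligned):
            ia.extend(range(a0, a1))
            ib.extend(range(b0, b1))
        if not ia:
            raise ValueError(f"alignment of {chain_a} and {chain_b} has no paired columns")
        A = np.array([cas_a[i].coords for i in ia])
        B = np.array([cas_b[i].coords for i in ib])
        return A, B
    raise ValueError(f"unknown match mode: {mode!r}")
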