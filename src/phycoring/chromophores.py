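"""Chromophore site detection and distance networks.

Phycocyanobilin (PCB) chromophores are open-chain tetrapyrroles covalently
bound through thioether links to conserved cysteines (alpha-84, beta-82,
beta-153).  Chromophore proximity is the structural proxy for
excitation-energy transfer, so this module reduces each chromophore to the
centroid of its heavy atoms (alternatives: closest heavy atom) and reports
pairwise distances within one assembly, between assemblies, and across
stacked ring layers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .structure import Assembly

__all__ = [
    "ChromophoreSite",
    "DistanceNetwork",
    "locate_chromophores",
    "pair_distances",
    "stacked_layer_distances",
    "named_pair_minimum",
    "DEFAULT_CHROMOPHORE_NAMES",
]

DEFAULT_CHROMOPHORE_NAMES = frozenset({"CYC", "PCB", "BLA"})


@dataclass
class ChromophoreSite:
    """One bound chromophore, identified by its anchoring cysteine."""

    id: str                       # e.g. "a84PCB" / "b153PCB"
    residue_name: str
    residue_number: int
    chain_id: str
    anchor_cys: int | None        # author residue number of the anchor Cys
    centroid: np.ndarray          # unweighted heavy-atom mean, Angstrom
    protomer_index: int
    assembly_id: str


@dataclass
class DistanceNetwork:
    nodes: list[ChromophoreSite]
    edges: list[tuple[str, str, float, str]]  # (id_a, id_b, distance, class)
    cutoff: float | None = None

    def min_edge(self) -> tuple[str, str, float, str] | None:
        return min(self.edges, key=lambda e: e[2]) if self.edges else None


def _site_id(role: str, anchor: int | None, residue_name: str) -> str:
    tag = "PCB"
    if anchor is None:
        return f"{role}?{tag}"
    return f"{role}{anchor}{tag}"


def locate_chromophores(assembly: Assembly,
                        residue_names: frozenset[str] | set[str] = DEFAULT_CHROMOPHORE_NAMES,
                        max_thioether: float = 2.5,
                        assembly_id: str | None = None) -> list[ChromophoreSite]:
    """Find chromophore hetero residues and their anchoring cysteines.

    The anchor is the cysteine whose S-gamma lies within ``max_thioether``
    Angstrom (default 2.5, a thioether bond length with slack) of any
    chromophore carbon.  Sites without an anchor are kept with anchor unset
    (a warning is emitted) and labelled with '?' in place of the residue
    number.
    """
    assembly_id = assembly_id if assembly_id is not None else (assembly.label or "asm")
    # Index chromophore residues: (chain, resnum, name) -> atoms
    chromo: dict[tuple[str, int, str], list] = {}
    for a in assembly.atoms:
        if a.is_hetero and a.residue_name in residue_names:
            chromo.setdefault((a.chain_id, a.residue_number, a.residue_name),
                              []).append(a)
    if not chromo:
        return []
    sg = [(a.chain_id, a.residue_number, a.coords) for a in assembly.atoms
          if a.residue_name == "CYS" and a.name == "SG" and not a.is_hetero]

    alpha_of = {p.alpha_chain: p for p in assembly.protomers}
    beta_of = {p.beta_chain: p for p in assembly.protomers}

    sites = []
    for (chain, resnum, resname), atoms in sorted(chromo.items()):
        heavy = [a for a in atoms if a.element.upper() != "H"]
        centroid = np.array([a.coords for a in heavy]).mean(axis=0)
        carbons = np.array([a.coords for a in heavy if a.element.upper() == "C"])
        anchor = None
        anchor_chain = chain
        if carbons.size and sg:
            best = None
            for (sc, sr, sxyz) in sg:
                d = float(np.min(np.linalg.norm(carbons - sxyz, axis=1)))
                if d <= max_thioether and (best is None or d < best[0]):
                    best = (d, sc, sr)
            if best is not None:
                _, anchor_chain, anchor = best
        if anchor is None:
            warnings.warn(f"chromophore {resname} {chain}{resnum}: no cysteine "
                          f"S-gamma within {max_thioether} A; anchor unset")
        if anchor_chain in alpha_of:
            role, pidx = "a", alpha_of[anchor_chain].index
        elif anchor_chain in beta_of:
            role, pidx = "b", beta_of[anchor_chain].index
        else:
            role, pidx = anchor_chain, -1
        sites.append(ChromophoreSite(
            id=_site_id(role, anchor, resname), residue_name=resname,
            residue_number=resnum, chain_id=chain, anchor_cys=anchor,
            centroid=centroid, protomer_index=pidx, assembly_id=assembly_id))
    return sites


def pair_distances(sites: list[ChromophoreSite],
                   cutoff: float | None = None) -> DistanceNetwork:
    """All pairwise centroid distances between chromophore sites.

    Edges between sites of the same assembly_id are classed ``intraprotein``,
    the rest ``interprotein``; an optional cutoff drops longer edges.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 chromophore sites")
    edges = []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            d = float(np.linalg.norm(sites[i].centroid - sites[j].centroid))
            if cutoff is not None and d > cutoff:
                continue
            cls = ("intraprotein" if sites[i].assembly_id == sites[j].assembly_id
                   else "interprotein")
            edges.append((sites[i].id, sites[j].id, d, cls))
    edges.sort(key=lambda e: e[2])
    return DistanceNetwork(nodes=list(sites), edges=edges, cutoff=cutoff)


def named_pair_minimum(network: DistanceNetwork, id_a: str, id_b: str) -> float:
    """Minimum distance over all symmetry-equivalent copies of a named pair.

    Published tables quote one representative value per pair label for a
    symmetric assembly; the minimum over equivalent copies is that value.
    """
    best = math.inf
    for a, b, d, _ in network.edges:
        if {a, b} == {id_a, id_b} or (id_a == id_b and a == b == id_a):
            best = min(best, d)
    if not math.isfinite(best):
        raise ValueError(f"no edge between site ids {id_a!r} and {id_b!r}")
    return best


def stacked_layer_distances(layer_a: Assembly, layer_b: Assembly,
                            residue_names: frozenset[str] | set[str] = DEFAULT_CHROMOPHORE_NAMES,
                            max_thioether: float = 2.5) -> DistanceNetwork:
    """Cross-layer chromophore network between two stacked assemblies.

    Only inter-layer pairs are kept, sorted ascending by distance; this is
    the network used to rank candidate energy-transfer routes between rings
    stacked along a shared symmetry axis.
    """
    sa = locate_chromophores(layer_a, residue_names, max_thioether,
                             assembly_id=layer_a.label or "layerA")
    sb = locate_chromophores(layer_b, residue_names, max_thioether,
                             assembly_id=layer_b.label or "layerB")
    if (layer_a.label or "layerA") == (layer_b.label or "layerB"):
        for s in sb:
            s.assembly_id = s.assembly_id + "'"
    edges = []
    for x in sa:
        for y in sb:
            d = float(np.linalg.norm(x.centroid - y.centroid))
            edges.append((x.id, y.id, d, "interprotein"))
    edges.sort(key=lambda e: e[2])
    return DistanceNetwork(nodes=sa + sb, edges=edges)
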