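"""Geometric detection of protein–ligand interactions and the
prompt-accuracy metric.

Four interaction types are recognized: hydrogen bonds, halogen bonds,
cation-π and π-π stacking.  π-π uses the printed criteria (ring-center
distance strictly below 4.4 Å, per-ring planarity deviation ≤ 15°,
inter-normal angle ≤ 30°); the other three use declared default
geometry in one threshold block so they can be calibrated against any
interaction-fingerprinting tool version.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .complexes import (ChemAnnotations, ComplexGraph, InteractionPromptSet,
                        PromptRecord)
from .samplers import reconstruct_bonds

__all__ = [
    "DetectorThresholds",
    "DetectedInteraction",
    "MultiInteractionResidueError",
    "detect_interactions",
    "extract_prompt_set",
    "prompt_accuracy",
    "annotate_complex",
    "ring_plane",
]


@dataclass(frozen=True)
class DetectorThresholds:
    """All detector geometry in one auditable block.

    Printed criteria (strict inequalities): pi_pi_center_max,
    pi_pi_planarity_max_deg, pi_pi_normal_max_deg.  The remaining
    thresholds are declared defaults (inclusive inequalities).
    """

    hydrogen_max: float = 4.0          # Å donor-acceptor heavy-atom distance
    halogen_max: float = 4.0           # Å ligand halogen to protein acceptor
    cation_pi_max: float = 6.0         # Å charged-group center to ring center
    pi_pi_center_max: float = 4.4      # Å ring-center distance (strict <)
    pi_pi_planarity_max_deg: float = 15.0  # per-ring planarity deviation (<=)
    pi_pi_normal_max_deg: float = 30.0     # inter-normal angle (<=)
    aromatic_residues: tuple[str, ...] = ("PHE", "TYR", "TRP")
    include_his: bool = False

    def aromatic_set(self) -> set[str]:
        s = set(self.aromatic_residues)
        if self.include_his:
            s.add("HIS")
        return s


@dataclass(frozen=True)
class DetectedInteraction:
    """One geometric interaction event between a pocket residue and the
    ligand, with the geometry values that satisfied the thresholds."""

    residue_name: str
    residue_index: int
    chain: str
    interaction_type: str
    ligand_atoms: tuple[int, ...]
    protein_atoms: tuple[int, ...]
    geometry: dict = field(default_factory=dict)


class MultiInteractionResidueError(ValueError):
    """Raised when a residue carries two or more distinct interaction
    types; such complexes are excluded rather than silently pruned."""


def ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-fit plane of a ring: (centroid, unit normal, max planarity
    deviation in degrees).

    The deviation of a ring atom is the angle between the vector from the
    centroid to the atom and the fitted plane; a perfectly planar ring
    has deviation 0°.
    """
    coords = np.asarray(coords, dtype=np.float64)
    centroid = coords.mean(axis=0)
    rel = coords - centroid
    _, _, vt = np.linalg.svd(rel)
    normal = vt[2]
    dev = 0.0
    for v in rel:
        nv = np.linalg.norm(v)
        if nv < 1e-9:
            continue
        s = np.clip(abs(np.dot(v, normal)) / nv, -1.0, 1.0)
        dev = max(dev, float(np.degrees(np.arcsin(s))))
    return centroid, normal, dev


def _angle_between_normals(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two ring normals folded into [0°, 90°]."""
    c = np.clip(abs(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)),
                0.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _residue_of(graph: ComplexGraph, protein_idx: int):
    a = graph.protein[protein_idx]
    return a.residue_name, a.residue_index, a.chain


def detect_interactions(graph: ComplexGraph,
                        thresholds: DetectorThresholds | None = None
                        ) -> list[DetectedInteraction]:
    """Scan a chemistry-annotated complex for the four interaction types.

    Requires ``graph.chem``; run bond reconstruction / annotation first
    (see `annotate_complex`).
    """
    if graph.chem is None:
        raise ValueError(
            "complex lacks chemistry annotations; run annotate_complex() "
            "(bond reconstruction + role assignment) before detection")
    thr = thresholds or DetectorThresholds()
    chem = graph.chem
    xl, xp = graph.x_L, graph.x_P
    out: list[DetectedInteraction] = []

    def emit(ptype, l_atoms, p_atoms, geometry, p_ref_atom):
        name, idx, chain = _residue_of(graph, p_ref_atom)
        out.append(DetectedInteraction(
            residue_name=name, residue_index=idx, chain=chain,
            interaction_type=ptype, ligand_atoms=tuple(l_atoms),
            protein_atoms=tuple(p_atoms), geometry=geometry))

    # hydrogen bonds: ligand donor/acceptor vs protein acceptor/donor
    for li in sorted(chem.ligand_donors | chem.ligand_acceptors):
        partners = set()
        if li in chem.ligand_donors:
            partners |= chem.protein_acceptors
        if li in chem.ligand_acceptors:
            partners |= chem.protein_donors
        for pi in sorted(partners):
            d = float(np.linalg.norm(xl[li] - xp[pi]))
            if d <= thr.hydrogen_max:
                emit("hydrogen", [li], [pi], {"distance": d}, pi)

    # halogen bonds: ligand Cl/Br/I as the donor-side atom
    for li in sorted(chem.ligand_halogens):
        for pi in sorted(chem.protein_acceptors):
            d = float(np.linalg.norm(xl[li] - xp[pi]))
            if d <= thr.halogen_max:
                emit("halogen", [li], [pi], {"distance": d}, pi)

    aromatic = thr.aromatic_set()
    protein_rings = [r for r in chem.protein_rings
                     if graph.protein[r[0]].residue_name in aromatic]

    # cation-pi: ligand cation vs protein aromatic ring, and the reverse
    for li in sorted(chem.ligand_cations):
        for ring in protein_rings:
            center, _, _ = ring_plane(xp[list(ring)])
            d = float(np.linalg.norm(xl[li] - center))
            if d <= thr.cation_pi_max:
                emit("cation-pi", [li], ring, {"distance": d}, ring[0])
    for ring in chem.ligand_rings:
        center_l, _, _ = ring_plane(xl[list(ring)])
        for pi in sorted(chem.protein_cations):
            d = float(np.linalg.norm(center_l - xp[pi]))
            if d <= thr.cation_pi_max:
                emit("cation-pi", ring, [pi], {"distance": d}, pi)

    # pi-pi stacking: printed criteria, strict center-distance inequality
    for lring in chem.ligand_rings:
        c_l, n_l, dev_l = ring_plane(xl[list(lring)])
        for pring in protein_rings:
            c_p, n_p, dev_p = ring_plane(xp[list(pring)])
            d = float(np.linalg.norm(c_l - c_p))
            ang = _angle_between_normals(n_l, n_p)
            if (d < thr.pi_pi_center_max
                    and dev_l <= thr.pi_pi_planarity_max_deg
                    and dev_p <= thr.pi_pi_planarity_max_deg
                    and ang <= thr.pi_pi_normal_max_deg):
                emit("pi-pi", lring, pring,
                     {"center_distance": d, "normal_angle": ang,
                      "planarity_ligand": dev_l, "planarity_protein": dev_p},
                     pring[0])
    return out


def extract_prompt_set(graph: ComplexGraph,
                       thresholds: DetectorThresholds | None = None
                       ) -> InteractionPromptSet:
    """Distill detections into per-residue prompt records.

    A residue detected with two or more distinct interaction types makes
    the whole complex invalid as training material; this raises
    MultiInteractionResidueError rather than dropping records.
    """
    detections = detect_interactions(graph, thresholds)
    by_residue: dict[tuple, set[str]] = {}
    names: dict[tuple, str] = {}
    for d in detections:
        key = (d.chain, d.residue_index)
        by_residue.setdefault(key, set()).add(d.interaction_type)
        names[key] = d.residue_name
    multi = {k: v for k, v in by_residue.items() if len(v) > 1}
    if multi:
        desc = "; ".join(f"{names[k]}-{k[1]}: {sorted(v)}"
                         for k, v in multi.items())
        raise MultiInteractionResidueError(
            f"complex rejected: residue(s) with multiple interaction types "
            f"({desc})")
    records = tuple(
        PromptRecord(residue_name=names[k], residue_index=k[1],
                     interaction_type=next(iter(v)), chain=k[0])
        for k, v in sorted(by_residue.items()))
    return InteractionPromptSet(records)


def prompt_accuracy(prompted: InteractionPromptSet,
                    detected: list[DetectedInteraction]) -> float:
    """Fraction of prompted (residue, type) pairs realized among the
    detections; extra detections neither help nor hurt."""
    if len(prompted) == 0:
        raise ValueError("prompt accuracy is undefined for an empty prompt set")
    matched = 0
    for rec in prompted:
        hit = any(
            d.residue_index == rec.residue_index
            and d.residue_name == rec.residue_name
            and d.interaction_type == rec.interaction_type
            and (not rec.chain or not d.chain or d.chain == rec.chain)
            for d in detected)
        matched += int(hit)
    return matched / len(prompted)


# ---------------------------------------------------------------------------
# chemistry annotation

# hydrogen-bond-capable protein atoms by residue (heavy atoms; backbone
# N donates, backbone O accepts, handled separately)
_SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "LYS": {"NZ"}, "TRP": {"NE1"},
    "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}
_CATION_ATOMS = {"LYS": {"NZ"}, "ARG": {"CZ"}}
_RING_ATOMS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}
_HALOGENS = {"Cl", "Br", "I"}


def annotate_complex(graph: ComplexGraph,
                     ligand_cations: set[int] | None = None) -> ComplexGraph:
    """Attach chemistry annotations derived from geometry and residue
    templates.

    Ligand: bonds are reconstructed from coordinates; N/O atoms act as
    both donors and acceptors (hydrogens are implicit), Cl/Br/I are
    halogen-bond donors, aromatic rings come from ring perception.
    Ligand charged groups cannot be inferred without protonation states;
    pass `ligand_cations` explicitly (quaternary nitrogens are flagged
    automatically).  Protein: roles follow residue/atom-name templates.
    """
    from dataclasses import replace

    donors, acceptors, halogens, cations = set(), set(), set(), set()
    rings: tuple[tuple[int, ...], ...] = ()
    if graph.n_ligand:
        mol = reconstruct_bonds(graph.x_L, graph.ligand_elements)
        deg = np.zeros(graph.n_ligand, dtype=int)
        for i, j, _ in mol.bonds:
            deg[i] += 1
            deg[j] += 1
        for i, e in enumerate(graph.ligand_elements):
            if e in ("N", "O"):
                donors.add(i)
                acceptors.add(i)
            if e in _HALOGENS:
                halogens.add(i)
            if e == "N" and deg[i] >= 4:
                cations.add(i)
        rings = mol.aromatic_rings
    if ligand_cations:
        cations |= set(ligand_cations)

    p_donors, p_acceptors, p_cations = set(), set(), set()
    ring_map: dict[tuple, list[int]] = {}
    for i, a in enumerate(graph.protein):
        res, an = a.residue_name, a.atom_name
        if an == "N":
            p_donors.add(i)
        if an in ("O", "OXT"):
            p_acceptors.add(i)
        if an in _SIDECHAIN_DONORS.get(res, ()):
            p_donors.add(i)
        if an in _SIDECHAIN_ACCEPTORS.get(res, ()):
            p_acceptors.add(i)
        if an in _CATION_ATOMS.get(res, ()):
            p_cations.add(i)
        if an in _RING_ATOMS.get(res, ()):
            ring_map.setdefault((a.chain, a.residue_index), []).append(i)
    protein_rings = tuple(tuple(v) for v in ring_map.values() if len(v) >= 5)

    chem = ChemAnnotations(
        ligand_donors=frozenset(donors),
        ligand_acceptors=frozenset(acceptors),
        ligand_halogens=frozenset(halogens),
        ligand_cations=frozenset(cations),
        ligand_rings=rings,
        protein_donors=frozenset(p_donors),
        protein_acceptors=frozenset(p_acceptors),
        protein_cations=frozenset(p_cations),
        protein_rings=protein_rings,
    )
    return replace(graph, chem=chem)
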