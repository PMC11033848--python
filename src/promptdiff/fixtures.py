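"""Deterministic toy pocket+ligand complexes with planted interaction
geometries.

Pocket residues are rigid 3–7 atom motifs, not full amino acids: every
geometric detection criterion concerns a local functional group (a
donor/acceptor oxygen, a charged nitrogen, an aromatic hexagon), so the
motifs carry exactly those groups under standard residue/atom names.
Residue slots sit on a circle around the origin with their functional
atoms pointing inward; a planted interaction places the matching ligand
contact group at a geometry that satisfies the detector's thresholds
with a comfortable margin (≥ 0.2 Å / 3°), so detection recovers exactly
the planted prompt set at zero noise.

All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .complexes import (AtomRecord, ComplexGraph, InteractionPromptSet,
                        PromptRecord, normalize_interaction_type)
from .interactions import annotate_complex

__all__ = ["ToyComplexSpec", "make_toy_complex", "make_toy_dataset",
           "DEFAULT_TEMPLATE"]

_SLOT_RADIUS = 8.0       # Å, residue anchor distance from the pocket center
_CONTACT = {             # planted contact geometry per interaction type (Å)
    "hydrogen": 2.9,     # ligand O to serine OG (threshold 4.0)
    "halogen": 3.2,      # ligand Cl to aspartate OD1 (threshold 4.0)
    "cation-pi": 4.0,    # ligand N+ to ring center (threshold 6.0)
    "pi-pi": 3.6,        # ring center to ring center (threshold < 4.4)
}
_RESIDUE_FOR = {"hydrogen": "SER", "halogen": "ASP",
                "cation-pi": "PHE", "pi-pi": "PHE"}

# 3-atom default ligand: a C-C-O fragment with fixed internal geometry;
# the terminal oxygen doubles as the hydrogen-bond contact atom
DEFAULT_TEMPLATE = (
    ("C", "C", "O"),
    np.array([[0.0, 0.0, 0.0],
              [1.50, 0.0, 0.0],
              [2.25, 1.20, 0.0]]),
)


@dataclass(frozen=True)
class ToyComplexSpec:
    n_residues: int = 4
    planted: tuple[tuple[int, str], ...] = ()   # (residue slot 0-based, type)
    ligand_template: tuple | None = DEFAULT_TEMPLATE
    sigma_geom: float = 0.0                     # Å, coordinate jitter scale
    seed: int = 0

    def __post_init__(self):
        if self.sigma_geom < 0:
            raise ValueError("sigma_geom must be >= 0")
        planted = tuple((int(s), normalize_interaction_type(t))
                        for s, t in self.planted)
        object.__setattr__(self, "planted", planted)
        for slot, _ in planted:
            if not (0 <= slot < self.n_residues):
                raise ValueError(f"planted slot {slot} outside 0..{self.n_residues-1}")
        if len({s for s, _ in planted}) != len(planted):
            raise ValueError("at most one planted interaction per residue slot")


def _hexagon(center, normal, radius=1.39, phase=0.0):
    """Six points of a regular hexagon in the plane through `center`
    with unit `normal`."""
    normal = normal / np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, normal)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, a)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    ang = phase + np.arange(6) * np.pi / 3
    return center + radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))


def _residue_atoms(kind: str, slot: int, inward: np.ndarray,
                   anchor: np.ndarray, chain: str = "A"):
    """Rigid residue motif atoms; `inward` is the unit vector toward the
    pocket center, `anchor` the CA position."""
    res_idx = slot + 1

    def A(element, offset, name):
        return AtomRecord(element=element, position=tuple(anchor + offset),
                          owner="protein", residue_name=kind,
                          residue_index=res_idx, chain=chain, atom_name=name)

    if kind == "SER":       # hydroxyl donor/acceptor
        return [A("C", np.zeros(3), "CA"), A("O", 1.4 * inward, "OG")]
    if kind == "ASP":       # carboxylate acceptor
        return [A("C", np.zeros(3), "CA"), A("O", 1.4 * inward, "OD1")]
    if kind == "PHE":       # aromatic hexagon, normal pointing inward
        ring_center = anchor + 1.0 * inward
        ring = _hexagon(ring_center, inward)
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        atoms = [A("C", np.zeros(3), "CA")]
        atoms += [AtomRecord(element="C", position=tuple(p), owner="protein",
                             residue_name="PHE", residue_index=res_idx,
                             chain=chain, atom_name=nm,
                             is_aromatic_ring_member=True)
                  for p, nm in zip(ring, names)]
        return atoms
    if kind == "ALA":       # inert filler
        return [A("C", np.zeros(3), "CA"), A("C", 1.5 * inward, "CB")]
    raise ValueError(f"unknown toy residue kind {kind!r}")


def _contact_group(itype: str, slot_dir: np.ndarray, anchor: np.ndarray):
    """Ligand atoms realizing one planted interaction; returns
    (elements, coords, cation flags)."""
    inward = -slot_dir
    if itype == "hydrogen":
        p = anchor + 1.4 * inward + _CONTACT["hydrogen"] * inward
        return ["O"], np.array([p]), []
    if itype == "halogen":
        p = anchor + 1.4 * inward + _CONTACT["halogen"] * inward
        return ["Cl"], np.array([p]), []
    if itype == "cation-pi":
        ring_center = anchor + 1.0 * inward
        p = ring_center + _CONTACT["cation-pi"] * inward
        return ["N"], np.array([p]), [0]
    if itype == "pi-pi":
        ring_center = anchor + 1.0 * inward
        lig_center = ring_center + _CONTACT["pi-pi"] * inward
        ring = _hexagon(lig_center, inward, phase=np.pi / 6)
        return ["C"] * 6, ring, []
    raise ValueError(itype)


def _place_template(template, itype: str, slot_dir: np.ndarray,
                    anchor: np.ndarray):
    """Rigidly place the ligand template so its contact feature realizes
    the planted interaction (single-interaction specs only)."""
    elements, coords = template
    elements = list(elements)
    coords = np.asarray(coords, dtype=np.float64)
    inward = -slot_dir
    if itype == "pi-pi":
        if len(elements) != 6 or set(elements) != {"C"}:
            raise ValueError("pi-pi template placement needs a 6-carbon ring")
        ring_center = anchor + 1.0 * inward
        target = ring_center + _CONTACT["pi-pi"] * inward
        return elements, _hexagon(target, inward, phase=np.pi / 6), []

    want = {"hydrogen": ("O", "N"), "halogen": ("Cl", "Br", "I"),
            "cation-pi": ("N",)}[itype]
    try:
        ci = max(i for i, e in enumerate(elements) if e in want)
    except ValueError:
        raise ValueError(
            f"ligand template has no contact atom for {itype}") from None
    if itype == "cation-pi":
        target = anchor + 1.0 * inward + _CONTACT[itype] * inward
    else:
        target = anchor + 1.4 * inward + _CONTACT[itype] * inward
    # orient the template so its body points toward the pocket center and
    # the contact atom toward the residue's functional group
    centroid = coords.mean(axis=0)
    axis = coords[ci] - centroid
    rot = _rotation_between(axis, -inward)
    placed = (coords - coords[ci]) @ rot.T + target
    cations = [ci] if itype == "cation-pi" else []
    return elements, placed, cations


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking direction a to direction b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite directions: rotate pi about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, perp)
        v /= np.linalg.norm(v)
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def make_toy_complex(spec: ToyComplexSpec
                     ) -> tuple[ComplexGraph, InteractionPromptSet]:
    """Build the deterministic base complex for a spec (no jitter; use
    `make_toy_dataset` for noisy copies)."""
    planted = dict(spec.planted)
    protein: list[AtomRecord] = []
    lig_elements: list[str] = []
    lig_coords_parts: list[np.ndarray] = []
    cation_idx: set[int] = set()
    records = []

    for slot in range(spec.n_residues):
        theta = 2 * np.pi * slot / spec.n_residues
        slot_dir = np.array([np.cos(theta), np.sin(theta), 0.0])
        anchor = _SLOT_RADIUS * slot_dir
        inward = -slot_dir
        itype = planted.get(slot)
        kind = _RESIDUE_FOR[itype] if itype else "ALA"
        protein += _residue_atoms(kind, slot, inward, anchor)
        if itype is None:
            continue
        records.append(PromptRecord(residue_name=kind, residue_index=slot + 1,
                                    interaction_type=itype, chain="A"))
        if len(planted) == 1 and spec.ligand_template is not None:
            try:
                els, xyz, cats = _place_template(spec.ligand_template, itype,
                                                 slot_dir, anchor)
            except ValueError:
                # template lacks a matching contact feature: plant the
                # minimal contact group for this type instead
                els, xyz, cats = _contact_group(itype, slot_dir, anchor)
        else:
            els, xyz, cats = _contact_group(itype, slot_dir, anchor)
        base = len(lig_elements)
        lig_elements += els
        lig_coords_parts.append(xyz)
        cation_idx |= {base + c for c in cats}

    if not planted:
        els, xyz = spec.ligand_template or DEFAULT_TEMPLATE
        lig_elements = list(els)
        xyz = np.asarray(xyz, dtype=np.float64)
        lig_coords_parts = [xyz - xyz.mean(axis=0)]  # park at the center

    lig_coords = np.vstack(lig_coords_parts)
    _check_feasible(lig_coords, np.array([a.position for a in protein]))
    ligand = tuple(AtomRecord(element=e, position=tuple(p), owner="ligand")
                   for e, p in zip(lig_elements, lig_coords))
    prompts = InteractionPromptSet(tuple(records))
    graph = ComplexGraph(ligand=ligand, protein=tuple(protein),
                         prompt_set=prompts)
    graph = annotate_complex(graph, ligand_cations=cation_idx)
    return graph, prompts


def _check_feasible(lig: np.ndarray, prot: np.ndarray, min_dist: float = 0.8):
    """Reject specs whose ligand atoms overlap each other or the pocket."""
    n_l = len(lig)
    pts = np.vstack([lig, prot]) if len(prot) else lig
    for i in range(n_l):
        for j in range(i + 1, len(pts)):
            d = float(np.linalg.norm(pts[i] - pts[j]))
            if d < min_dist:
                raise ValueError(
                    f"geometrically infeasible spec: atoms {i},{j} overlap "
                    f"at {d:.2f} Å")


def make_toy_dataset(spec: ToyComplexSpec, n_samples: int, seed: int | None = None
                     ) -> list[tuple[ComplexGraph, InteractionPromptSet]]:
    """i.i.d. jittered copies of the base complex: ligand coordinates
    perturbed by N(0, sigma_geom^2) per coordinate; prompts carried over."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    base, prompts = make_toy_complex(spec)
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    out = []
    x0 = base.x_L
    for ss in root.spawn(n_samples):
        rng = np.random.default_rng(ss)
        x = x0 + spec.sigma_geom * rng.standard_normal(x0.shape)
        out.append((base.with_ligand(x, base.ligand_elements), prompts))
    return out
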