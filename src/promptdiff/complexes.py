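"""Protein–ligand complex data model.

A complex is a joint 3D point cloud: ligand block followed by protein
block, ``x = [x_L, x_P]``, ``h = [h_L, h_P]``.  Edges connect atom pairs
closer than a distance cutoff (default 7 Å, strict).  Interaction
prompts are per-residue labels — one of the four supported interaction
types — broadcast to every atom of the prompted residue as a one-hot
code; the matching learnable continuous embeddings live in the denoiser.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .diffusion import AtomVocabulary
from .nn.autodiff import Tensor, concat

__all__ = [
    "INTERACTION_TYPES",
    "normalize_interaction_type",
    "AtomRecord",
    "ComplexGraph",
    "EdgeSet",
    "PromptRecord",
    "InteractionPromptSet",
    "ChemAnnotations",
    "build_edges",
    "zero_center",
    "encode_initial_features",
    "protein_features",
]

# order fixed once; the one-hot prompt code and the classification head
# (class 0 = no interaction, classes 1..4 = this order) both follow it
INTERACTION_TYPES = ("cation-pi", "halogen", "hydrogen", "pi-pi")

_TYPE_ALIASES = {
    "cation-pi": "cation-pi", "cationpi": "cation-pi", "cation_pi": "cation-pi",
    "cation": "cation-pi", "caption": "cation-pi",  # 'caption' appears in the wild
    "halogen": "halogen",
    "hydrogen": "hydrogen", "hbond": "hydrogen", "h-bond": "hydrogen",
    "pi-pi": "pi-pi", "pipi": "pi-pi", "pi_pi": "pi-pi",
    "pi-stacking": "pi-pi", "pistacking": "pi-pi",
}


def normalize_interaction_type(name: str) -> str:
    key = name.strip().lower().replace(" ", "")
    try:
        return _TYPE_ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unknown interaction type {name!r}; expected one of {INTERACTION_TYPES}"
        ) from None


DEFAULT_CUTOFF = 7.0  # Å

PROTEIN_ELEMENTS = ("C", "N", "O", "S")
STANDARD_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class AtomRecord:
    element: str
    position: tuple[float, float, float]
    owner: str  # 'ligand' | 'protein'
    residue_name: str = ""
    residue_index: int | None = None
    chain: str = ""
    atom_name: str = ""
    is_aromatic_ring_member: bool = False

    def __post_init__(self):
        if self.owner not in ("ligand", "protein"):
            raise ValueError(f"owner must be ligand/protein, got {self.owner!r}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")
        if self.owner == "protein" and (not self.residue_name
                                        or self.residue_index is None):
            raise ValueError("protein atoms need residue_name and residue_index")
        if self.owner == "ligand" and (self.residue_name or
                                       self.residue_index is not None):
            raise ValueError("ligand atoms must not carry residue fields")


@dataclass(frozen=True)
class PromptRecord:
    residue_name: str
    residue_index: int
    interaction_type: str
    chain: str = ""

    def __post_init__(self):
        object.__setattr__(self, "interaction_type",
                           normalize_interaction_type(self.interaction_type))
        object.__setattr__(self, "residue_name", self.residue_name.upper())


@dataclass(frozen=True)
class InteractionPromptSet:
    """Per-residue interaction assignments.

    Each residue may appear at most once (complexes whose residues carry
    several interaction types are excluded upstream).  ``v_discrete``
    broadcasts the residue-level one-hot code to every atom of the
    residue; unprompted residues get an all-zero row.
    """

    records: tuple[PromptRecord, ...]

    def __post_init__(self):
        keys = [(r.chain, r.residue_index) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("a residue appears in more than one prompt record")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def type_of(self, chain: str, residue_index: int) -> str | None:
        for r in self.records:
            if r.residue_index == residue_index and (not r.chain or not chain
                                                     or r.chain == chain):
                return r.interaction_type
        return None

    def v_discrete(self, graph: "ComplexGraph") -> np.ndarray:
        """(N_P, 4) one-hot prompt rows, zero for unprompted residues."""
        out = np.zeros((len(graph.protein), len(INTERACTION_TYPES)))
        for i, a in enumerate(graph.protein):
            itype = self.type_of(a.chain, a.residue_index)
            if itype is not None:
                out[i, INTERACTION_TYPES.index(itype)] = 1.0
        return out

    def validate_against(self, graph: "ComplexGraph"):
        residues = {(a.chain, a.residue_index, a.residue_name)
                    for a in graph.protein}
        pairs = {(c, i) for c, i, _ in residues}
        for r in self.records:
            ok = any((not r.chain or c == r.chain) and i == r.residue_index
                     and n == r.residue_name for c, i, n in residues)
            if not ok:
                raise ValueError(
                    f"prompt references residue {r.residue_name}-{r.residue_index}"
                    f"{(' chain ' + r.chain) if r.chain else ''} absent from pocket"
                )
        _ = pairs


@dataclass(frozen=True)
class ChemAnnotations:
    """Chemistry needed by the geometric interaction detector.

    Indices refer to the ligand / protein atom lists of the owning
    ComplexGraph.  Rings are lists of atom-index lists (aromatic only).
    """

    ligand_donors: frozenset[int] = frozenset()
    ligand_acceptors: frozenset[int] = frozenset()
    ligand_halogens: frozenset[int] = frozenset()
    ligand_cations: frozenset[int] = frozenset()
    ligand_rings: tuple[tuple[int, ...], ...] = ()
    protein_donors: frozenset[int] = frozenset()
    protein_acceptors: frozenset[int] = frozenset()
    protein_cations: frozenset[int] = frozenset()
    protein_rings: tuple[tuple[int, ...], ...] = ()


@dataclass(frozen=True)
class EdgeSet:
    """Symmetric distance-cutoff edges with cached Euclidean distances."""

    pairs: np.ndarray        # (E, 2) directed pairs, both directions stored
    distances: np.ndarray    # (E,)
    cutoff: float
    n_atoms: int

    def neighbors(self, i: int) -> np.ndarray:
        return self.pairs[self.pairs[:, 0] == i, 1]

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n_atoms, self.n_atoms), dtype=bool)
        if len(self.pairs):
            A[self.pairs[:, 0], self.pairs[:, 1]] = True
        return A

    def __len__(self):
        return len(self.pairs)


def build_edges(coords: np.ndarray, cutoff: float = DEFAULT_CUTOFF) -> EdgeSet:
    """All atom pairs with Euclidean distance strictly below `cutoff` (Å)."""
    coords = np.asarray(coords, dtype=np.float64)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if coords.size and not np.all(np.isfinite(coords)):
        raise ValueError("coordinates contain NaN/inf")
    n = len(coords)
    if n < 2:
        return EdgeSet(pairs=np.zeros((0, 2), dtype=int),
                       distances=np.zeros(0), cutoff=cutoff, n_atoms=n)
    tree = cKDTree(coords)
    raw = tree.query_pairs(r=cutoff, output_type="ndarray")
    if len(raw):
        d = np.linalg.norm(coords[raw[:, 0]] - coords[raw[:, 1]], axis=1)
        keep = d < cutoff  # strict: 'below 7 Å'
        raw, d = raw[keep], d[keep]
    else:
        d = np.zeros(0)
    pairs = np.concatenate([raw, raw[:, ::-1]]) if len(raw) else np.zeros((0, 2), int)
    dists = np.concatenate([d, d]) if len(raw) else np.zeros(0)
    return EdgeSet(pairs=pairs, distances=dists, cutoff=cutoff, n_atoms=n)


@dataclass(frozen=True)
class ComplexGraph:
    """Protein pocket plus (possibly empty) ligand, concatenation order
    ligand-then-protein throughout."""

    ligand: tuple[AtomRecord, ...]
    protein: tuple[AtomRecord, ...]
    prompt_set: InteractionPromptSet | None = None
    chem: ChemAnnotations | None = None
    cutoff: float = DEFAULT_CUTOFF

    @property
    def n_ligand(self) -> int:
        return len(self.ligand)

    @property
    def n_protein(self) -> int:
        return len(self.protein)

    @property
    def n_atoms(self) -> int:
        return self.n_ligand + self.n_protein

    @property
    def x_L(self) -> np.ndarray:
        return np.array([a.position for a in self.ligand], dtype=np.float64).reshape(-1, 3)

    @property
    def x_P(self) -> np.ndarray:
        return np.array([a.position for a in self.protein], dtype=np.float64).reshape(-1, 3)

    @property
    def x(self) -> np.ndarray:
        return np.vstack([self.x_L, self.x_P])

    @property
    def ligand_elements(self) -> list[str]:
        return [a.element for a in self.ligand]

    def h_L(self, vocab: AtomVocabulary) -> np.ndarray:
        return vocab.one_hot(self.ligand_elements)

    def h_P(self) -> np.ndarray:
        return protein_features(self.protein)

    def edges(self) -> EdgeSet:
        return build_edges(self.x, self.cutoff)

    def with_ligand(self, coords: np.ndarray, elements: list[str]) -> "ComplexGraph":
        coords = np.asarray(coords, dtype=np.float64)
        lig = tuple(AtomRecord(element=e, position=tuple(p), owner="ligand")
                    for e, p in zip(elements, coords))
        return replace(self, ligand=lig, chem=None)

    def translated(self, v: np.ndarray) -> "ComplexGraph":
        v = np.asarray(v, dtype=np.float64)

        def mv(atoms):
            return tuple(replace(a, position=tuple(np.asarray(a.position) + v))
                         for a in atoms)

        return replace(self, ligand=mv(self.ligand), protein=mv(self.protein))

    def transformed(self, R: np.ndarray, v: np.ndarray) -> "ComplexGraph":
        """Apply the rigid motion x -> R x + v to every atom."""
        R = np.asarray(R, dtype=np.float64)
        v = np.asarray(v, dtype=np.float64)

        def mv(atoms):
            return tuple(replace(a, position=tuple(R @ np.asarray(a.position) + v))
                         for a in atoms)

        return replace(self, ligand=mv(self.ligand), protein=mv(self.protein))

    def interaction_class_labels(self) -> np.ndarray:
        """Per-protein-atom class labels for the classification head:
        0 = no prompt, 1..4 = INTERACTION_TYPES order."""
        labels = np.zeros(self.n_protein, dtype=int)
        if self.prompt_set is not None:
            for i, a in enumerate(self.protein):
                itype = self.prompt_set.type_of(a.chain, a.residue_index)
                if itype is not None:
                    labels[i] = 1 + INTERACTION_TYPES.index(itype)
        return labels


def protein_features(atoms) -> np.ndarray:
    """Raw per-atom protein features: element one-hot (+other), residue
    one-hot over the 20 standard residues (+other), backbone flag."""
    n_el = len(PROTEIN_ELEMENTS) + 1
    n_res = len(STANDARD_RESIDUES) + 1
    out = np.zeros((len(atoms), n_el + n_res + 1))
    for i, a in enumerate(atoms):
        ei = PROTEIN_ELEMENTS.index(a.element) if a.element in PROTEIN_ELEMENTS \
            else n_el - 1
        out[i, ei] = 1.0
        ri = STANDARD_RESIDUES.index(a.residue_name) \
            if a.residue_name in STANDARD_RESIDUES else n_res - 1
        out[i, n_el + ri] = 1.0
        if a.atom_name in BACKBONE_ATOMS:
            out[i, n_el + n_res] = 1.0
    return out


def zero_center(graph: ComplexGraph, mode: str = "protein") -> ComplexGraph:
    """Translate the complex so the designated center of mass is zero.

    mode: 'protein' (pocket centroid; default — the pocket is the fixed
    conditioning frame), 'ligand', or 'joint'.
    """
    if graph.n_atoms == 0:
        raise ValueError("cannot center an empty complex")
    if mode == "protein":
        sel = graph.x_P
    elif mode == "ligand":
        sel = graph.x_L
    elif mode == "joint":
        sel = graph.x
    else:
        raise ValueError(f"unknown centering mode {mode!r}")
    if len(sel) == 0:
        raise ValueError(f"centering mode {mode!r} selects no atoms")
    return graph.translated(-sel.mean(axis=0))


def encode_initial_features(h_P_raw, v_discrete, h_L_raw, embed_params):
    """Initial linear embedding of raw features.

    Protein rows consume the concatenation [h_P_raw, v_discrete]; ligand
    rows consume h_L_raw alone.  `embed_params` is a mapping with keys
    W_P, b_P, W_L, b_L (arrays or autodiff Tensors).  Output width is
    the shared hidden size.
    """
    v_discrete = np.asarray(v_discrete, dtype=np.float64)
    if v_discrete.shape[-1] != len(INTERACTION_TYPES):
        raise ValueError("v_discrete must have one column per interaction type")
    if v_discrete.shape[-2] != np.asarray(h_P_raw).shape[-2]:
        raise ValueError("v_discrete row count must equal protein atom count")

    def T_(v):
        return v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=np.float64))

    h_P = concat([T_(h_P_raw), T_(v_discrete)], axis=-1)
    h0_P = h_P @ T_(embed_params["W_P"]) + T_(embed_params["b_P"])
    h0_L = T_(h_L_raw) @ T_(embed_params["W_L"]) + T_(embed_params["b_L"])
    return h0_P, h0_L
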