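"""Generation: pocket-conditional ancestral sampling, mask-based
inpainting for fragment growing, ligand-size sampling and bond
reconstruction.

The reverse chain starts from isotropic Gaussian coordinates (in the
pocket-centered frame) and uniform atom types at ``t = T``; at every step
the denoiser's clean-sample prediction is plugged into the closed-form
posterior, from which the next state is drawn.  Protein atoms are held
fixed throughout conditional sampling.  Inpainting clamps a masked
subset of atoms to single-step noised copies of a reference at every
step and regenerates the rest with a jointly trained (protein+ligand)
denoiser.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .complexes import ComplexGraph, InteractionPromptSet
from .denoiser import Denoiser
from .diffusion import AtomVocabulary, Schedule
from .nn.autodiff import no_grad

__all__ = [
    "AtomCountModel",
    "InpaintMask",
    "ReconstructedMolecule",
    "sample_atom_count",
    "generate_ligands",
    "generate_ligand",
    "inpaint",
    "inpaint_step",
    "reconstruct_bonds",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ligand size model


@dataclass(frozen=True)
class AtomCountModel:
    """Empirical joint table over (pocket-size bin, ligand atom count).

    ``bin_edges`` partition the pocket-size statistic (number of pocket
    atoms); ``counts`` are the support of the ligand-size distribution
    and ``weights[b, i]`` the probability of ``counts[i]`` in bin ``b``
    (each row sums to 1; all-zero rows mark empty bins).
    """

    bin_edges: np.ndarray          # (n_bins+1,)
    counts: np.ndarray             # (n_counts,)
    weights: np.ndarray            # (n_bins, n_counts)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if np.any(w < 0):
            raise ValueError("atom-count weights must be nonnegative")
        sums = w.sum(axis=1)
        if not np.all(np.isclose(sums[sums > 0], 1.0)):
            raise ValueError("each nonempty bin's weights must sum to 1")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, float))
        object.__setattr__(self, "counts", np.asarray(self.counts, int))

    def bin_of(self, pocket_size: int) -> int:
        b = int(np.searchsorted(self.bin_edges, pocket_size, side="right")) - 1
        return int(np.clip(b, 0, len(self.weights) - 1))

    @staticmethod
    def default_toy() -> "AtomCountModel":
        # documented default: small pockets favor 3-8 atoms, larger 8-25
        counts = np.arange(3, 26)
        small = np.exp(-0.5 * ((counts - 6) / 2.0) ** 2)
        large = np.exp(-0.5 * ((counts - 16) / 4.0) ** 2)
        return AtomCountModel(
            bin_edges=np.array([0.0, 30.0, np.inf]),
            counts=counts,
            weights=np.stack([small / small.sum(), large / large.sum()]),
        )

    @staticmethod
    def fit(pocket_sizes, ligand_sizes, bin_edges) -> "AtomCountModel":
        """Build the table from (pocket size, ligand size) training pairs."""
        pocket_sizes = np.asarray(pocket_sizes, int)
        ligand_sizes = np.asarray(ligand_sizes, int)
        counts = np.arange(ligand_sizes.min(), ligand_sizes.max() + 1)
        edges = np.asarray(bin_edges, float)
        W = np.zeros((len(edges) - 1, len(counts)))
        for p, l in zip(pocket_sizes, ligand_sizes):
            b = int(np.clip(np.searchsorted(edges, p, side="right") - 1,
                            0, len(W) - 1))
            W[b, l - counts[0]] += 1
        sums = W.sum(axis=1, keepdims=True)
        W = np.divide(W, sums, out=np.zeros_like(W), where=sums > 0)
        return AtomCountModel(bin_edges=edges, counts=counts, weights=W)


def sample_atom_count(pocket: ComplexGraph, model: AtomCountModel,
                      rng: np.random.Generator,
                      override: int | None = None) -> int:
    """Draw a ligand atom count from the bin matching the pocket size."""
    if pocket.n_protein == 0:
        raise ValueError("pocket is empty")
    if override is not None:
        if override < 1:
            raise ValueError("atom-count override must be >= 1")
        return int(override)
    b = model.bin_of(pocket.n_protein)
    w = model.weights[b]
    if w.sum() <= 0:
        log.warning("empty atom-count bin %d; falling back to global marginal", b)
        w = model.weights.sum(axis=0)
        w = w / w.sum()
    return int(rng.choice(model.counts, p=w))


# ---------------------------------------------------------------------------
# conditional sampling


def _sample_categorical_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized one-hot draws from per-row categorical distributions."""
    p = probs / probs.sum(axis=-1, keepdims=True)
    c = np.cumsum(p, axis=-1)
    u = rng.random(p.shape[:-1] + (1,))
    k = np.minimum((u > c).sum(axis=-1), p.shape[-1] - 1)
    out = np.zeros_like(p)
    np.put_along_axis(out, k[..., None], 1.0, axis=-1)
    return out


def generate_ligands(pocket: ComplexGraph, prompts: InteractionPromptSet | None,
                     n_atoms: int, schedule: Schedule, denoiser: Denoiser,
                     rng: np.random.Generator, n_samples: int = 1,
                     final_types: str = "argmax",
                     keep_trajectory: bool = False):
    """Sample `n_samples` ligands of `n_atoms` atoms each in the pocket.

    Returns (coords (B, n_atoms, 3) in the input frame, elements list of
    lists, trajectory or None).
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    prompts = prompts if prompts is not None else InteractionPromptSet(())
    prompts.validate_against(pocket)
    vocab = denoiser.vocab
    K = vocab.K
    T = schedule.T

    center = pocket.x_P.mean(axis=0)
    x_P = (pocket.x_P - center)[None]
    h_P = pocket.h_P()[None]
    v_d = prompts.v_discrete(pocket)[None]

    B = n_samples
    x_t = rng.standard_normal((B, n_atoms, 3))
    h_t = _sample_categorical_rows(np.full((B, n_atoms, K), 1.0 / K), rng)
    traj = [] if keep_trajectory else None

    with no_grad():
        for t in range(T, 0, -1):
            out = denoiser.forward(x_t, h_t, x_P, h_P, v_d, t, T)
            x0_hat, h0_hat = out.x0_hat.data, out.h0_hat.data
            b_t = schedule.beta_at(t)
            a_t = schedule.alpha_at(t)
            ab_t = schedule.alpha_bar_at(t)
            ab_prev = schedule.alpha_bar_at(t - 1)
            mu = (np.sqrt(ab_prev) * b_t * x0_hat
                  + np.sqrt(a_t) * (1.0 - ab_prev) * x_t) / (1.0 - ab_t)
            if t > 1:
                beta_tilde = (1.0 - ab_prev) / (1.0 - ab_t) * b_t
                x_t = mu + np.sqrt(beta_tilde) * rng.standard_normal(mu.shape)
                lik = a_t * h_t + (1.0 - a_t) / K
                prior = ab_prev * h0_hat + (1.0 - ab_prev) / K
                h_t = _sample_categorical_rows(lik * prior, rng)
            else:
                x_t = mu  # beta~_1 = 0: deterministic final coordinates
                if final_types == "argmax":
                    h_t = np.zeros_like(h0_hat)
                    np.put_along_axis(h_t, np.argmax(h0_hat, axis=-1)[..., None],
                                      1.0, axis=-1)
                else:
                    h_t = _sample_categorical_rows(h0_hat, rng)
            if keep_trajectory:
                traj.append((x_t.copy(), h_t.copy()))

    coords = x_t + center
    elements = [vocab.decode(h_t[b]) for b in range(B)]
    return coords, elements, traj


def generate_ligand(pocket, prompts, n_atoms, schedule, denoiser, rng,
                    **kwargs):
    """Single-ligand convenience wrapper around `generate_ligands`."""
    coords, elements, traj = generate_ligands(
        pocket, prompts, n_atoms, schedule, denoiser, rng, n_samples=1, **kwargs)
    return coords[0], elements[0], traj


# ---------------------------------------------------------------------------
# inpainting


@dataclass(frozen=True)
class InpaintMask:
    """Binary per-atom flags over the joint complex; 1 = fixed context
    (drawn around the reference at every step), 0 = regenerated."""

    m: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.m, dtype=np.float64)
        if not np.all((m == 0.0) | (m == 1.0)):
            raise ValueError("mask entries must be 0 or 1")
        object.__setattr__(self, "m", m)

    def validate_for(self, n_atoms: int, require_free: bool = True):
        if len(self.m) != n_atoms:
            raise ValueError(f"mask length {len(self.m)} != atom count {n_atoms}")
        if require_free and np.all(self.m == 1.0):
            raise ValueError("mask is all-ones: nothing to generate")


def inpaint_step(x_t: np.ndarray, x0_ref: np.ndarray, x0_hat: np.ndarray,
                 m: np.ndarray, t: int, schedule: Schedule,
                 eps_known: np.ndarray, eps_unknown: np.ndarray) -> np.ndarray:
    """One inpainting combination step for coordinates.

    x_known  = sqrt(1-beta_t) x0_ref + sqrt(beta_t) eps_known
    x_unknown = mu~_t(x_t, x0_hat) + sqrt(beta~_t) eps_unknown
    x_{t-1}  = m ⊙ x_known + (1-m) ⊙ x_unknown
    """
    b_t = schedule.beta_at(t)
    a_t = schedule.alpha_at(t)
    ab_t = schedule.alpha_bar_at(t)
    ab_prev = schedule.alpha_bar_at(t - 1)
    x_known = np.sqrt(1.0 - b_t) * x0_ref + np.sqrt(b_t) * eps_known
    mu = (np.sqrt(ab_prev) * b_t * x0_hat
          + np.sqrt(a_t) * (1.0 - ab_prev) * x_t) / (1.0 - ab_t)
    beta_tilde = (1.0 - ab_prev) / (1.0 - ab_t) * b_t
    x_unknown = mu + np.sqrt(beta_tilde) * eps_unknown
    m = np.asarray(m, dtype=np.float64).reshape(-1, 1)
    return m * x_known + (1.0 - m) * x_unknown


def inpaint(complex0: ComplexGraph, mask: InpaintMask, schedule: Schedule,
            joint_denoiser, rng: np.random.Generator,
            final_types: str = "argmax") -> ComplexGraph:
    """Regenerate the unmasked atoms of a reference complex.

    `joint_denoiser` is a Denoiser configured with ``joint=True`` (its
    coordinate prediction covers protein and ligand atoms), or any
    callable ``(x_t, h_t, t) -> (x0_hat_all, h0_hat_ligand)`` for
    scripted testing.  The categorical stream reuses the same mask
    combination — an extension beyond the coordinate equations.
    Masked atoms equal the reference exactly at termination.
    """
    n = complex0.n_atoms
    n_L = complex0.n_ligand
    mask.validate_for(n)
    T = schedule.T

    vocab = joint_denoiser.vocab if isinstance(joint_denoiser, Denoiser) \
        else AtomVocabulary()
    K = vocab.K
    center = complex0.x_P.mean(axis=0) if complex0.n_protein else np.zeros(3)
    x0_ref = complex0.x - center
    h0_ref = complex0.h_L(vocab)
    m = mask.m
    m_L = m[:n_L]

    x_t = rng.standard_normal((n, 3))
    h_t = _sample_categorical_rows(np.full((n_L, K), 1.0 / K), rng)

    if isinstance(joint_denoiser, Denoiser):
        h_P = complex0.h_P()[None]
        v_d = np.zeros((1, complex0.n_protein, 4))

        def predict(x_t, h_t, t):
            with no_grad():
                out = joint_denoiser.forward(
                    x_t[None, :n_L], h_t[None], x_t[None, n_L:], h_P, v_d, t, T)
            return out.x0_hat.data[0], out.h0_hat.data[0]
    else:
        predict = joint_denoiser

    for t in range(T, 0, -1):
        x0_hat, h0_hat = predict(x_t, h_t, t)
        if x0_hat.shape[0] != n:
            raise ValueError("joint denoiser must predict all atoms")
        eps_known = rng.standard_normal((n, 3))
        eps_unknown = rng.standard_normal((n, 3))
        if t == 1:
            eps_unknown = np.zeros((n, 3))  # beta~_1 = 0
        x_t = inpaint_step(x_t, x0_ref, x0_hat, m, t, schedule,
                           eps_known, eps_unknown)
        # categorical stream: same mask combination (single-step kernel
        # around the reference types, mirroring the coordinate equation)
        a_t = schedule.alpha_at(t)
        ab_prev = schedule.alpha_bar_at(t - 1)
        h_known = _sample_categorical_rows(a_t * h0_ref + (1.0 - a_t) / K, rng)
        if t > 1:
            lik = a_t * h_t + (1.0 - a_t) / K
            prior = ab_prev * h0_hat + (1.0 - ab_prev) / K
            h_unknown = _sample_categorical_rows(lik * prior, rng)
        else:
            h_unknown = np.zeros_like(h0_hat)
            if final_types == "argmax":
                np.put_along_axis(h_unknown,
                                  np.argmax(h0_hat, axis=-1)[..., None],
                                  1.0, axis=-1)
            else:
                h_unknown = _sample_categorical_rows(h0_hat, rng)
        h_t = m_L[:, None] * h_known + (1.0 - m_L[:, None]) * h_unknown

    # final replacement: masked atoms equal the reference exactly (use the
    # original-frame coordinates so no centering round-off enters)
    x_final = np.where(m[:, None] == 1.0, complex0.x, x_t + center)
    h_final = np.where(m_L[:, None] == 1.0, h0_ref, h_t)
    elements = vocab.decode(h_final)
    out = complex0.with_ligand(x_final[:n_L], elements)
    # protein atoms: unmasked ones take their regenerated coordinates
    from dataclasses import replace as _replace
    prot = tuple(
        _replace(a, position=tuple(x_final[n_L + i]))
        for i, a in enumerate(complex0.protein)
    )
    return _replace(out, protein=prot)


# ---------------------------------------------------------------------------
# bond reconstruction

# single-bond covalent radii (Å), Cordero et al. consensus values
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}
BOND_TOLERANCE = 0.45  # Å over the covalent-radius sum
MAX_NEIGHBORS = {  # heavy-atom coordination caps (hydrogens implicit)
    "C": 4, "N": 4, "O": 2, "F": 1, "P": 5, "S": 6, "Cl": 1, "Br": 1, "I": 3,
}


@dataclass(frozen=True)
class ReconstructedMolecule:
    elements: tuple[str, ...]
    coords: np.ndarray
    bonds: tuple[tuple[int, int, str], ...]   # (i, j, 'single'|'aromatic')
    aromatic_rings: tuple[tuple[int, ...], ...] = ()
    is_valid: bool = False                    # passes the RDKit valency check

    def to_rdkit(self):
        from rdkit import Chem
        from rdkit.Geometry import Point3D
        mol = Chem.RWMol()
        for e in self.elements:
            mol.AddAtom(Chem.Atom(e))
        for i, j, order in self.bonds:
            bt = Chem.BondType.AROMATIC if order == "aromatic" \
                else Chem.BondType.SINGLE
            mol.AddBond(int(i), int(j), bt)
        aromatic_atoms = {a for ring in self.aromatic_rings for a in ring}
        for a in aromatic_atoms:
            mol.GetAtomWithIdx(int(a)).SetIsAromatic(True)
        conf = Chem.Conformer(len(self.elements))
        for i, p in enumerate(self.coords):
            conf.SetAtomPosition(i, Point3D(*map(float, p)))
        mol.AddConformer(conf)
        return mol


def reconstruct_bonds(coords: np.ndarray, types) -> ReconstructedMolecule:
    """Assign bonds by covalent-radius distance, cap valences, and
    perceive aromatic rings (planar 5/6-membered C/N cycles)."""
    import networkx as nx

    coords = np.asarray(coords, dtype=np.float64)
    elements = tuple(types)
    for e in elements:
        if e not in COVALENT_RADII:
            raise ValueError(f"unknown element {e!r}")
    n = len(elements)
    cand = []
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            thr = COVALENT_RADII[elements[i]] + COVALENT_RADII[elements[j]] \
                + BOND_TOLERANCE
            if d < thr:
                cand.append((d, i, j))
    cand.sort()  # keep shortest bonds when valence caps bind
    deg = np.zeros(n, dtype=int)
    bonds = []
    for d, i, j in cand:
        if deg[i] < MAX_NEIGHBORS[elements[i]] and \
                deg[j] < MAX_NEIGHBORS[elements[j]]:
            bonds.append((i, j))
            deg[i] += 1
            deg[j] += 1

    G = nx.Graph(bonds)
    G.add_nodes_from(range(n))
    rings = []
    for cyc in nx.cycle_basis(G):
        if len(cyc) not in (5, 6):
            continue
        if not all(elements[a] in ("C", "N") for a in cyc):
            continue
        pts = coords[cyc]
        centroid = pts.mean(axis=0)
        _, s, vt = np.linalg.svd(pts - centroid)
        planarity = s[2] / max(s[0], 1e-9)
        if planarity < 0.1:  # near-planar
            rings.append(tuple(sorted(cyc)))
    ring_atoms = {a for r in rings for a in r}
    bond_list = []
    for i, j in bonds:
        aromatic = any(i in r and j in r for r in rings)
        bond_list.append((i, j, "aromatic" if aromatic else "single"))

    mol = ReconstructedMolecule(elements=elements, coords=coords,
                                bonds=tuple(bond_list),
                                aromatic_rings=tuple(rings))
    valid = False
    try:
        from rdkit import Chem
        rd = mol.to_rdkit()
        Chem.SanitizeMol(rd)
        valid = True
    except Exception:
        valid = False
    object.__setattr__(mol, "is_valid", valid)
    _ = ring_atoms
    return mol
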