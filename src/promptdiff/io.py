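"""Standard-format readers/writers and the structured run configuration.

Pockets come in as PDB (waters and heteroatoms excluded; highest-
occupancy altloc kept; insertion codes preserved so such residues stay
distinct).  Ligands go in/out as SDF through RDKit.  Prompt files are
TSV or JSON records ``residue_name, residue_index, interaction_type``
(optionally a chain column), case-insensitive on the type name.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .complexes import (AtomRecord, ComplexGraph, InteractionPromptSet,
                        PromptRecord)
from .denoiser import DenoiserConfig
from .diffusion import LossWeights
from .interactions import DetectedInteraction, DetectorThresholds
from .samplers import ReconstructedMolecule

__all__ = [
    "RunConfig", "read_pocket", "write_pocket_pdb", "read_ligand",
    "write_ligand", "read_prompts", "write_prompts", "write_detections",
    "load_config", "save_config", "write_manifest",
]

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def read_pocket(path) -> ComplexGraph:
    """Parse a PDB pocket into a protein-only ComplexGraph.

    Residue names and indices are preserved verbatim for prompt
    matching; insertion codes are appended to the chain identifier so
    inserted residues remain distinct.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("pocket", str(path))
    except (PDBConstructionException, ValueError) as e:
        raise ValueError(f"unparseable PDB {path}: {e}") from e

    atoms: list[AtomRecord] = []
    model = next(structure.get_models())
    for chain in model:
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag.strip() or res.get_resname().strip() in _WATER_NAMES:
                continue  # waters / heteroatoms excluded by default
            chain_id = chain.id + (icode.strip() or "")
            for atom in res:
                if atom.is_disordered():
                    # keep the highest-occupancy conformer
                    alts = sorted(atom.disordered_get_list(),
                                  key=lambda a: a.get_occupancy() or 0.0)
                    atom = alts[-1]
                el = (atom.element or atom.get_name()[0]).strip().capitalize()
                if el == "H" or el == "D":
                    continue
                atoms.append(AtomRecord(
                    element=el, position=tuple(map(float, atom.coord)),
                    owner="protein", residue_name=res.get_resname().strip(),
                    residue_index=int(resseq), chain=chain_id,
                    atom_name=atom.get_name().strip()))
    if not atoms:
        raise ValueError(f"{path}: no protein atoms after filtering "
                         "(file may contain only waters/heteroatoms)")
    return ComplexGraph(ligand=(), protein=tuple(atoms))


def write_pocket_pdb(graph: ComplexGraph, path):
    """Write the protein part as minimal ATOM records."""
    lines = []
    for i, a in enumerate(graph.protein, start=1):
        x, y, z = a.position
        lines.append(
            f"ATOM  {i:5d} {a.atom_name:<4s} {a.residue_name:>3s} "
            f"{(a.chain or 'A')[0]}{a.residue_index:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ligand(path) -> list[tuple[list[str], np.ndarray]]:
    """Read all molecules from an SDF/MOL file as (elements, coords)."""
    from rdkit import Chem

    out = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    for mol in supplier:
        if mol is None:
            continue
        conf = mol.GetConformer()
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        coords = np.array([[conf.GetAtomPosition(i).x,
                            conf.GetAtomPosition(i).y,
                            conf.GetAtomPosition(i).z]
                           for i in range(mol.GetNumAtoms())])
        keep = [i for i, e in enumerate(elements) if e != "H"]
        out.append(([elements[i] for i in keep], coords[keep]))
    if not out:
        raise ValueError(f"no readable molecules in {path}")
    return out


def write_ligand(mols, path):
    """Write reconstructed molecules to an SDF file (1e-4 Å? SDF V2000
    stores 4 decimal places, which round-trips to that precision)."""
    from rdkit import Chem

    if isinstance(mols, ReconstructedMolecule):
        mols = [mols]
    if not mols:
        raise ValueError("refusing to write an empty molecule batch")
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for m in mols:
            if not m.elements:
                raise ValueError("empty molecule")
            rd = m.to_rdkit()
            try:
                Chem.SanitizeMol(rd)
            except Exception:
                pass  # write raw structure; validity is reported separately
            writer.write(rd)
    finally:
        writer.close()


def read_prompts(path) -> InteractionPromptSet:
    """Read a prompt file (TSV columns: residue_name, residue_index,
    interaction_type[, chain]; or a JSON list of such records/triples)."""
    path = Path(path)
    text = path.read_text()
    records: list[PromptRecord] = []
    if path.suffix.lower() == ".json":
        data = json.loads(text)
        for item in data:
            if isinstance(item, dict):
                records.append(PromptRecord(
                    residue_name=item["residue_name"],
                    residue_index=int(item["residue_index"]),
                    interaction_type=item["interaction_type"],
                    chain=item.get("chain", "")))
            else:
                name, idx, itype, *rest = item
                records.append(PromptRecord(name, int(idx), itype,
                                            rest[0] if rest else ""))
    else:
        for ln, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: need residue_name, "
                                 "residue_index, interaction_type")
            records.append(PromptRecord(
                parts[0].strip(), int(parts[1]), parts[2].strip(),
                parts[3].strip() if len(parts) > 3 else ""))
    return InteractionPromptSet(tuple(records))


def write_prompts(prompts: InteractionPromptSet, path):
    lines = ["# residue_name\tresidue_index\tinteraction_type\tchain"]
    for r in prompts:
        lines.append(f"{r.residue_name}\t{r.residue_index}\t"
                     f"{r.interaction_type}\t{r.chain}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_detections(detections: list[DetectedInteraction], path):
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps([asdict(d) for d in detections], indent=2))
        return
    lines = ["residue_name\tresidue_index\tchain\tinteraction_type\t"
             "ligand_atoms\tprotein_atoms\tgeometry"]
    for d in detections:
        lines.append(
            f"{d.residue_name}\t{d.residue_index}\t{d.chain}\t"
            f"{d.interaction_type}\t"
            f"{','.join(map(str, d.ligand_atoms))}\t"
            f"{','.join(map(str, d.protein_atoms))}\t"
            f"{json.dumps(d.geometry)}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Structured configuration for CLI runs; round-trips losslessly
    through YAML."""

    schedule: dict = field(default_factory=lambda: {"T": 1000, "kind": "sigmoid"})
    denoiser: DenoiserConfig = field(default_factory=DenoiserConfig)
    loss: LossWeights = field(default_factory=LossWeights)
    sampler: dict = field(default_factory=dict)  # atom_count_table / n_atoms
    detector: DetectorThresholds = field(default_factory=DetectorThresholds)
    seed: int = 0
    outdir: str = "runs"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["detector"]["aromatic_residues"] = list(
            d["detector"]["aromatic_residues"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "denoiser" in d and isinstance(d["denoiser"], dict):
            d["denoiser"] = DenoiserConfig(**d["denoiser"])
        if "loss" in d and isinstance(d["loss"], dict):
            d["loss"] = LossWeights(**d["loss"])
        if "detector" in d and isinstance(d["detector"], dict):
            det = dict(d["detector"])
            if "aromatic_residues" in det:
                det["aromatic_residues"] = tuple(det["aromatic_residues"])
            d["detector"] = DetectorThresholds(**det)
        return cls(**d)


def load_config(path) -> RunConfig:
    cfg = RunConfig.from_dict(yaml.safe_load(Path(path).read_text()) or {})
    table = cfg.sampler.get("atom_count_table")
    if table and not Path(table).exists():
        raise ValueError(f"atom-count table not found: {table}")
    return cfg


def save_config(cfg: RunConfig, path):
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def write_manifest(outdir, config: RunConfig | dict, seed: int, extra=None):
    """Config echo + seed + versions: enough to reproduce a run."""
    import promptdiff

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": seed,
        "config": config.to_dict() if isinstance(config, RunConfig) else config,
        "versions": {"promptdiff": promptdiff.__version__,
                     "numpy": np.__version__},
    }
    if extra:
        manifest.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
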