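# promptdiff

Interaction-prompt-guided equivariant diffusion for pocket-conditioned 3D
molecular generation.

## The problem

Structure-based generative models place ligand atoms inside a protein
pocket, but the generative process is blind to *which* residues the
chemist wants the molecule to engage.  Binding free energy is dominated
by a handful of hotspot residues, and a practical design tool should let
the user say "form a hydrogen bond with this serine, stack against that
phenylalanine" and have the generator comply.

`promptdiff` implements such a tool end to end at laboratory-toy scale:

* **Denoising diffusion over a protein–ligand point cloud.**  Ligand
  coordinates x follow a variance-preserving Gaussian chain
  q(x_t | x_{t-1}) = N(√(1−β_t) x_{t-1}, β_t I); one-hot atom types h
  follow a uniform-mixing categorical chain
  C(h_t | (1−β_t) h_{t-1} + β_t/K).  Both admit closed-form posteriors
  q(·_{t-1} | ·_t, ·_0), and the reverse chain plugs the network's clean
  predictions (x̂₀, ĥ₀) into them.
* **Interaction prompts.**  Each pocket residue can carry one of four
  interaction labels — hydrogen bond, halogen bond, cation-π, π-π — as a
  one-hot code v⁽ᵈ⁾ entering the initial feature embedding and a
  learnable continuous embedding v⁽ᶜ⁾ injected into every network block
  and into the cross-attention context.
* **An SE(3)-equivariant denoiser.**  Stacked blocks of (1) distance-
  graph feature attention, (2) coordinate updates as attention-weighted
  sums of relative vectors, and (3) ligand→protein cross-attention whose
  head split drives features (first half) and coordinates (second half).
  Features are rigid-motion invariant, coordinates equivariant — verified
  numerically to double precision.
* **Samplers.**  Pocket-conditional ancestral sampling, ligand-size
  sampling from an empirical (pocket size × ligand size) table, and
  mask-based inpainting for fragment growing:
  x_{t-1} = m ⊙ x_{t-1}^known + (1−m) ⊙ x_{t-1}^unknown with the known
  part drawn around the reference scaffold at every step.
* **A geometric interaction detector** with the π-π criteria
  (ring-center distance < 4.4 Å, per-ring planarity deviation ≤ 15°,
  inter-normal angle ≤ 30°) and declared-default hydrogen / halogen /
  cation-π thresholds, plus the **prompt accuracy** metric: the fraction
  of prompted (residue, type) pairs realized in a generated molecule.
* **Synthetic fixtures**: deterministic toy pockets with planted
  interaction geometries so training, sampling, detection and evaluation
  run offline in seconds.

The network and trainer run on a small reverse-mode automatic-
differentiation engine over numpy arrays (`promptdiff.nn`), validated
against finite differences.

## Worked example

Train a tiny model on a planted hydrogen-bond complex, then generate:

```python
import numpy as np
from promptdiff import (ComplexGraph, InteractionPromptSet,
                        parameter_recovery_experiment)

result = parameter_recovery_experiment(seed=1)
print(result)
```

Output from an actual run:

```
ParameterRecoveryResult(mean_pairwise_distance_error=0.1165,
                        prompted_hbond_rate=0.97,
                        unprompted_hbond_rate=0.0,
                        final_loss=0.5549, n_generated=100)
```

Generated ligands reproduce the 3-atom template's internal geometry to
0.12 Å mean pairwise-distance error, and 97/100 prompted samples realize
the planted hydrogen bond versus 0/100 unprompted — the prompt embedding
demonstrably steers generation.

The prompt-accuracy metric itself: if `[GLU, 14, hydrogen]` and
`[TYR, 39, cation-π]` are prompted and only the cation-π is detected in
a generated conformer, accuracy is 50%:

```python
from promptdiff import InteractionPromptSet, PromptRecord, prompt_accuracy
prompted = InteractionPromptSet((PromptRecord("GLU", 14, "Hydrogen"),
                                 PromptRecord("TYR", 39, "cation")))
prompt_accuracy(prompted, detected)   # -> 0.5
```

## Command line

```bash
promptdiff make-fixtures --out fx --interaction hydrogen
promptdiff detect --pocket fx/pocket.pdb --ligand fx/ligand.sdf
promptdiff evaluate --pocket fx/pocket.pdb --prompts fx/prompts.tsv \
                    --ligands fx/ligand.sdf
promptdiff train --config cfg.yaml --out net.npz
promptdiff sample --pocket fx/pocket.pdb --prompts fx/prompts.tsv \
                  --checkpoint net.npz --config cfg.yaml --out gen.sdf
promptdiff inpaint --pocket fx/pocket.pdb --ligand fx/ligand.sdf \
                   --keep 0,1 --checkpoint joint.npz --config cfg.yaml \
                   --out grown.sdf
```

Exit codes: 0 success, 2 validation failure, 1 runtime error.  Every run
writes a `manifest.json` (config echo + seed + versions).

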