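# Methods

## Model

A protein–ligand complex is a joint 3D point cloud
M = (x, h) with x = [x⁽ᴸ⁾, x⁽ᴾ⁾] ∈ ℝ^{N×3} (Å) and per-atom features
h = [h⁽ᴸ⁾, h⁽ᴾ⁾].  Ligand features are one-hot element codes over the
vocabulary {C, N, O, F, P, S, Cl, Br, I} (K = 9, hydrogens implicit);
protein features are element one-hot (+other), residue one-hot over the
20 standard residues (+other) and a backbone flag.

### Forward (noising) process

Over T steps (default T = 1000) ligand coordinates follow the
variance-preserving Gaussian chain

  q(x_t | x_{t−1}) = N(x_t | √(1−β_t) x_{t−1}, β_t I),

with marginal N(√ᾱ_t x₀, (1−ᾱ_t) I), ᾱ_t = Π_{s≤t}(1−β_s).  Ligand
types follow the uniform-mixing categorical chain
C(h_t | (1−β_t) h_{t−1} + β_t/K) with marginal
C(ᾱ_t h₀ + (1−ᾱ_t)/K).  Protein atoms are conditioning context and are
never noised in the pocket-conditional model.

Both chains have closed-form single-step posteriors given the clean
sample: the Gaussian (μ̃_t, β̃_t) with

  μ̃_t = [√ᾱ_{t−1} β_t x₀ + √α_t (1−ᾱ_{t−1}) x_t] / (1−ᾱ_t),
  β̃_t = (1−ᾱ_{t−1})/(1−ᾱ_t) · β_t,

and the categorical θ_post ∝ [α_t h_t + (1−α_t)/K] ⊙
[ᾱ_{t−1} h₀ + (1−ᾱ_{t−1})/K].  We define ᾱ₀ := 1, so β̃₁ = 0 and the
final reverse step is deterministic.  Unit tests verify θ_post against
brute-force Bayes enumeration (≤ 1e−10 for K ≤ 5, T ≤ 10) and the
marginal against composed single-step kernels by Monte Carlo.

### Noise schedule

The functional form of β_t is a free design choice; the default is a
sigmoid ramp from β_min = 1e−7 to β_max = 2e−2 over T steps (slow noise
injection early, consistent with point-cloud diffusion practice), with
`linear`, `cosine` and `explicit` selectable in configuration so the
choice is auditable.  The per-step coordinate-loss weights are γ_t = 1
for all t; a configurable vector is retained for experimentation.  The
toy experiments use T = 100 with β ∈ [1e−5, 0.1], chosen so ᾱ_T ≈ 0.01
(the terminal state is essentially pure noise at that depth too).

### Interaction prompts

Prompts are per-residue labels from {cation-π, halogen, hydrogen, π-π}
(this order fixes the one-hot layout).  Each residue may carry at most
one label; complexes violating this are rejected outright during prompt
extraction rather than silently pruned.  A residue-level prompt is
broadcast to every atom of the residue.  Two encodings act in parallel:

* v⁽ᵈ⁾ ∈ {0,1}⁴ one-hot rows (all-zero for unprompted residues),
  concatenated with the raw protein features before the initial linear
  embedding;
* v⁽ᶜ⁾: four learnable embedding vectors (one per type, shared across
  residues and blocks).  Per-atom continuous prompts are computed as
  v⁽ᵈ⁾ · V⁽ᶜ⁾, so unprompted atoms receive exactly zero — the neutral
  element.  v⁽ᶜ⁾ is re-added at the start of every block's feature
  module (the block equations place it inside the block) and enters the
  cross-attention context of every block.

### Denoiser

Φ predicts (x̂₀, ĥ₀) from (x_t, h_t, t).  Default six blocks (two in
the toy experiments); each block runs three modules in order:

1. **Feature update.**  Messages m_ij = cat(d_ij, h_i, h_j) over the
   distance graph (edge iff d_ij < 7 Å, strict); keys/values are MLPs of
   m_ij, queries an MLP of h_i; multi-head attention is normalized per
   node over its neighborhood, and a node with no neighbors receives a
   zero update (residual passthrough).  Features see coordinates only
   through d_ij, hence rigid-motion invariance.
2. **Coordinate update.**  The same message machinery produces per-head
   scalar gates; the update is Σ_j a_ij g_ij (x_i − x_j) averaged over
   heads, applied to ligand rows only (all rows in the joint variant).
   Weighted sums of relative vectors are rotation-equivariant and
   translation-invariant by construction.
3. **Cross-attention.**  Ligand atoms attend to all protein atoms (no
   cutoff — the long-range pathway).  Context cxt = cat(h⁽ᴾ⁾, v⁽ᶜ⁾);
   similarity is an MLP of cat(per-head query·key, d̃_ij) where d̃_ij is
   a Gaussian radial-basis expansion (default 32 centers on 0–10 Å)
   followed by an MLP.  With nheads heads (must be even; there is no
   principled tie-break for an odd split), the first half of the
   softmax heads aggregates context values into a feature update and
   the second half is averaged into per-pair weights on the
   ligand−protein relative vectors for a coordinate update, normalized
   by the number of protein atoms for scale stability.  A configuration
   flag disables this module entirely (ablation variant); the ablated
   network contains no distance-encoding parameters at all.

Time conditioning appends t/T to the raw features before the initial
linear embedding.  The predicted x̂₀ is the final ligand coordinate
block; ĥ₀ is a softmax head over the final ligand features; a
classification head reads the final protein features and predicts the
per-atom interaction class (none + four types) — the last block's
features are the natural input since they feed no further block.  The
distance graph is rebuilt after every block from the updated
coordinates (configurable), since ligand atoms move.

The SE(3) identities (coordinates equivariant, features/logits
invariant under joint rigid motions; permutation equivariance over
atoms) hold to ~1e−15 in double precision; the test suite enforces
1e−8 over 20 random transforms.

### Training

L = λ_x L^x + λ_h L^h + λ_c Cls, with L^x = γ_t ⟨‖x₀−x̂₀‖²⟩ (squared
norm per atom, averaged over atoms), L^h the KL divergence between
θ_post(h_t, h₀) and θ_post(h_t, ĥ₀) averaged over atoms, and Cls the
cross-entropy of the protein interaction-class logits.  Default
λ = (1, 1, 1).  Minibatch Adam; one uniform random t is shared per
minibatch (a standard simplification — per-sample t would require
per-sample schedule scalars in the loss).

The network and trainer run on a compact reverse-mode autodiff engine
over float64 numpy arrays written for this package (`promptdiff.nn`):
tape-based, broadcasting-aware, with batched matmul and a masked
softmax.  Gradients are validated against central finite differences in
the unit tests.  Zero-initialized output gates on the coordinate
pathways mean those gates' upstream layers receive zero gradient at the
very first step; after one optimizer step gradients flow to every
parameter group, which the suite checks explicitly.

### Sampling

Conditional generation centers the frame on the pocket centroid (the
"subspace trick": fixing the center of mass removes the translational
degree of freedom; the pocket is the natural anchor because it stays
fixed across denoising steps — ligand-only and joint centering are
selectable).  Ligand size is drawn from an empirical joint table over
(pocket-size bin, ligand atom count); the pocket-size statistic is the
number of pocket atoms, the table ships as a documented toy default
plus a fitting routine, and an explicit user override wins.  The chain
starts from N(0, I) coordinates and uniform types at t = T and samples
the closed-form posteriors with (x̂₀, ĥ₀) substituted.  At t = 1 the
coordinate draw is deterministic (β̃₁ = 0) and the final types are the
argmax of ĥ₀ (a final categorical draw is selectable).  Identical
seeds give bit-identical output.

### Inpainting (fragment growing)

A joint variant of the model (coordinate updates and coordinate loss
cover protein atoms as well) supports mask-based scaffold completion:
per step, x_{t−1}^known ~ N(√(1−β_t) x₀, β_t I) around the reference,
x_{t−1}^unknown ~ N(μ̃_θ(x_t), β̃_t I) from the model, combined as
m ⊙ known + (1−m) ⊙ unknown; at termination masked atoms are set to the
reference exactly.  The printed equations cover coordinates only; this
implementation applies the same mask combination to the categorical
type stream, which is an extension beyond those equations and is flagged
as such.  The joint variant here diffuses all coordinates but keeps
protein *types* as clean conditioning features; predicting protein
element identities adds nothing to the fragment-growing use case.

### Bond reconstruction

Bonds are post-processed from geometry: a bond where the interatomic
distance is below the covalent-radius sum plus 0.45 Å (Cordero
consensus radii), shortest-first under per-element coordination caps;
5/6-membered near-planar C/N cycles are perceived as aromatic; the
result converts to RDKit and an SDF, and a validity flag records
whether the molecule passes the RDKit valency check.

## Interaction detector

All geometry lives in one threshold block:

| type | criterion | default | convention |
|---|---|---|---|
| π-π | ring-center distance | < 4.4 Å | strict (printed) |
| π-π | per-ring planarity deviation | ≤ 15° | printed bound |
| π-π | inter-normal angle | ≤ 30° | printed bound, folded to [0°, 90°] |
| hydrogen | donor–acceptor heavy-atom distance | ≤ 4.0 Å | declared default |
| halogen | ligand Cl/Br/I to protein acceptor | ≤ 4.0 Å | declared default |
| cation-π | charged-group center to ring center | ≤ 6.0 Å | declared default |

Planarity deviation of a ring atom is the angle between the
centroid→atom vector and the SVD-fitted ring plane.  Hydrogen/halogen/
cation-π defaults follow common interaction-fingerprinting practice and
are isolated as constants precisely so they can be calibrated against
any external tool version; the printed π-π numbers are asserted in
tests at ±0.05 Å / ±1° around each boundary.  Aromatic residues are
{PHE, TYR, TRP} with HIS configurable.  Residues match prompts by
(name, index), plus chain when both sides carry one.

**Prompt accuracy** = |prompted records matched by a detection with the
same residue and type| / |prompted|.  Extra detections neither help nor
hurt; an empty prompted set is rejected (the metric is undefined, and
evaluation excludes complexes with no detected interaction).

## Synthetic fixtures

Toy pockets place rigid residue motifs on a circle (radius 8 Å) with
functional groups pointing inward: SER (hydroxyl donor/acceptor), ASP
(carboxylate acceptor), PHE (aromatic hexagon, ring normal inward), ALA
(inert filler).  Planted contact geometries — ligand O at 2.9 Å from
the serine oxygen, Cl at 3.2 Å from the aspartate oxygen, N⁺ at 4.0 Å
on the ring axis, stacked hexagon at 3.6 Å — satisfy every threshold
with ≥ 0.2 Å / 3° margin while staying far enough from the other slots
that zero-noise detection recovers exactly the planted prompt set
(plant-and-recover closure, tested for all four types).  Datasets are
i.i.d. ligand-coordinate jitters N(0, σ²); all randomness flows from
one seed through `numpy.random.SeedSequence` spawning.

What the toys do **not** emulate: full amino-acid sterics, protonation
states, realistic ligand chemistry and flexibility, crystal-structure
noise, or the size and diversity of real docking datasets.  Passing
tests therefore demonstrate the correctness of the machinery — the
diffusion algebra, equivariance, prompt plumbing, detection geometry —
and a genuine prompted-vs-unprompted behavioral contrast at toy scale,
not generative quality on real targets.

## Parameter-recovery experiment

A 2-block, width-32, 2-head denoiser with T = 100 trains for 1200 Adam
steps (batch 16, lr 2e−3, ≈ 1 minute on one CPU) on 500 jittered copies
(σ = 0.1 Å) of the 3-atom C–C–O template: half in the hydrogen-bond
pose with the prompt, half parked at the pocket center without it.
Then 100 ligands are generated in each prompt condition.  Reported:
the mean absolute error between sorted generated and template pairwise
distances (sorting gives a permutation-invariant comparison of the
3-distance multiset), and the fraction of samples whose detected
interactions realize the planted hydrogen-bond prompt.  Typical values:
≈ 0.12 Å error, ≈ 97–100% prompted rate versus 0% unprompted.  The
test suite asserts the 3-seed median error < 0.3 Å and the directional
prompt effect.  These problem sizes (500 training samples, 1200 steps,
100 generations) are the package's chosen toy-scale study conditions.

## Numerical choices and degenerate inputs

* Pairwise distances add 1e−12 inside the square root to keep the
  diagonal differentiable; self-pairs are masked out of attention.
* Masked softmax subtracts a stop-gradient row max; rows with no valid
  entry yield exactly zero attention (residual passthrough).
* KL terms add 1e−30 to both arguments before the log ratio, so
  identical distributions give exactly zero.
* Edges use strict `<` at the 7 Å cutoff ("below"); printed detector
  thresholds are strict, declared defaults inclusive.
* Fewer than two atoms → empty edge set (valid); NaN coordinates,
  empty centering selections, all-ones inpaint masks, t = 0 posteriors
  and empty prompt sets in the accuracy metric are rejected with
  messages.
* PDB reading keeps the highest-occupancy altloc, skips waters,
  heteroatoms and hydrogens, and appends insertion codes to the chain
  identifier so inserted residues stay distinct.

## Known limitations

* The denoiser backend is a purpose-built numpy autodiff engine: ideal
  for the toy scales exercised here, not for training on real docking
  datasets (no GPU, no kernel fusion).
* Ligand charged groups cannot be inferred from elements and geometry
  alone; cation annotations are explicit (quaternary nitrogens are
  flagged automatically).
* Bond reconstruction is purely geometric; bond orders beyond
  aromatic/single are not assigned, so the validity flag is
  conservative.
* One shared t per training minibatch; the classification head reads
  only the final block.
* The hydrogen-bond criterion omits the donor-angle term unless
  explicit hydrogens are present (they are implicit throughout the toy
  data).
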