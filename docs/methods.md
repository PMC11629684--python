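# Methods

`plbind` predicts protein–ligand binding affinity (−log Kd/Ki) from three
protein modalities — a sampled molecular surface, the pocket's 3D residue
structure, and the full amino-acid sequence — fused by cross-attention and
combined with a ligand-graph embedding and a bipartite contact-graph
embedding. This note records the model, its assumptions, the defaults that
matter, and the choices made where the design was genuinely open.

## Surface modality

The surface is a mesh-free oriented point cloud generated on the fly from
the atomic coordinates. We use the smooth (softmin) distance field

    f(x) = −σ · log Σ_k exp(−‖x − a_k‖ / σ),      σ = 1.05 Å,

whose level set at 1.05 Å approximates the solvent-accessible envelope.
Points are initialized around atoms, projected onto the level set by ten
gradient-descent steps (step 0.5), trimmed to a ±0.05 Å band, filtered by a
visibility heuristic that discards interior-facing points, and thinned on a
voxel grid to ≈1 point/Å². Normals are the normalized field gradient and
point outward because the field increases away from the atoms. All free
constants of the construction are pinned here because the cited sampling
procedure leaves them open.

The *pocket* is the K = 512 surface points nearest the ligand centroid
(256/1024 variants are one config flag; ties resolve to the lower index).
Per-point features:

* **Chemical** — the 16 nearest atom centers contribute (atom-type one-hot ⊕
  inverse distance, capped at 2 Å⁻¹) through a shared 3-layer MLP,
  sum-pooled. The atom-type vocabulary has 22 elements (the six basic
  protein elements, common halogens/metals, and a catch-all); a reduced
  6-type variant {H, C, N, O, P, S} is config-selectable.
* **Geometric** — mean and Gaussian curvature at scales {1, 2, 5, 10} Å from
  a ridge-regularized quadric fit in the tangent plane, using the Monge-patch
  formulas. The ridge penalty weights (1, ½, 1) on the quadratic
  coefficients equal the Frobenius norm of the second-fundamental-form
  matrix, and the ridge scale is built from the rotation-invariant quantity
  u² + v², so H and K are independent of the arbitrary in-plane tangent
  basis even for degenerate neighborhoods (rank-deficient unregularized fits
  are *not* basis-stable; this bit us and is covered by tests).
  Neighborhoods with fewer than 5 points yield zero curvature with a logged
  warning.

Embedding uses three quasi-geodesic convolutions with the normal-corrected
distance d(x_i, x_j) = ‖x_i − x_j‖ · (2 − ⟨n_i, n_j⟩) under a Gaussian
window exp(−d²/2r²) truncated at 2r (r = 9 Å). Every input is a distance,
a normal dot product, or an atom type, so the scalar embedding is invariant
to rigid motions by construction; the tests demand ≤1e-4 relative drift
under 20 random rotations+translations in double precision.

## Structure modality

Pocket residues (any atom within 8 Å of any ligand atom) form a graph with
k = 16 nearest neighbors by Cα distance, edges directed both ways. Node
scalars: residue one-hot and φ/ψ/ω sines/cosines; node vectors: forward and
backward Cα orientations and the side-chain (CB) direction; edge scalars: 16
Gaussian RBFs of Cα distance on [0, 20] Å; edge vectors: the unit
displacement. This is the standard geometric-vector-perceptron (GVP)
protein featurization; the source method leaves the featurization open and
cites the GVP encoder, so we adopt its conventions.

Messages are computed by exactly three GVP layers on the concatenated
node-and-edge tuple, and nodes update by

    h_v(i) ← LayerNorm( h_v(i) + (1/k′) · Dropout( Σ_j m_ij ) ),

with k′ the in-degree. Scalar channels use an affine LayerNorm; vector
channels are rescaled by the RMS of their norms (no learned parameters),
which preserves equivariance. Dropout multiplies the summed message before
the 1/k′ scaling, following the printed order of operations. With dropout
off the update is exactly LayerNorm(h + mean of messages), which the tests
verify against an independent closed-form evaluation.

One genuinely open point is whether the structure modality should cover the
whole chain rather than the pocket; we follow the pocket-only reading
(the visualization analysis labels the structure embedding as the pocket's)
and the pocket radius is a config key.

## Sequence modality

The full sequence represents the protein's global context. The embedding
backend is pluggable and frozen: backend weights never join training, only
the linear adapter into the shared width does. The default backend is a
deterministic hash-seeded per-residue lookup with a ±2-residue moving
average — it exists so that the entire pipeline (including the frozen
contract) is testable without downloading a pretrained language model. A
pretrained transformer backend (per-residue hidden states, width 1024)
plugs into the same interface when its weights are available. Sequences
longer than 1000 residues are embedded in overlapping chunks (overlap 50)
whose overlaps are averaged. Unknown characters map to X with a warning.

The fallback embedder captures residue identity and a little local context;
it carries no evolutionary or long-range information, so passing tests show
the plumbing and the frozen contract are correct, not that sequence features
rival a language model on real proteins.

## Fusion

Surface tokens pass through a transformer encoder (self-attention); two
decoder stacks then align structure tokens and sequence tokens against the
encoded surface (queries = structure/sequence, keys/values = surface).
Decoders are separate per modality by default (`fusion.share_decoders`
shares them). Surface and structure tokens carry no positional encoding —
a point set and a residue set have no canonical order the attention should
exploit — while sequence tokens receive sinusoidal positions. Each modality
is average-pooled and concatenated (surface, structure, sequence) into a
width-3d embedding; the surface block pools the *encoder* output, since the
decoders do not modify surface tokens. Defaults: d = 128, 4 heads, 2
encoder and 2 decoder blocks (reduced in the CPU protocols below).

## Ligand and interaction

The ligand is a heavy-atom 2D graph (element, degree, formal charge,
aromaticity, hybridization per atom; bond type, conjugation, ring flag per
bond) encoded attentive-fingerprint style: three neighbor-attention rounds
with GRU updates, then two attentive readout rounds against a molecule
super-node. Attention weights are exposed for inspection and every
neighborhood distribution sums to one.

The interaction embedding comes from the bipartite contact graph
G = (V_l, V_p, E): an edge joins a ligand atom and a protein atom exactly
when their distance is strictly below c = 5 Å; there are never intra-set
edges. V_p defaults to the atoms of the pocket residues (config flag for
all atoms) to keep the graph bounded and pocket-centric. Two rounds of
cross-edge message passing (per-node mean aggregation, so duplicate edge
listings are harmless) feed per-edge embeddings (endpoint states ⊕ 16 RBFs
of distance on [0, 5] Å), which are pooled over edges — mean by default,
sum as an option — and mapped by an MLP. Zero-edge graphs return a learned
null embedding.

The final head is an MLP over [fused protein ⊕ ligand ⊕ interaction],
trained with mean-squared error and Adam; model selection is best
validation RMSE with early stopping. Evaluation reports RMSE, MAE, Pearson
R, and SD = √(Σ(y − (a + bŷ))²/(N−2)) with (a, b) the least-squares fit of
y on ŷ — the affine-invariant regression standard deviation conventional
in affinity benchmarking (the source leaves SD undefined; this is the only
definition consistent with SD < RMSE in published comparisons).

## Numerical and engineering choices

All tensors are float64 on a small in-package reverse-mode autodiff engine
(`plbind.nn`), which keeps the invariance and algebra tests meaningful at
1e-5–1e-12 tolerances; gradients are verified against finite differences.
Softmax and segment-softmax detach their max-shift (gradient-exact). All
k-nearest selections break ties toward the lower index; exact distance ties
are therefore not stable under rigid motion (rotation changes which of two
exactly tied candidates rounds lower), which only matters for perfectly
symmetric synthetic geometry and is handled in tests by a 0.02 Å jitter.
Every stochastic step — sampling, initialization, dropout, shuffling,
label noise — takes an explicit seed, and runs are bit-reproducible on one
platform.

## Synthetic complexes and what they show

The generator builds a helix mini-protein (rise 1.5 Å, radius 2.3 Å,
100°/residue; N/CA/C/O plus a CB pseudo-atom at 2.4 Å) with a uniformly
random sequence, and a random-tree small molecule (bond length 1.5 Å,
internal atoms carbon, leaves C/N/O) placed ~4 Å off the side-chain shell
with ±2 Å jitter, ligand size 5–12 atoms. Labels follow

    y = 2 + α · (#contacts < 5 Å) / 10 + ε,   ε ~ N(0, σ²),  α = 1, σ = 0.2,

which keeps labels in the 2–12 range of −log Kd data and makes the
interaction pathway the learnable signal. These complexes exercise every
module precondition and the full file-format path (PDB + SDF + index), but
they are not physically realistic: no secondary-structure diversity, no
chemistry in the affinity law, no conformational strain. Passing the
protocols below shows the architecture can extract a contact-driven signal
end to end — not that it reaches benchmark accuracy on real data.

## Reference protocols and problem sizes

Two protocols run at reduced width so they complete in minutes on one CPU
core (pocket K = 64, d = 32, ligand width 32, 1 encoder/decoder block,
2 GVP layers, structure dropout 0, lr 2e-3 with ×0.99 per-epoch decay —
constant-rate Adam occasionally ends a long memorization run mid-recovery
from a late loss spike — batch 8):

* **Memorization** — 20 complexes, 300 epochs, no validation: the trained
  model's MSE over the training set (eval mode) must fall below 0.05.
* **Recovery** — 200 training complexes (the last 20 used only for early
  stopping, patience 8, ≤40 epochs), 50 held-out test complexes from an
  independent seed stream: held-out Pearson R ≥ 0.8 and RMSE ≤ 0.5
  (label noise alone bounds RMSE from below at ≈0.2).

These runs set `interaction.pooling = "sum"`: the synthetic label is linear
in the contact *count*, which mean pooling removes by construction. The
library default remains mean pooling.

## Known limitations

* The fallback sequence backend is a stand-in for a pretrained language
  model in capability, though not in interface; real-data accuracy claims
  would require the pretrained backend.
* Surface sampling density is approximate (voxel thinning), and curvature
  at coarse scales saturates on small synthetic proteins.
* The whole-chain structure variant and MOL2 ligands are supported but not
  exercised by the reference protocols.
* Training is single-process CPU; no minibatch vectorization across
  complexes (graphs are processed one complex at a time).
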