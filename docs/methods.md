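# Methods

This note documents the model, the surrogate chemistry inputs, the numerical
choices, and what the desk-scale experiments do and do not demonstrate.

## Model

SMG-BERT encodes a molecule as three fused information channels:

**1D — token sequences.** RDKit parses each SMILES into its heavy-atom graph;
atoms are re-ordered to canonical-SMILES order so the same structure always
produces the same sequence. Each atom contributes an atom token (element
symbol, optionally split into `C`/`C@`/`C@@` variants at tetrahedral
stereocenters) and an NMR token (its chemical shift, discretized into 1-ppm
bins over [−50, 300) ppm). A global node `<G>` is prepended; its final
representation is the molecule-level embedding. The two sequences are embedded
by independent tables of width d_model/2 and concatenated:
`z = E_A(S_A') ∥ E_N(S_N')`. There are no positional encodings — atom order
within a molecule is arbitrary — which makes the encoder permutation
equivariant over atoms and permutation invariant at the global node, a
property the test suite asserts directly.

**2D — bond-energy channel.** A per-molecule bond-energy matrix `B` (kJ/mol,
zero off-bond) is min-max normalized **over bonded entries only** to `Bnorm`;
normalizing over the full matrix would pin `Bmin` to the structural zeros and
destroy the contrast between bond types. `M = Binary(B)` is the adjacency
mask, with the diagonal and the global row/column set to 1 (every token may
attend to itself; the molecule token attends everywhere).

**3D — distance channel.** A single relaxed conformer (seeded ETKDG distance
geometry + MMFF relaxation; the lowest-energy conformer found stands in for
the ground state) yields the raw distance matrix `Draw` (Å). One transformer
encoder layer turns it into the distance fraction matrix `D`: each entry
`d_ij` is featurized with 16 radial basis functions (channel 0 is the raw
distance), each column's features are mean-pooled into a token summary,
contextualized by the transformer layer, and a pairwise additive readout
reassembles a square score matrix. This construction is exactly permutation
equivariant — a dense projection over the atom-indexed profile axis would not
be — and setting the readout weight on the raw-distance channel to one (rest
zero) reproduces `Draw` identically, which the tests exploit as an
identity-initialization check. `D` is computed once per molecule and shared
across layers and heads.

**Modified attention**, per head in each of the 6 encoder layers:

    A   = softmax(Q Kᵀ / √d_k)        (over valid positions)
    A2d = A ⊙ M + λ·Bnorm             (λ = 0.2)
    A3d = A2d + D
    out = A3d · V

`A3d` is deliberately not re-normalized: the element-wise mask and the
additive biases produce raw scores (zero wherever the mask removes a pair),
and the recorded `A3d` is what the interpretability module exports. Multi-head
attention (8 heads by default) broadcasts `M`, `Bnorm`, `D` across heads;
`n_heads = 1` recovers the single-head algebra literally.

## Self-supervised objectives

Both token sequences are corrupted independently, BERT-style: 20 % of
non-global positions are selected (at least one), of which 80 % become `<M>`,
10 % a different random valid token and 10 % stay unchanged. The literal
whole-sequence corruption reading (80 % of *all* tokens masked) is reachable
with `select_rate = 1.0`.

* `L_A`, `L_N` — mean cross-entropy of a 2-layer MLP head at the corrupted
  positions (all corrupted positions, including "keep", by default; the
  masked-only reading is a config switch).
* `L_B` — mean squared error of a 2-layer head on `r_i ∥ r_j`, symmetrized
  over the two orderings, against the normalized bond energies, over bonded
  pairs only (bond energy is undefined for non-bonds; the printed
  all-pairs double sum would be dominated by structural zeros).
* `L_3D` — `r' = W_r r` maps each atom representation to a virtual 3-vector;
  predicted distances (all pairs), bond angles (bonded paths i–j–k) and
  unsigned torsions (bonded paths i–j–k–l) are compared to the conformer's
  values by per-family mean squared error (units Å², rad², rad², summed). The
  predictions are computed by the *same* geometry kernels that build the
  ground truth, so the two cannot drift apart. Angles use
  `atan2(‖u×v‖, u·v)` about the central atom — the translation-invariant
  reading of the printed formula. Torsions use `arccos` of the bond-plane
  normals (unsigned, hence mirror-invariant); a signed variant is available
  behind `signed_torsions`.

All family losses are means, not sums, so the total is invariant to batch and
molecule size; raw sums are available behind `mean_losses=False`.

The total is uncertainty-weighted with learnable per-task scales,

    L = L_A/σ₁² + L_N/σ₂² + L_B/σ₃² + L_3D/σ₄² + Σ log σ_k ,

σ parameterized as log σ (positivity), initialized at σ = 1. For fixed
component losses the stationary point is σ_k² = 2 L_k, which the tests verify
against the implemented gradient.

## Surrogate chemistry inputs

The NMR shifts and bond energies are deterministic environment-keyed lookup
tables packaged with the module, not physical predictions: the architecture
needs consistent, chemically discriminating per-atom and per-bond values, and
a reproducible closed form provides them without any external model.

* `nmr_environments.csv` — key = element plus the sorted multiset of
  (bond-order, neighbor-element) descriptors at radius 1. Each element owns a
  disjoint shift band (mirroring how different nuclei resonate on entirely
  different scales); the environment modulates the position inside the band.
  The table enumerates every valence-consistent radius-1 environment over the
  fixture generator's element/bond space plus aromatic-ring environments, so
  lookups never miss for generated fixtures; unknown environments fall back
  to the element's band midpoint.
* `bde_table.csv` — key = (element pair, bond order), values are
  literature-typical mean bond dissociation energies (kJ/mol); unknown keys
  fall back to a per-order default.

Externally predicted values can be injected per molecule through the
`overrides` arguments (and the corresponding CSV schemas), taking precedence
over the tables.

## Synthetic fixtures

`generate_fixtures(n, seed)` draws distinct molecules (2–16 heavy atoms) from
valence-respecting random acyclic trees over {C, N, O, S, F, Cl, Br} (single
bonds plus occasional C=O) and mono-/di-substituted benzenes; with
`include_chiral_pairs` it adds `C[C@H](X)Y` / `C[C@@H](X)Y` enantiomer pairs.
The regression label is a documented closed form of composition,
`y = Σ_e w_e·count_e − 0.5·(aromatic atoms) + N(0, 0.1)`, with weights
`C 1.0, N 2.5, O 3.0, F 1.5, Cl 2.0, Br 2.2, S 2.8` — learnable from token
content alone, so fine-tuning is testable without external data.

What the fixtures do **not** emulate: realistic property–structure
relationships (the label ignores geometry), conformational flexibility
(single conformer), ring diversity (two scaffold classes, so scaffold
splitting often falls back to random for fixture tables), tautomers, charged
species, and realistic NMR/BDE values. Passing the desk-scale experiments
therefore demonstrates that the architecture and losses are implemented
correctly and can learn, not that the model would reach benchmark-grade
accuracy on real data — that would require a large pre-training corpus and
trained NMR/BDE predictors.

Enantiomer conformers are generated enantiomer-consistently: the
lexicographically smaller canonical SMILES of the (molecule, mirror) pair is
embedded and reflected for the other enantiomer, so mirror pairs have exactly
equal interatomic distance multisets and opposite signed torsions, as mirror
symmetry dictates. This makes the representational fact behind chiral
discrimination directly testable: with distance matrices and unsigned
torsions only, enantiomers are provably indistinguishable; chiral atom tokens
(or signed torsions) are required to break the degeneracy. Both are options;
neither is claimed to be what the original work used.

## Numerical and training choices

* **Autodiff core.** The network runs on a compact in-package reverse-mode
  autodiff over float64 NumPy arrays (`smgbert.autodiff`), with exactly the
  primitives a transformer plus the geometry losses need. Every primitive is
  gradient-checked against central differences in the test suite.
* **Pre-norm residuals.** Layer normalization is applied before each
  sub-layer, with a final LayerNorm after the stack. Post-norm placement is
  available (`pre_norm=False`) and is used in the oracle tests that follow
  the printed equations, but at desk-scale step budgets post-norm 6-layer
  stacks underfit severely; pre-norm trains reliably.
* **Near-zero distance-bias init.** The `D` readout starts at ~0: raw
  distances are O(1–10) while the masked softmax term has row sums ≤ 1, and a
  full-scale `D` at initialization swamps attention and collapses token
  representations. Training grows the 3D bias from an unbiased start; the
  characteristic self-scores-near-zero pattern of a 3D-informed attention map
  emerges from a trained, not initial, `D`.
* **Optimizer.** Adam (lr 2e-3, 100-step linear warmup) for network weights;
  the four log σ scalars get a faster Adam (25× lr) so task balancing reaches
  its stationary point within short schedules. Gradient-norm clipping is
  implemented but off by default — at these scales it throttles learning.
* **Degenerate inputs.** Collinear bond angles evaluate to exactly π via
  atan2; torsion quads with zero-norm plane normals are skipped (targets) or
  masked out (predictions) with a log message; a degenerate bond-energy range
  maps all bonded entries to 1; molecules with no bonds/angles/torsions
  contribute zero to the corresponding loss families; `arccos` inputs are
  clamped to [−1, 1] and its gradient guarded near ±1.
* **Determinism.** One integer seed fixes parameter init, conformer
  embedding (per-molecule seeds derived from the master seed and the
  canonical SMILES), corruption, batch order and dropout; re-running
  reproduces the loss trajectory bit-for-bit on the same machine.

## Desk-scale experiment sizes

The packaged experiments are sized for a single CPU: pre-training uses 64
fixture molecules, d_model = 64 (all other architecture constants at their
full-scale defaults: 6 layers, 8 heads, dropout 0.1, λ = 0.2), batch 4, 100 epochs
(~1 min); the fine-tuning task uses 500 fixtures with a 2-layer head on the
`<G>` representation and the pre-training loss retained as a regularizer
(weight 0.1, the package's choice); the channel-ablation comparison uses 300
fixtures, 40 pre-training epochs, 8 fine-tuning epochs and 5 seeds per
variant. `d_model = 512` remains the default for real use.

Ablation semantics: `no_3d` zeroes `D` *and* drops `L_3D` (otherwise 3D
information would leak through supervision); `no_chem` replaces NMR tokens
with a constant token, `Bnorm` with the plain adjacency `M`, and drops `L_N`
and `L_B`.

## Known limitations

* The fixture label is nearly linear in composition, so fine-tuning from a
  random encoder can approach the pre-trained model's accuracy on it; the
  robust pre-training signals at desk scale are the total-loss decrease and
  held-out masked-token accuracy above the majority baseline. Comparisons on
  this task between trained variants have substantial run-to-run spread.
* Surrogate NMR/BDE values are reproducible stand-ins, not predictions;
  interpretability maps reflect the surrogate chemistry.
* `r' = W_r r` is a linear projection, so `L_3D` cannot reach zero for most
  molecules; it is a shaping signal, not a coordinate predictor.
* Scaffold splitting is only as meaningful as the scaffold diversity of the
  input; fixture tables often contain fewer than three scaffold groups, in
  which case the documented random fallback fires.
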