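# Methods

## Problem setting

Fixed-backbone sequence design is treated as independent per-residue
classification. The backbone of a protein — N, Cα, C, O; side chains are
removed at parse time — is the only input; the model's job is to predict,
for every residue position, a distribution over the 20 canonical amino
acids compatible with the local geometry. Positions are predicted
independently: there is no autoregressive coupling, so an *n*-residue
protein always yields an *n*×20 row-stochastic matrix.

## Structure ingestion

PDB input is parsed with gemmi. Conventions, chosen where the format leaves
room and applied deterministically:

- MODEL 1 only; altloc '' or 'A' only; waters, hetero groups, hydrogens and
  side-chain atoms dropped.
- Residues missing any of N, Cα, C are skipped and counted; so are residues
  whose N–Cα (outside 1.2–1.8 Å) or Cα–C (outside 1.3–1.8 Å) bond is
  implausible, unless `force=True`.
- MSE maps to M; other non-canonical residues are skipped with a warning.
- In-memory residue indices are 0-based and dense per chain; author
  numbering and insertion codes are kept as metadata.

## Canonical frames and voxelisation

Every residue defines a local orthonormal frame: Cα at the origin, the unit
vector Cα→N along +X, C in the XY plane with positive Y, +Z the
right-handed normal of the N–Cα–C plane. The specific in-plane convention
is arbitrary; what matters — and what the tests pin down — is that
canonical coordinates are invariant to rigid motions of the input, which
makes the frame tensors and hence the predictions rotation/translation
invariant (verified to 1e-6 on tensors, 1e-4 through the network).

A cube of edge `frame_edge_length` (default 12 Å) centred on the target Cα
is discretised into `voxels_per_side` (default 21, enforced odd so Cα sits
in the exact centre voxel) cells per edge; voxel (i,j,k) has its centre at
((i,j,k) − (V−1)/2)·Δ with Δ = edge/V. An atom belongs to the cube when
every canonical coordinate satisfies |x| ≤ edge/2. Gaussian rendering uses
exp(−d²/2σ²) with σ = r_vdW/2 (C 1.70 Å, N 1.55, O 1.52), truncated at
d > 2σ, accumulated additively with no normalisation — peak 1 at the atom
centre, compact support, deterministic. Occupancy mode instead sets the
single nearest voxel to 1 (collisions saturate at 1).

The **virtual Cβ** is rebuilt for every residue (glycine included) from
N/Cα/C using the standard linear combination of the local bond vectors and
their cross product, rescaled to exactly 1.522 Å. Because it is a pure
function of backbone geometry it gives the network a side-chain direction
cue without leaking the native identity. Channel layouts: `CNO` merges all
carbons into one channel; `CNOCB` separates the virtual Cβ; `CNOCBCA`
(default) also separates Cα.

**Property channels.** Polarity uses the Zimmerman scale with threshold 20
(< 20 ⇒ non-polar −1, else polar +1; under this published scale only
D, E, H, K, R are polar — the rule is implemented as stated, not
"corrected"; a value of exactly 20 counts as polar). Charge is D,E → −1;
K,R,H → +1; others 0 (histidine grouped with the basic residues). The
value is written into the voxel nearest each residue's Cα in one extra
channel. At design time a per-residue constraint vector overrides the
sequence-derived values — the "fix sites" workflow; overriding one site
changes exactly one voxel.

## Dataset and balanced undersampling

Frames persist to HDF5 (float32 tensors, uint8 labels with 255 for
non-canonical residues, string metadata, the voxel config as a JSON
attribute). Splits are assigned at **structure** granularity so overlapping
frames of one protein never straddle train/validation/test.

Balanced epoch plans cap every class at the smallest nonzero class count in
the split. Classes above the cap contribute a fresh uniform subset drawn
without replacement from their **full** pool each epoch; the random stream
is keyed by (seed, epoch), so plans are reproducible, differ between
epochs, and over a run the union of consumed frames grows well beyond one
epoch's cap. Redrawing from the full pool (rather than only from the
previously discarded frames) keeps the epoch size fixed and maximises
coverage; the two readings are equivalent in distribution over a run.

## Architectures and training

No deep-learning framework is used: `voxdesign.nn` is a compact
channels-last numpy engine (3D convolution via precomputed im2col index
tables, ELU, spatial dropout, max/global-average pooling, dense, Adam)
with hand-written backward passes, verified against central finite
differences to ~1e-8 relative error. Everything is deterministic under a
seed, which the reproducibility contracts rely on.

- `timed`: per block, two k×k×k convolutions (ELU) followed by spatial
  dropout (default rate 0.1) that drops whole channels; after the blocks a
  1×1×1 convolution to 20 channels and global average pooling produce the
  logits. There is deliberately no dense layer: the network-in-network
  head preserves the spatial meaning of the final feature maps. Default
  blocks 32/64/128.
- `prodconn_like`: valid-padded conv blocks, flatten, dense hidden
  layer(s), dense 20-way output — the classic flatten-dense head.
- `densenet3d`: one densely connected block (each conv sees the
  concatenation of all earlier maps, growth rate 8 by default) with the
  same 1×1×1 + GAP head.
- The registry is open: `register_architecture` adds new builders.

`conv_padding` ('same' default) is exposed on the spec because of a
practical finding: with a GAP head over a mostly-empty grid, tiny models
suffer logit dilution — the class evidence at a few occupied voxels is
averaged over hundreds of empty ones and 'same'-padded small models
plateau. 'valid' padding lets the maps shrink toward the frame centre
before pooling; the desk-scale test models use it.

Training: unweighted 20-class cross-entropy (balancing lives in the
sampler, not the loss), Adam at 1e-3, batch 64, 50 epochs by default.
With `balance=True` each epoch consumes a balanced plan; the history
records per-epoch loss, the class histogram of consumed frames, and
validation macro-recall. Validation macro-recall is computed on the full
validation split: macro-recall is already class-balanced, so undersampling
the metric set would only add variance.

## Sampling

The temperature transform is `softmax(z/T)` with `z = log p`. Feeding
log-probabilities (rather than the probabilities themselves) is the
interpretive choice that makes all three stated limits exact: T=1 returns
the input row identically, T=0 degenerates to argmax (lowest index wins
ties), T→∞ tends to uniform over the row's support, and zero-probability
classes stay at exactly zero. Sequences are drawn position-independently
from the tempered rows with numpy's PCG64 generator, consumed
sequence-by-sequence then position-by-position, so a (matrix, config) pair
always yields the same list.

## Metrics

- Macro-Recall averages per-class recall over classes **present in the
  reference**; the formula's denominator is undefined for references
  missing classes, so absent classes are excluded (a `strict` flag divides
  by 20 instead). A constant predictor against a reference containing all
  20 classes scores exactly 5%.
- Prediction bias: 100 × (predicted − true count)/total per class; signed,
  sums to zero.
- Net charge: Henderson–Hasselbalch over termini and D, E, C, Y, H, K, R
  with the EMBOSS pKa set; pI by bisection on pH ∈ [0, 14] to |charge| <
  1e-4 (the charge is strictly decreasing in pH, so bisection is exact).
- Entropy: Shannon, base 2, 0·log 0 = 0; cap log₂20 ≈ 4.32 bits.
- RMSD: Kabsch (SVD with proper-rotation correction) over Cα pairs in
  sequential 1:1 correspondence — compared structures are same-length by
  construction, so no structural alignment is needed. RMSD₁₀₀ =
  RMSD/(1 + ln √(n/100)).
- Packing density: count of backbone atoms (N, Cα, C, O of all residues;
  virtual Cβ excluded) within 7 Å of each residue's Cα, own atoms
  included; choices recorded in the report metadata.

## Synthetic fixtures

Backbones grow from internal coordinates (N–Cα 1.458 Å, Cα–C 1.525, C–N
1.329; angles 111.2°/116.2°/121.7°) by natural-extension frame placement;
the carbonyl O sits in the peptide plane trans to the next N. Ideal
generators: helix (φ,ψ) = (−57°,−47°), strand (−135°,135°), coil
(−75°,65°) — a polyproline-II-like region chosen to be clearly outside
both other torsion classes. Measured torsions round-trip the specification
to 1e-3 degrees; consecutive Cα–Cα distances are 3.80 ± 0.05 Å for trans
peptides; the helix rise is 1.5 ± 0.1 Å.

The labelled task assigns each residue a letter by torsion class (helix→A,
strand→V, coil→G), draws segment classes at 60/30/10 (deliberately skewed
so balancing has work to do), segment lengths uniform 6–12, and jitters
all coordinates with σ = 0.05 Å Gaussian noise. Labels are therefore a
deterministic, learnable function of frame geometry — a 1-NN classifier on
flattened frames solves the task outright, which the tests use as an
independent learnability oracle.

**What this does and does not show.** The synthetic task validates the
machinery: voxelisation geometry, invariances, the training loop, the
balancing contract, and that the CNN can extract a geometric signal. It
does not emulate real structure data: there are no side-chain-driven
correlations, no irreducible backbone→sequence ambiguity, no resolution
artefacts, and the label alphabet is effectively 3 letters. Test accuracy
here says nothing quantitative about sequence recovery on real proteins.

A consequence worth recording: because the synthetic labels are
deterministic, balanced and unbalanced training both converge to
(near-)zero prediction bias — the frequency-bias phenomenon needs residual
uncertainty to express itself. It is therefore measured where it is real:
in paired under-trained runs at a fixed seed, evaluated on a
class-balanced subset, the unbalanced arm predicts the majority class
strictly more often than its balanced twin; and at convergence the
balanced arm's bias magnitude never exceeds the unbalanced arm's. The
strict magnitude inequality at convergence is deliberately not asserted —
on this generator it would compare 0 with 0.

## Problem sizes

Desk-scale defaults used by the tests and the acceptance script: frames of
9³ voxels over a 12 Å cube (Δ ≈ 1.33 Å), a 600-frame dataset (20
structures × 30 residues, 60/20/20 structure-level splits), and a
two-conv-block `timed` model (8/16 filters, valid padding, ~13.6k
parameters) trained 15 epochs at batch 32 — about 5 s per training run.
The published-default 21³×5 frame geometry is exercised directly for
voxelisation and shape checks; only training uses the reduced grid.

## Known limitations

- The CNN engine is CPU-bound numpy; it is built for correctness and
  determinism at desk scale, not for training on large structure corpora.
- Layer counts and filter sizes of the named architectures are
  configurable defaults, not replicas of any published weight set;
  benchmark-scale sequence-recovery numbers are out of scope.
- No structural alignment: RMSD assumes equal-length, order-corresponded
  backbones.
- mmCIF, assemblies, hydrogens and rotamers are not handled.
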