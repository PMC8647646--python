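# Methods

## Problem and model

`hanppis` predicts, for every residue of a protein, whether it is a
protein–protein interaction (PPI) site — a residue whose solvent-accessible
surface changes on complex formation. The predictor is purely
sequence-derived: it consumes six per-residue feature blocks (one-hot
identity, PSI-BLAST PSSM log-odds, 8-state DSSP secondary structure plus an
availability flag, Kyte–Doolittle hydropathy, relative sequence position,
and a 1024-d protein-language-model embedding) and classifies each residue
from a sliding window of its sequence neighbourhood.

The classifier is a two-level hierarchical attention network, the document
→ sentence → word hierarchy transplanted to windows → K-mers → residues:

1. **Fusion.** The embedding block is projected to P = 50 dimensions by a
   trainable rectified affine layer, then spliced with the other five
   blocks into a fused vector of width 20+20+9+1+1+P = 101.
2. **Residue level.** Each K-mer of the window (non-overlapping chunks of
   k = 3) is encoded by a bidirectional GRU (u = 86 units per direction);
   a context-vector attention layer
   (s_t = tanh(W_a h_t + b_a)ᵀ u_ctx, α = softmax(s), v = Σ α_t h_t)
   pools the residue states into one K-mer vector.
3. **K-mer level.** A second Bi-GRU + attention pools the K-mer vectors
   into a window vector.
4. **Output.** A 2-unit softmax yields p(non-site), p(site); calls use a
   0.5 threshold by default.

Training minimises class-weighted cross-entropy,
−(1/n) Σ c_i [y_i log p_i + (1−y_i) log(1−p_i)] with c_i = 7 for positive
residues (countering the ≈1:5.5 site:non-site imbalance), using Adam
(α = 10⁻³, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸) at batch size 3.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `window` | 7 | sliding-window length (odd); the local context presented per residue |
| `kmer` | 3 | K-mer chunk size; 7/3 gives chunks of 3,3,1 with the target residue inside the central K-mer |
| `max_len` | 500 | proteins truncated beyond this; bounds sample counts and the position-feature denominator |
| `hidden` | 86 | GRU units per direction, both levels |
| `attention` | 86 | attention-layer width, both levels |
| `projection` | 50 | embedding-projection width; fused width = 51 + P |
| `pos_weight` | 7.0 | positive-class loss weight |
| `batch_size` | 3 | Adam mini-batch |
| `epochs` | 10 | chosen so that the separable synthetic benchmark converges well inside it; real data may need more |
| `val_fraction` | 0.1 | protein-level carve-out of the train partition used only for best-epoch selection; the test partition is never used for model selection |
| `threshold` | 0.5 | p(site) binarisation cut-off; every confusion-matrix metric depends on it |

The learning rate, Adam moments, epoch budget, initialisation (seeded
Glorot-uniform, zero biases) and the 0.5 threshold are this package's own
defaults; they are exposed in `TrainConfig`.

## Numerical and design choices

- **Gradients.** The network runs on a small reverse-mode autodiff tape
  over numpy (`hanppis.autodiff`), float64 throughout. Analytic gradients
  are verified against central finite differences (step 10⁻⁵, the
  truncation/round-off optimum at this precision) to relative error
  < 10⁻⁴ on a reduced network, across multiple seeds.
- **Padding.** Windows overhanging a sequence end are zero-filled with an
  explicit mask. The GRU copies its state through masked steps, and
  attention assigns masked positions *exactly* zero weight (the masked
  softmax zeroes them rather than relying on −∞ score arithmetic); a
  fully padded K-mer receives zero K-mer-level weight and an all-zero
  residue distribution.
- **PSSM squashing.** Raw log-odds are mapped through the logistic
  1/(1+e^(−x)) so network inputs are bounded in (0,1); a `raw=True`
  parse mode keeps the integers.
- **Hydropathy.** The Kyte–Doolittle scale, the field's standard choice;
  pluggable via the `scale` argument.
- **Unknown residues** (X, B, Z, U, O): zero one-hot, hydropathy 0; they
  still carry PSSM/SS/embedding rows. DSSP blank (coil) maps to the
  "other" secondary-structure slot; residues absent from the DSSP file
  get an all-zero SS block with the availability flag down.
- **Recurrent cell.** GRU only. (An LSTM option was considered and
  dropped: the architecture is attention-dominated and a second untested
  cell type adds surface without value.)
- **Loss clipping.** Probabilities are clipped to [10⁻⁷, 1−10⁻⁷] to keep
  the log-loss finite; gradients are zero in the clipped region.
- **Zero-denominator metrics** report 0 with a warning (precision with no
  positive calls, recall with no positives).
- **Ablation** removes a feature block from the fused vector entirely
  (input width shrinks; dropping the embedding also removes the
  projection layer) and retrains under the identical seed. A restored
  block reproduces baseline metrics bit-for-bit.
- **Best-epoch selection** uses a 10% protein-level validation carve-out
  of the train partition (validation F1); with `val_fraction=0` the
  lowest train loss is kept instead.

## The synthetic data generator

Real benchmark corpora require PSI-BLAST against NR, DSSP on solved
structures, and a pre-trained embedding model, none of which are desk
reproducible. The generator (`hanppis.synthetic`) emulates the structure
those data have:

- proteins of 50–500 residues, uniform background composition;
- a short motif planted at seeded non-overlapping positions, the residue
  at the motif's centre index (⌊(m−1)/2⌋) labeled positive — labels
  depend only on local context, the assumption window-based
  classification rests on;
- per-protein plant counts targeting a 1:5.5 negative:positive ratio
  (realised ratio verified within 20%);
- surrogate features: PSSM log-odds ±2 around the one-hot identity (plus
  optional Gaussian noise σ), categorical secondary structure with
  globular-protein state frequencies, hash-seeded embeddings in [−1,1];
  all written in the exact PSI-BLAST/DSSP/TSV dialects the parsers read
  (the ASCII PSSM dialect stores integers, so file round trips are exact
  at σ = 0).

The **default motif is "KD"** (labeled at 'K'). With w = 7 and k = 3 the
positive window carries the motif at positions 3–4, entirely inside the
central K-mer, so the label depends only on that K-mer — the premise of
the motif-recovery check below. A 3-mer motif labeled at its centre would
straddle the left and central K-mers, and the network then legitimately
parks its attention on the left chunk; the 3-mer "KDY" remains available
as a config option and in the labeling-rule tests.

What the generator does **not** emulate: evolutionary profile structure
(real PSSMs encode conservation, not identity), structurally consistent
secondary structure, sequence homology between proteins, or long-range
label determinants. A model that passes the synthetic benchmarks is
demonstrated to be *trainable, calibrated and attention-interpretable on
window-determined labels* — not to reach any particular accuracy on real
interface data.

## Problem sizes used in the checks

The learnability benchmark trains the default configuration on 200
noise-free proteins of length 50 (10,000 residue samples, 80/20 protein
split) and asks for test F1 ≥ 0.8 plus central-K-mer attention dominance;
it converges within the default 10 epochs. Unit and property tests use
reduced widths (u ≈ 6, E ≈ 12) since every architectural contract is
size-free; the gradient oracle runs at u = 3, P = 2, E = 5 where finite
differences are cheap.

## Known limitations

- Training is single-threaded numpy; at the published scale (hundreds of
  proteins up to 500 residues) a full run is hours, not minutes. The
  architecture is faithful but not performance-competitive with a GPU
  implementation.
- The published headline numbers (F1 0.393 etc.) are properties of the
  real benchmark corpora and real features; this package checks their
  internal arithmetic consistency and reproduces the *qualitative*
  claims (learnability, central-attention pattern) on synthetic data.
- One forward pass per residue (no cross-window batching of overlapping
  computation); inference is O(L · w) GRU steps per protein.
- The attention interpretation is correlational: weight concentration on
  the motif K-mer demonstrates recoverability on planted signals, not a
  causal attribution method.
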