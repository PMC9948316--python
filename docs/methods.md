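# Methods

## The task

Structural fingerprints (MACCS keys, Avalon, atom-pair, path-based,
topological-torsion and circular/Morgan fingerprints) are lossy set
representations of a molecular graph.  `fp2mol` treats the inverse problem
— recovering the molecule from its fingerprint — as sequence-to-sequence
translation: the on-bit indices (hashed fingerprints) or raw feature
identifiers (sparse fingerprints) of a molecule form the source
"sentence", and a transformer encoder–decoder is trained to emit the
molecule's SMILES string (or a robust bracket-token string) token by
token.  Reconstructions are scored by Tanimoto similarity
`Tc(A, B) = |A ∩ B| / |A ∪ B|` between prediction and ground-truth feature
sets; *Tanimoto exactness* is the percentage of predictions with `Tc = 1`
under a chosen metric fingerprint.

## Featurizers

Thirteen featurizers are registered, all computed with RDKit, with binary
variants hashed to 2048 bits except MACCS (166 keys) and Avalon (512
bits):

| name | family | size | parameters |
|---|---|---|---|
| MACCS | predefined substructures | 166 | — |
| Avalon | paths and feature classes | 512 | — |
| HashAP | hashed atom pairs | 2048 | minLength 1, maxLength 6 |
| RDK4 | path-based, branched subgraphs | 2048 | minPath 2, maxPath 4 |
| RDK4-L | path-based, linear only | 2048 | minPath 2, maxPath 4 |
| TT | topological torsions | sparse | 4-atom paths |
| HashTT | hashed torsions | 2048 | 4-atom paths |
| AEs | circular atom environments | sparse | radius 1 |
| ECFP0/ECFP2/ECFP4 | circular, hashed | 2048 | radius 0 / 1 / 2 |
| FCFP2/FCFP4 | circular, pharmacophoric invariants | 2048 | radius 1 / 2 |

Everything is presence-only (set semantics); counts are discarded.
Similarity metrics additionally include `ECFP2*`/`ECFP4*`, the unhashed
(explicit-bit) sparse variants of the radius-1/2 circular fingerprints,
for 15 metric fingerprints in total.  The primary metric of the pipeline
is the sparse radius-1 circular fingerprint (`AEs`).  Two RDKit details
are worth noting: the MACCS bit vector RDKit produces is 167 long with
bit 0 unused, so on-bit indices are shifted down by one into `[0, 166)`;
and sparse fingerprints are rendered as decimal feature-ID strings sorted
numerically, whereas hashed fingerprints use index order.

## The robust bracket-token representation

No SELFIES codec is available in the dependency set, so the package
implements its own robust molecular string language
(`fp2mol.robust`) following the same design idea: every unit is a
bracketed token, and *any* sequence of alphabet tokens decodes to a valid
molecule.  Decoding is valence-capped (each element carries its lowest
common valence: C4, N3, O2, S2, P3, halogens 1), bond orders are clipped
to the remaining valence of both partners, unmatched branch tokens are
forgiven, impossible ring closures are ignored, and a saturated
attachment point re-roots growth at the most recent atom with spare
valence.  Because decoding never requests an illegal valence, RDKit
sanitization cannot fail, which gives the representation its
zero-invalidity guarantee.

Encoding mirrors the molecule's canonical Kekulé SMILES layout
(atom-by-atom, branch tokens for parentheses, `[RingN]` tokens for ring
closures at atom distance N).  Tetrahedral parity and double-bond
direction are order-sensitive, so the encoder verifies the round trip and
searches sign-flips of the stereo tokens (up to 2^10 variants) until the
decoded canonical SMILES matches the input; molecules outside the
restricted alphabet (charges, isotopes, exotic elements, hypervalent S/P)
are rejected with an error.  The corpus generator only admits molecules
that round-trip, so both representations are always available for every
record.

## Synthetic corpus

The generator emulates a large drug-like training corpus at desk scale.
Molecules are produced by sampling random token strings in the robust
alphabet (carbon-weighted, occasional double/triple bonds, branch and
small-ring tokens) and decoding them — decoding is total, so every sample
is valid by construction.  Records are filtered to a heavy-atom cap
(default 50, inclusive), de-duplicated by canonical isomeric SMILES
(first occurrence wins), and stereo-enriched molecule by molecule:
records without stereo annotations have their unassigned stereocenters
enumerated and one randomly chosen isomer substituted until the target
stereo fraction (default 0.30) is met.  With the default token-length
range (8–40) the corpus has a mean of roughly 17 heavy atoms — small
organic molecules.  What the generator does *not* emulate: realistic
functional-group statistics, ring-system distributions, charged species
and synthesizability.  Passing tests therefore demonstrate the
correctness and trainability of the pipeline, not chemistry-space
coverage comparable to a curated database.

A diversity-selection operation mirrors corpus extension by atom-type
coverage: candidates are added greedily by the number of new radius-0
circular features (atom types) they contribute, ties broken by input
order, stopping when a budget is reached or no candidate adds coverage.

## Model and training

The translator is a standard pre-layer-norm transformer encoder–decoder
(defaults: 6 layers, 8 heads, d_model 512, d_ff 2048, dropout 0.1,
sinusoidal positional encoding on both sides, final layer norms after
both stacks, untied embeddings scaled by sqrt(d_model)).  It runs on a
small reverse-mode autodiff engine over NumPy float32 arrays written for
this package; evaluation-mode forwards are deterministic and
cross-attention probabilities can be captured for attribution.

Training minimizes mean per-token negative log-likelihood with padding
excluded, using Adam and a cyclic decayed learning-rate schedule: within
each cycle (default 25,000 steps) the rate ramps linearly from the floor
(3.9e-12) to the peak (1e-3) over the warm-up (5,000 steps), then decays
geometrically so it reaches the floor exactly at the cycle end, and the
cycle repeats with an unchanged per-cycle maximum.  The geometric
(log-linear) decay shape is chosen so the published endpoint values are
met exactly; the per-cycle maximum is held constant because the schedule
"rises to its maximum again" after each cycle.  Batches are sized by
token count (default 8,000): pairs are bucketed by source length and
packed greedily so `(max source len + max target len) × pairs` stays
within budget, and batch order is reshuffled each epoch from the run
seed.  Label smoothing is off.  Checkpoints (single `.npz` archive with
the config JSON and a config hash validated on load) are written every
25,000 steps by default.

## Decoding and evaluation

Top-1 predictions come from beam search (default beam 5, length cap 256,
no length normalization; beam 1 is exactly greedy argmax, and a
vectorized batched greedy decoder is provided whose outputs are
guaranteed to match per-item decoding — padding never changes results).
A hypothesis that fails to terminate within the cap is returned truncated
and flagged invalid.

Evaluation implements:

* **Tanimoto exactness** under any of the 15 metric fingerprints
  (`Tc = 1` is tested by exact feature-set equality, not float
  comparison); invalid predictions count in the denominator only.
* **Accuracy breakdown** by first matching rule: invalid → not exact
  (primary metric) → string exact (raw equality) → non-canonical (equal
  stereo-preserving canonical forms) → stereo (equal stereo-stripped
  canonical forms) → others (residual: symmetry/enumeration artifacts).
  The four exact categories partition the Tc-exact total by
  construction.  Mean Tc assigns 0 to invalid predictions.
* **Fingerprint-bias matrix**: one row per model, Tanimoto exactness
  under each of the 15 metrics.
* **Significance thresholds**: the empirical (1−p) quantile of Tc over
  seeded random molecule pairs (no self-pairs), i.e. the similarity
  exceeded by at most a fraction p of random pairs.  The empirical
  quantile is used instead of parametric CDF fits because desk-scale
  samples make parametric fitting unstable.
* **Stereo-error profile**: stereo-category records are partitioned into
  reversed / missing / spurious / mixed by comparing CIP and double-bond
  descriptors keyed by canonical ranks of the stereo-stripped form.  For
  highly symmetric molecules the rank-based atom mapping can be
  ambiguous; such records land in `mixed`.

For the robust representation, a token sequence that places no atoms
decodes to the *empty* molecule: it is still a valid decode (the
zero-invalidity property is semantic, not statistical) but can never be
Tc-exact against a non-empty ground truth.

## Attribution

Integrated gradients attribute the teacher-forced log-probability of each
predicted token to the source feature-token embeddings along a straight
path from a baseline, using the right-Riemann sum with m steps (default
64).  The baseline is the padding-token embedding — the natural "absent
feature" for a set-valued input.  Each row satisfies the completeness
identity (row sum ≈ F_t(x) − F_t(baseline)); the residual shrinks as m
grows.  Attention maps expose the decoder's cross-attention, by default
the final layer averaged over heads, so rows sum to 1.  Which layer/head
aggregation is most faithful is left configurable.

## Desk-scale experiment sizing

`fp2mol.experiments.run_desk_experiment` reproduces the whole pipeline at
a size a single CPU completes in minutes: 2,000 generated molecules, 100
held out; AEs → SMILES pairs; a reduced transformer (2 layers, 4 heads,
d_model 128, d_ff 256, dropout 0 — memorization needs no regularization);
token budget 2,000 per batch; up to 3,000 steps with the schedule shape
preserved but scaled (warm-up 300, cycle 1,500, peak 1e-3) and early
stopping once the tracked 200-pair subset is reproduced string-exactly at
≥ 95%.  The model trains on a 600-pair
slice of the corpus while the memorization bar is measured on the tracked
200-pair subset — training on more pairs than the subset is what makes
held-out generalization possible at all at this scale.  Held-out
reconstructions are decoded greedily (at this model size, beam search
without length normalization favours short hypotheses and hurts exact
reconstruction, although it raises validity) and scored by Tanimoto
exactness under the primary metric against a shuffled-pairing baseline
(the same predictions scored against a seeded derangement of the held-out
ground truths).

## Numerical choices and limitations

* float32 throughout the network; Tanimoto and quantiles in float64.
* Softmax/log-softmax use max-subtraction; attention masking is additive
  (−1e9 on padding and future positions).
* Greedy/beam ties broken by lowest token index (argsort order);
  significance quantile uses the sorted-index convention
  `values[int((1−p)·n)]`, so p = 1 returns the sample minimum.
* The decoder never emits pad or begin-of-sequence tokens.
* Vocabularies are corpus-derived (frequency then lexicographic order)
  with pad/bos/eos/unk reserved at indices 0–3; unseen feature IDs at
  inference map to unk.
* The transformer is CPU-bound NumPy: desk-scale only.  No multi-GPU
  data parallelism, no alternative schedulers, no count-weighted
  fingerprints, no DeepSMILES/InChI targets.
* Stereochemistry is the model's known weak point: fingerprints are
  mostly stereo-insensitive, so stereo assignment is under-determined
  from the source sequence by design.
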