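# Methods

## Model

`disocrf` labels each residue of a protein as ordered (O) or disordered (D)
with a first-order linear-chain conditional random field. For an
observation sequence `x` (the per-residue feature matrix, L×F) and a label
chain `y ∈ {O, D}^L`,

    P(y | x) = exp( Σ_{i≥2} λ[y_{i−1}, y_i] + Σ_i Σ_l μ[l, y_i]·x_{i,l} ) / Z(x).

Transition features are position-independent indicators of the four label
pairs (4 weights); the first position carries no transition term. State
features are real-valued: each feature `l` contributes `x_{i,l}·1[y_i = y]`
with one weight per (feature, label) pair, the standard extension of
indicator-feature CRFs to continuous inputs. There are no
observation-dependent transition features.

All inference is exact and in log space (log-sum-exp throughout; no
probability-space recursions, so under/overflow cannot occur by
construction): the partition function by the forward recursion, posterior
node and pairwise marginals by forward–backward, and decoding by Viterbi.
Score ties in Viterbi resolve to O deterministically (O has index 0 and
every argmax takes the first maximizer); an all-zero model therefore
decodes to all-O. Marginal decoding (threshold on P(D), default 0.5,
ties → O) is available behind a flag.

## Training

The objective is the penalized conditional log-likelihood

    Σ_seq [score(y|x) − log Z(x)] − ||w||² / (2σ²),

whose gradient is empirical minus expected feature counts (node marginals
for state weights, pairwise marginals for transitions) minus `w/σ²`. It is
concave, so the quasi-Newton optimizer (L-BFGS-B, analytic gradient) finds
the global optimum; the accepted objective sequence is non-decreasing, which
the tests assert. Defaults: at most 50 iterations, all weights initialized
to 0.05, Gaussian prior σ² = 100, relative function tolerance 1e-6. The
iteration count and initial value follow the tuned settings for this task;
the penalty form and prior variance were open design choices, resolved to
the standard Gaussian-prior CRF objective. Training is deterministic: the
only randomness
anywhere in the package (subsampling, CV, simulation) takes explicit seeds.

Models serialize to versioned JSON (alphabet, F, both weight blocks, the
training config); floats round-trip exactly via shortest-repr encoding.

## Features (F = 242)

Per residue `i`, the feature row is the concatenation of four blocks, with
the block layout recorded in the cache-file header:

| block | dim | content |
|---|---|---|
| `pssm_window` | 220 | normalized PSSM rows of the 11-residue window centered on `i` |
| `kmer` | 20 | amino-acid frequencies in the same window (k = 1) |
| `secondary_structure` | 1 | scalar code of the PSIPRED class |
| `rsa` | 1 | predicted relative solvent accessibility, fraction |

PSSM log-odds scores are squashed to [0, 1] piecewise-linearly: 0 at or
below −5, `0.5 + 0.1x` between, 1 at or above +5 (implemented as a clip,
which matches the piecewise form exactly at the branch points). Window
slots beyond the termini contribute the normalized-zero row (all 0.5); the
composition window instead clips to the chain and uses the true residue
count as denominator, so frequencies always sum to 1 over standard
residues. Non-standard letters (B, J, O, U, X, Z) are excluded from both
numerator and denominator rather than given invented frequencies. The
secondary-structure code is C→0, H→0.5, E→1 — the track is one-dimensional
by design and any fixed injective code is admissible, so the mapping is
configurable. RSA units are auto-detected (any value > 1.5 ⇒ percent
scale, divided by 100) and stored as fractions. All coordinates are
1-based inclusive throughout, matching structure-annotation conventions.

Parsers accept the PSI-BLAST ASCII PSSM, PSIPRED `.ss2` and SABLE-style
column dialects, cross-check residue letters against the FASTA sequence
when given (X tolerated on either side), and report the offending line or
position on error. Running PSI-BLAST/PSIPRED/SABLE themselves is out of
scope; only their outputs are consumed.

## Evaluation protocol

D is the positive class. `Sn = TP/(TP+FN)`, `Sp = TN/(TN+FP)`,
`ACC = (Sn+Sp)/2` (balanced accuracy — the mean of class accuracies, not
raw accuracy), and MCC in its confusion-matrix form. A zero MCC
denominator returns 0 with a warning; an absent truth class makes Sn or Sp
NaN with a warning. Benchmark filters keep X-ray entries with resolution
≤ 2 Å (inclusive), length ≥ 30 (inclusive) and at least one disordered
region; entries without a resolution are excluded with a logged reason.

Ratio balancing targets a global D:O count of 1:m by removing ordered
residues uniformly at random across the whole dataset (never disordered
ones). Each excision splits its chain at the removed position, so surviving
subsequences contain only genuinely adjacent residue pairs — excision
without splitting would fabricate transitions between non-adjacent
residues. If the requested ratio is already exceeded the call is a no-op
with a warning. Cross-validation folds are assigned at the protein level
(never splitting a chain across train and test, which would leak), sizes
differing by at most one, seeded. The ratio-curve harness subsamples only
the training portion of each fold and pools confusion counts over all test
residues; per-protein and pooled metrics are both reported by the CLI.

A caveat found while characterizing the harness: balancing far below the
natural ratio (e.g. 1:50 → 1:2) removes so many ordered residues that the
survivors are mostly isolated single-residue fragments, which erases the
O→O transition statistics and degrades the CRF badly. On synthetic data
with natural imbalance 1:50 the cross-validated MCC curve is unimodal in
the training ratio with its peak at a moderate balance (≈1:20), declining
toward the extreme — the balance optimum depends on the natural imbalance
of the source data and does not transfer across datasets.

## Synthetic data

The generator emulates the statistical structure the CRF assumes, not
biophysics. Labels follow a two-state Markov chain started from its
stationary distribution; default persistence 0.95/0.95 gives mean segment
length 20 residues (the scale of typical crystallographic IDRs) and
stationary disorder fraction 0.5. Conditional on the label, tracks are
emitted independently per position:

- **PSSM**: Gaussian raw scores, noise SD 1.0, clipped to [−10, 10]. The
  state-dependent mean shift per column is `δ·sd/(2√20)`, so the 20-column
  profile carries an aggregate between-state Mahalanobis separation of `δ`
  — `δ` is a per-block separation budget, keeping the task's difficulty
  interpretable rather than letting 20 columns multiply a per-column shift.
- **Residue identity**: categorical, mixed from a uniform background toward
  a disorder-enriched (P,E,S,Q,K,G,A,R) or order-enriched (W,F,Y,I,L,V,C,M)
  composition with strength `min(δ,3)/3`.
- **Secondary structure**: disordered positions emit coil with high
  probability, ordered positions a helix/strand-rich mix, same mixing.
- **RSA**: Gaussian with SD 0.1, disordered mean higher by `δ·0.1`,
  clipped to [0, 1]; at δ = 3 a midpoint threshold on RSA alone gives
  balanced accuracy Φ(δ/2) ≈ 0.93.

At δ = 0 every track's distribution is identical across states. The
generator writes the same FASTA/PSSM/.ss2/RSA/interval files the real
pipeline parses, so synthetic and real inputs are interchangeable.

What passing tests on these data do and do not show: the synthetic tracks
are conditionally independent given the labels and exactly first-order
Markov — real disorder has long-range dependence, homology structure and
annotation noise, none of which is modelled. Recovery results here verify
the estimator and decoder, not real-data accuracy.

## Experiments used in validation

Problem sizes were chosen to exercise the full pipeline while keeping runs
small: the recovery experiment trains on 200 proteins (lengths 60–200,
~26k residues) and evaluates 100 held-out proteins; train and test seeds
are derived as independent children of one master seed. At δ = 3 the
held-out residue-level MCC is ≈ 0.99; at δ = 0 it is statistically
indistinguishable from 0. The continuity comparison fits a logistic
regression on the identical per-residue feature rows, thresholds it to
match the CRF's test-set sensitivity, and compares disordered-segment
counts. At δ = 3 both predictors operate near ceiling (residue error
≈ 0.5%), so the segment-count difference is small (order of a few
segments in ~700) and its sign can vary with the simulation seed; the
related, robust property — that strengthening the D→D transition weight
never increases the number of decoded segments on fixed state scores — is
tested directly on toy inputs.

## Known limitations

- Two labels only; no semi-Markov or higher-order structure, no
  observation-dependent transitions.
- Full-scale benchmarking (MobiDB/DisProt corpora with PSI-BLAST/
  PSIPRED/SABLE runs) is out of scope; real-data accuracy is not claimed.
- The subsampling optimum is dataset-dependent (see above).
- Feature caches store floats at 8 significant digits; round-trips are
  near-exact but not bit-exact (model files are bit-exact).
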