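# Methods

This note documents the models, defaults, numerical choices and known
limitations of `pepobs`, in the order data flows through the package.

## Digestion and uniqueness

Trypsin is modeled by the standard rule: cleave C-terminal of K or R unless
the next residue is P. Peptides carry 0-based half-open coordinates and a
missed-cleavage count equal to the internal K/R-not-before-P sites left
uncut; with zero missed cleavages the peptides tile the parent exactly.
A peptide is *proteotypic* when its sequence occurs as a tryptic peptide
(up to two missed cleavages, the usual search-engine ceiling) in exactly
one database protein. Uniqueness is defined at the parent-protein level — a
sequence repeated inside one protein is still proteotypic — and I/L are
distinct residues by default (`il_equivalent=True` merges them, since the
two are isobaric in MS). Training and prediction candidates are fully
tryptic (0 missed cleavages) and length-bounded to 6–30 residues, the
typical LC-MS observable range; digestion itself imposes no bounds so the
tiling invariant holds.

## Intensity ingestion

The intensity table (TSV: `protein_id`, `peptide_sequence`, `xic_area`,
optional `study_id`, `pep`) is assumed to come from a search pipeline that
already applied PSM-level filtering; if a `pep` column is present it is
additionally thresholded at 0.01 (configurable). Rows are restricted to
proteotypic fully tryptic candidates; semi- or non-tryptic rows are
dropped at load. When a protein occurs in several studies, only the study
with the most quantified peptides is kept (ties: lexicographically
smallest study id — any deterministic rule works; this one needs no
second pass). Duplicate peptide rows within the kept study collapse to
their maximum XIC. Unobserved candidates of a retained protein are added
with XIC 0; relevance is XIC divided by the protein's maximum, so exactly
the most intense peptide(s) score 1; proteins whose candidates are all
zero carry no ranking signal and are excluded (logged). Train/validation
splitting is by protein (never by peptide), 20% validation by default,
seeded.

## Features

The 45-entry registry is fixed in order and serialized with every model:
20 residue frequencies (alphabetical), 9 general properties, 12
peptide-averaged per-residue scales, 4 digestion-related entries.
Constants and conventions:

* Monoisotopic residue masses plus one water (18.010565 Da).
* Charge via Henderson–Hasselbalch with EMBOSS pKa values (N-term 8.6,
  C-term 3.6; K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1); the
  net-charge feature is evaluated at pH 7.0. The isoelectric point is the
  unique root of the strictly decreasing charge function, found by
  bisection on [0, 14] to 1e-3 (tested against a 1e-4 grid scan).
* Residue sets: positive {K,R,H}, negative {D,E}, polar {S,T,N,Q,Y,H},
  hydrophobic {A,V,L,I,M,F,W,C}.
* Per-residue scales are aggregated by arithmetic mean (configurable to
  sum). Two scales are published tables embedded verbatim (Wolfenden 1981
  hydration potentials as the hydrophobicity index; Kyte–Doolittle 1982
  hydropathy as the second hydrophobicity scale); the other eleven are
  synthetic stand-ins that reproduce the qualitative residue ordering of
  the named property — see `aaindex_tables.py`, where each table's
  `source` field says which kind it is, and any table can be replaced by a
  two-column TSV.
* Missed-cleavage frequency is missed cleavages per residue. It is
  retained in the registry as a negative control even though candidates
  are fully tryptic (it is constantly zero there, and the standardizer
  maps constant features to zero).
* The N-/C-terminal digestion probabilities look up the flanking residue
  pair (P1, P1′) of the cleavage event that created each terminus in a
  propensity table; protein-terminal boundaries need no cleavage and get
  1.0. The default table is estimated from the training table itself: a
  tryptic site of a retained protein counts as cleaved if it is a terminus
  of any quantified peptide, and pair probabilities use add-one smoothing
  ((cleaved+1)/(total+2), unseen pairs 0.5). This is a deliberately simple
  empirical model; a user-supplied table overrides it.

Features are z-standardized with parameters fitted on the training matrix
(zero-spread features get sd 1.0) and stored with the model.

## Network and training

Architecture: input → 5 dense hidden layers of 128 rectifier units → one
linear output. Defaults reproduce the reference configuration exactly:
dropout 0.2, SGD learning rate 0.001, minibatch 3, 10 epochs. Choices the
reference leaves open, fixed here:

* Output unit is linear (the target lies in [0, 1] but clamping the output
  would flatten gradients at the boundaries).
* Loss is the mean squared error over each minibatch.
* Weight initialization is uniform in ±sqrt(6/(fan_in+fan_out)), seeded;
  biases start at zero.
* Plain SGD — no momentum, decay or schedule.
* Dropout uses inverted scaling at train time (hidden activations divided
  by 1−p), so prediction requires no rescaling; the last short minibatch
  of an epoch is used as-is; examples are reshuffled each epoch from the
  run seed. All randomness (init, shuffling, masks) derives from one
  integer seed; with dropout 0 a run is bit-reproducible.
* A non-finite loss aborts training with a diagnostic rather than
  continuing silently.

Per-protein ranking digests the query protein, filters to proteotypic
candidates, scores, divides by the maximum score (top peptide reads 1.0)
and sorts descending with lexicographic tie-breaks. If the maximum raw
score is not positive, raw scores are emitted unscaled and the result
carries `normalized=False` instead of dividing by a non-positive number.
Models serialize to a single JSON document (weights round-trip bit-exact
through Python's shortest-repr floats); loading refuses unknown format
versions, and prediction refuses feature vectors from a different registry
version.

## Evaluation

nDCG@k uses gain(s) = log₂(1+s) by default. A literal log₂(s) is undefined
at s = 0 (and negative for s < 1), which relative-XIC relevances hit
constantly; the shifted transform is zero at s = 0, positive otherwise,
and keeps the logarithmic shape. A graded-levels alternative (s binned to
integer grades 1..L, gain = log₂(grade)) is provided. Groups smaller than
k are scored at k′ = min(k, n) rather than padded; single-peptide groups
score 1.0 and are counted separately in reports; when every gain in a
group is zero the group scores 1.0 by convention and is flagged. Equal
predicted scores are ordered lexicographically by sequence before scoring,
so evaluation is deterministic. The random baseline scores uniformly
random orderings (seeded) and its Monte-Carlo mean matches exhaustive
permutation averages on small groups (tested). The default k is 4,
matching the handful of surrogates a targeted assay uses.

## Interrogation

Feature importance reads the first hidden layer: aᵢⱼₖ = wⱼᵢxᵢₖ + bⱼ,
pᵢⱼ = meanₖ|aᵢⱼₖ|, cᵢⱼ = pᵢⱼ/Σᵢpᵢⱼ (denominator per neuron),
c⁺ᵢ = Σⱼ max(0, cᵢⱼ). The default uses the example-averaged magnitude pᵢⱼ
in the numerator so cᵢⱼ is example-free; a strict per-example mode forms
cᵢⱼₖ = aᵢⱼₖ/Σᵢpᵢⱼ and averages over examples, with the rectifier applied
before (default) or after the average — both orders are implemented
because they differ whenever potentials change sign across examples.
Importance is computed over the training examples by convention, in the
standardized feature space the weights were learned in. Two caveats when
reading reports: the bias term enters every feature's potential at a
neuron, compressing contrast; and correlated features (length vs molecular
weight, frequencies vs composition fractions) share their contribution, so
related features should be read as groups. With briefly trained networks a
sizable share of c⁺ still reflects the random initialization.

## Synthetic data

The generator emulates the structure the method assumes: i.i.d. random
proteins (uniform residues by default, configurable distribution), and per
proteotypic candidate a latent observability o = logistic(Σ w_f z_f) over
globally standardized features, scaled by multiplicative lognormal noise
(XIC areas are positive and right-skewed) and censored to zero with a
configured probability ("identified but not quantified"). It does not
simulate spectra, retention time, modifications, homology structure or
instrument effects — so passing tests demonstrate that the pipeline
recovers plantable statistical signal, not that it captures real
ionization physics.

The standard benchmark fixture is 750 proteins of 120–600 residues
(generator seed 42), signal weights +2.0 on the hydrophobicity index and
−1.0 on peptide length, noise sd 0.2, zero fraction 0.1, split 600
train / 150 held out (split seed 11). These sizes keep a full training
run around ten seconds while leaving ~11.6k training peptides, enough for
stable rank recovery; the end-to-end tests train it with three independent
seeds to avoid single-seed luck. On this fixture the default model reaches
held-out median nDCG@4 ≈ 0.91 versus ≈ 0.52 for random permutations, and
≈ 0.999 with noise and censoring switched off (recomputed by the test
suite, `tests/test_acceptance.py`).

A known limitation, asserted honestly by the importance test on this
fixture: the dominant signal feature (hydrophobicity) surfaces at the top
of the c⁺ ranking, but the weaker length signal disperses into collinear
features (molecular weight, residue counts) and lands outside the top 10 —
at this training scale the first-layer weights move only a few percent
from initialization, which bounds the contrast the interrogation can
develop.

## Command-line interface

Each subcommand is a thin wrapper over exactly one library pipeline and
writes a `manifest.json` (parameters, seed, input checksums, package
version) sufficient to re-run it; outputs are deterministic given seed and
inputs. Errors exit non-zero with both a human-readable message and a JSON
line on stderr.
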