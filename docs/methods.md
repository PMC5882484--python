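# Methods

## Model and assumptions

`confomer` predicts a continuous molecular property y (log units) from
sparse occurrence counts of canonical atom signatures, and quantifies
per-compound uncertainty with conformal regression. The only
distributional assumption is *exchangeability*: compounds to be predicted
are drawn from the same distribution as the training compounds. Under
that assumption an inductive conformal predictor (ICP) is marginally
valid at every confidence level by construction; no Gaussianity,
homoscedasticity or model-correctness assumptions are needed. Efficiency
(interval tightness), by contrast, depends entirely on how well the
endpoint and error models fit, so the package treats validity as a
guarantee to be audited and efficiency as the quantity to optimize.

## Signature descriptors

An atom signature of height h is a canonical serialization of the
subgraph induced by all atoms within h bonds of a root atom. The dialect
is a rooted DFS string: atom labels `[El]` (element lowercased when
aromatic, with a formal-charge suffix), bond symbols `""`/`=`/`#`/`:`
for single/double/triple/aromatic, children visited in lexicographic
order of (bond symbol, atom label, serialized subtree), and numbered
back-reference markers for ring revisits, assigned in visit order
(height-3 benzene: `[c,1](:[c](:[c](:[c](:[c](:[c,1])))))`). Sibling
order is decided by serializing each candidate subtree from a snapshot of
the already-visited state; for the height ≤ 3 neighborhoods used here
this greedy canonicalization is invariant to input atom order, which the
test suite verifies by renumbering atoms of drug-like molecules.
Hydrogens are implicit and never appear. The vocabulary key is the pair
(serialization, height), so the same-looking neighborhood at two declared
heights counts as two features. The dialect is internally consistent but
deliberately makes no claim of byte-compatibility with other signature
implementations.

Vocabulary indices follow first-appearance order over the input compound
sequence; `min_count` thresholds on distinct-compound support (default 1).
At prediction time, out-of-vocabulary signatures are dropped from the
counts — the linear model has no weight for them — but tallied into a
per-molecule novelty ratio as an applicability-domain diagnostic.

## Endpoint and error models

Both models are L2-regularized ε-insensitive linear SVR (scikit-learn
`LinearSVR`, dual coordinate descent, the liblinear algorithm) on raw
counts; no scaling or centering is applied. The tuned hyperparameters
are:

| parameter | meaning | default |
|---|---|---|
| `cost` | error penalty C | 1.0 |
| `epsilon` | solver termination tolerance | 1e−4 |
| `tube` | ε-insensitive tube width (not tuned) | 0.1 |
| `seed` | solver RNG seed | 42 |

`epsilon` is the *termination tolerance*, not the tube width — the two
are easy to conflate because liblinear exposes both. Error models for
the normalized (resp. log-normalized) measure are trained on the
magnitudes |y−ŷ| (resp. ln max(|y−ŷ|, 1e−8)) of **in-sample** endpoint
residuals on the proper training set. The out-of-fold alternative was
evaluated and rejected: out-of-fold targets inflate the aggregate
predictor's overcoverage (see "Aggregation behavior") rather than reduce
it.

## Conformal machinery

Calibration scores are sorted ascending and the score at 1-based rank
⌈c·(n+1)⌉ is used at confidence c; the +1 convention preserves
finite-sample validity, and a rank beyond n yields an explicitly flagged
unbounded interval (never silently clipped). Interval construction
exactly inverts the nonconformity measure (the algebraic round-trip is
tested to machine precision). The normalized denominator is floored at
1e−8 because a linear error model can predict ≤ 0.

The cross-conformal predictor (CCP) permutes the training set with a
seeded RNG, splits it into k folds of size ⌊n/k⌋ or ⌈n/k⌉ (default
k=10), and builds one ICP per fold (fold i calibrates member i). A
prediction takes the median of member midpoints and the median of member
widths, then re-centers the interval as midpoint ± width/2; the median
over an even member count is the mean of the central pair. k=1
degenerates to a single seeded 80/20 proper/calibration split.

### Aggregation behavior

Measured over repeated synthetic draws (n_train = 2000, k = 10), a single
ICP is exactly valid (mean coverage 0.799 at nominal 0.80), while the
median-aggregated CCP is mildly conservative for the *normalized*
measure: +1.0 to +1.7 coverage points, because the median of k noisy
per-member error scalings tracks per-compound difficulty better than any
single member does. The abs_diff and log-normalized (β=1) CCPs are
nearly unbiased. Consequence for testing: CCP coverage with the
normalized measure can sit at or just above the top of the exact binomial
99% band around the nominal level, so validity checks compare against
that band with the aggregation conservatism in mind rather than treating
small upward excursions as bugs.

## Gradients

The gradient of a prediction with respect to a descriptor is the change
in the endpoint prediction when that descriptor's occurrence count is
incremented by one; only descriptors present in the molecule are
perturbed, and the reported value is the median over CCP members (for
purely linear members this equals the member-median weight exactly —
asserted in tests). Per-atom contributions sum the gradients of every
descriptor whose subgraph contains the atom, and depictions color atoms
on a symmetric blue–white–red scale normalized by the maximum absolute
contribution. SVG output has no extra dependencies; PNG requires an
RDKit build with Cairo.

## Synthetic data

The generators define the study conditions for every benchmark in the
package.

**Vector datasets** draw sparse non-negative integer count features
(p=200, density 0.05 by default; counts 1+Poisson(1) where present) and a
linear signal y = w·x with i.i.d. Gaussian noise of per-sample standard
deviation `noise_base + hetero_gain · x₀`, where the noise-driver
feature x₀ ~ Poisson(`hetero_rate`) is drawn unconditionally so the
heteroscedastic condition actually varies at low density. I.i.d. draws
make the data exchangeable, so conformal validity holds by construction
up to binomial noise. Two named conditions are used:

* `heteroscedastic_spec` — sd = 0.3 + 0.3·x₀, x₀ ~ Poisson(1): the
  moderate condition for validity benchmarks (n = 4000, split 2000/2000).
* `strongly_heteroscedastic_spec` — sd = 0.2 + 1.0·x₀, x₀ ~ Poisson(0.5):
  mostly easy samples with a hard right tail (n = 3000, split 1500/1500).
  The efficiency advantage of error-model measures exists only when the
  noise-scale distribution is right-skewed (its median well below its
  upper quantiles); this was derived with an ideal error model before
  pipeline measurement, and in this regime the normalized measure's
  median interval width at 80% is robustly below abs_diff's.

**Molecule datasets** sample (with replacement) from a fixed in-repo list
of 222 drug-like structures and assign the label y = Σ c(s)·n(s) over the
molecule's height-1..3 signatures s, where each fragment contribution
c(s) is derived from an md5 hash (uniform in ±0.25) and small Gaussian
noise (sd 0.1) is added. Labels are therefore *additive and linear in
signature counts*, so the linear SVR is well-specified and conformal
machinery can be tested separately from model-misspecification effects.
The labels are synthetic and are not experimental logD; a few named
reference drugs (atenolol, sotalol, tolnaftate, amiodarone, strychnine,
furosemide) are included as structures for interpretation demos only.
What passing tests on these data do *not* show: robustness to assay
noise structure, activity cliffs, tautomer/charge-state ambiguity, or
distribution shift between train and test chemistry — real-data effects
the generators deliberately exclude.

## Standardization

Input standardization keeps exactly the fragment with the most heavy
atoms (salt/solvent stripping), breaking ties by larger molecular weight
and then lexicographically smaller canonical SMILES, followed by
canonical-SMILES deduplication (first occurrence wins). Fuller
normalization pipelines (tautomers, charge neutralization, stereo rules)
are intentionally out of scope; the subset implemented is portable across
toolkits and fully testable. Unparsable records are skipped with a
logged warning and counted, never fatal — the large-scale screening
convention.

## Numerical choices and degenerate inputs

* Solver determinism: fits are reproducible given (data, params, seed);
  `max_iter` is 200000 so default-tolerance fits converge on the problem
  sizes used here.
* Grid-search ties prefer lower cost, then larger epsilon (the simplest
  model); failed cells are reported as missing with a warning.
* Degenerate fits (constant targets, all-empty feature vectors) raise
  typed errors rather than returning silent nonsense.
* Coverage uses closed intervals (a truth exactly on a bound counts as
  covered); infinite-width intervals count as covering, are excluded from
  median-width summaries, and are reported as a separate fraction.
* Q² is the squared Pearson correlation between observed and predicted
  (affine-invariant; distinct from 1 − PRESS/SS).

## Problem sizes

Benchmarks run at desk scale by design: validity uses 2000/2000
train/test vectors with p=200; efficiency uses 1500/1500; molecular
end-to-end checks use a few hundred compounds with vocabularies of a few
thousand signatures. These sizes put binomial noise on coverage near
±1% and keep the full suite fast while exercising every code path at
realistic sparsity.

## Known limitations

* The CCP median aggregation is mildly conservative for normalized
  nonconformity (see above); exact finite-sample validity is an ICP
  property, not a CCP one.
* The signature dialect does not encode stereochemistry or isotopes.
* Interval symmetry is structural: the method cannot produce skewed
  intervals even when the conditional error distribution is skewed.
* At very high confidence the calibration rank can exceed the list
  length, producing unbounded intervals; large calibration sets are the
  only remedy.
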