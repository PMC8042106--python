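# Methods

## The diagnostic design

The package frames compound promiscuity as a classification problem per
*target pair*: dual-target compounds (DT, active against both targets of the
pair) against single-target compounds (ST, active against exactly one). A
pair enters the analysis when at least 50 ST compounds per target and 100 DT
compounds are available; these thresholds are exposed as
`assembly.MIN_ST_PER_TARGET` and `assembly.MIN_DT`. Qualifying sets are
balanced relative to the limiting class: with
`k = min(floor(|DT|/2), |ST_A|, |ST_B|)` the balanced dataset holds `k`
compounds per ST class and `2k` DT compounds, subsampled uniformly without
replacement (never upsampled). When `|DT|` is odd, at most one DT compound
is dropped, so the DT half and the combined ST half stay exactly equal —
which is also why balanced accuracy rather than raw accuracy is the headline
measure. The balanced set is split into ten random 50/50 train/test trials.
Splits are stratified by compound class (ST-A / ST-B / DT) with the extra
member of an odd class going to training; stratification keeps the
engineered 50:50 class prior intact in both halves. Per-class stratification
is a design choice of this package; a global 50/50 split would preserve the
prior only in expectation.

Models of every pair predict, at each trial, the test half of that same
trial for every pair: one native record and `n−1` cross records per (model
pair, algorithm, trial). Reusing the *same* test half for native and cross
evaluation at a trial means any native/cross gap is attributable to the
model, not to test-set composition.

## Synthetic libraries

The generator produces the statistical skeleton of pair-based promiscuity
data with a known ground truth. Molecules are assembled from three curated
pools with single-attachment-point SMILES fragments:

* ~20 drug-like **scaffolds** with 1–3 attachment points,
* ~30 small **decorations** filling free attachment points with
  probability 0.7 (hydrogen otherwise),
* ring-sized **head fragments** on the first attachment point of every
  compound: the pair's **signature fragment** with probability
  `carrier_rate` for DT compounds and `leak_rate` for ST compounds, or a
  **decoy** fragment otherwise.

Defaults are a minimally qualifying pair — 50 + 50 ST, 100 DT — with
`carrier_rate = 0.9` and `leak_rate = 0.05`, i.e. a strong but imperfect
structural basis for promiscuity with a small amount of structural label
noise; noise enters only through these rates, never through label flips. In
**local** mode each pair receives a distinct signature from a pool of ten;
in **global** mode all pairs share one. The Bayes ceiling of a
fragment-detector classifier at these rates is BA = (0.9 + 0.95)/2 = 0.925.

Three properties of the pools required deliberate design, because without
them the "local" regime silently contains global signal:

1. **Reachability.** Scaffolds and decorations are sulfur-free while the
   signature fragments are sulfur-marked (one benzoxazole exception is a
   fused heterocycle unreachable from the background pools), so a signature
   substructure can only occur by planting. With `carrier_rate = 1,
   leak_rate = 0` a plain substructure search reproduces the labels exactly
   — the planted-signal oracle that upper-bounds every classifier.
2. **Size neutrality.** Non-carriers receive size-matched decoy ring
   fragments; otherwise "is a larger molecule" would separate DT from ST
   globally.
3. **Composition neutrality.** The decoy pool echoes every signature
   chemotype (fused azoles, aromatic S-heterocycles, thioethers, sulfonyls,
   thioamides, N-linked saturated rings), and the ten signatures alternate
   chemotypes. Without analogue decoys, "contains an aromatic
   S-heterocycle" and similar coarse features act as global promiscuity
   cues that a Tanimoto k-NN happily transfers across pairs (observed as
   cross-pair BA ≈ 0.8 in early designs). With them, element and
   functional-group composition is class-neutral and only the specific
   planted substructure is informative — mirroring congeneric
   medicinal-chemistry series in which actives and inactives share their
   background chemistry.

The pools are frozen constants; a leak audit (every signature query against
products of all other fragments, decoys, and scaffold × decoration
backgrounds over four attachment contexts) runs in the test suite.

Randomness fans out from one master seed through `SeedSequence` spawn keys
(one child stream per pair, and separate keys for balancing, splitting, and
model seeding), so identical configurations are byte-identical and adding
pairs or trials never perturbs existing ones.

A second, chemistry-free tier plants the same carrier/leak structure in
random bit vectors (a per-pair signature bit block plus independent
background bits). It exercises models and metrics fast, without RDKit in
the loop; only attribution needs real atoms.

What the generator does **not** emulate: real chemical space (potency
values, assay confidence, scaffold inequality between pairs, shared
compounds across pairs), correlated targets, or activity-cliff structure.
Passing the diagnostic contract on these libraries shows the pipeline
detects locality/globality of structural signal *when it is the only
signal*; it does not certify performance levels on database-derived sets.

## Fingerprints

Folded binary Morgan (circular atom-environment) fingerprints, radius 2 and
2048 bits by default — the ECFP4-equivalent standard. Bits are binary, not
counts. For attribution the package records, per set bit, every environment
occurrence (center atom, radius, environment atom set). Two policies
matter:

* **Fold collisions:** all environments hashing to one bit are kept as
  separate occurrences, and `n_occ` counts them all — the atom-mapping
  formula divides by occurrence count, so collisions must stay visible.
* **Symmetry:** symmetry-equivalent environments (the six carbons of
  benzene) count as distinct occurrences per center atom.

The Tanimoto coefficient |x∧y|/|x∨y| doubles as the SVM kernel; two empty
vectors are assigned similarity 1 (identical objects), keeping the Gram
matrix well defined.

## Models

Three algorithms with a fixed global class convention DT = +1, ST = −1:

* **SVM** with the precomputed Tanimoto kernel (`sklearn.svm.SVC`); the
  fitted object retains support vectors, dual coefficients y⁽ⁱ⁾λ⁽ⁱ⁾ and
  bias so the decision function is reproducible as an explicit dual sum —
  the prerequisite for attribution. A decision value of exactly zero
  predicts ST (conservative toward the non-promiscuous class).
* **Random forest** on the raw bit matrix, 100 trees. Tree count is a
  compute budget rather than a regularisation knob (accuracy is monotone
  and plateaus in it), so it is fixed instead of cross-validated.
* **k-NN** with Tanimoto distance (1 − similarity). The default grid holds
  odd k only; an even vote split would fall to ST via the class ordering.

Hyperparameters (SVM C ∈ {0.1, 1, 10, 100}; RF max depth ∈ {unlimited, 20};
k ∈ {1, 3, 5}) are selected by an inner stratified 5-fold grid search on
the training half maximising MCC, then refit on the full half — the ten
outer trials are the outer loop of the nested cross-validation. Grid ties
resolve to the first listed value. All estimator seeds derive from the
run seed.

## Evaluation

Confusion counts (DT positive) feed the five formula-defined measures.
Degenerate denominators are handled explicitly: a metric whose denominator
vanishes is *missing* (`None`), excluded from summaries and counted in
`n_missing`, never silently zero — except MCC with a zero marginal, which
is reported as 0 with a degeneracy flag. Distribution summaries are
five-number (min, quartiles, max; `numpy` linear-interpolation quantiles)
plus 1.5·IQR outliers, per (kind, algorithm, measure); the median is the
headline statistic. Cross records can be partitioned by protein-family
relation into same-family (all four targets one family), different-family
(disjoint family sets) and mixed buckets; the mixed bucket is this
package's interpretation for the remainder, since partial overlaps belong
to neither extreme.

## Attribution

For a test compound x under a Tanimoto-kernel SVM, the weight of feature d
splits the kernel expansion over shared bits:

fc(x, d) = Σᵢ y⁽ⁱ⁾λ⁽ⁱ⁾ x⁽ⁱ⁾_d x_d / (⟨x⁽ⁱ⁾, x⁽ⁱ⁾⟩ + ⟨x, x⟩ − ⟨x⁽ⁱ⁾, x⟩)

fc is computed for set bits only (it vanishes identically on unset bits),
over the folded fingerprint with the collision policy above. Summing fc
over bits reconstructs Σᵢ y⁽ⁱ⁾λ⁽ⁱ⁾K(x⁽ⁱ⁾, x), so `Σ_d fc + b` must equal
the decision value; the pipeline tracks the largest deviation (≈1e−14 in
practice, tolerance 1e−6). Atom weights distribute each feature's weight
over its occurrences, fw(a) = Σ fc/(n_atoms · n_occ), which conserves the
total exactly (tolerance 1e−9). The bias has no feature and is excluded
from atom maps but reported alongside, keeping the decomposition checkable.
Rendering (red gradient for positive/DT, blue for negative/ST, one Gaussian
per atom) is an optional thin layer over RDKit similarity maps; the
numerical tables are the tested surface. Attribution applies to SVM models
only.

Signature recovery is scored per compound as the fraction of
non-fragment atoms whose weight lies below the mean weight of the planted
fragment's atoms (1.0 = the fragment outranks everything), averaged over
correctly predicted DT test carriers of a pair.

## Problem sizes and numerical choices

The study-scale runs used by the test suite are ten-pair libraries at the
default sizes (200 compounds per pair), ten trials, all three algorithms —
3,000 prediction records and 10,000 attributed SVM predictions per mode,
about three minutes each on one CPU. Examples use two-to-three-pair
libraries. The fixed session seed is 2021. Determinism is exact: rerunning
any configuration reproduces every table bit for bit.

Known limitations: no probability calibration or significance testing; no
count fingerprints or alternative fingerprint families (the fingerprint
layer is parameterised but ships one default); attribution for k-NN and RF
is out of scope by design; the CLI is a thin wrapper (`run`, `generate`)
over the library rather than a stage-by-stage orchestration surface —
individual stages are library calls.
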