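# Methods

`pesig` derives multi-gene support-vector-machine (SVM) signatures that
classify tumours as sensitive or resistant to a drug, starting from a
literature-curated seed gene list and expanding it through a pathway
interaction network. This note records the model, its assumptions, the
parameters that matter, and the design choices made where the design
was genuinely open.

## Pipeline overview

1. **Preprocessing.** Probe-level expression is collapsed to one row
   per gene (arithmetic mean of probes). Validation cohorts are
   quantile-normalized against the training panel's mean-quantile
   distribution. Continuous GI50 values are dichotomized into
   sensitive/resistant training labels.
2. **Angle preselection.** Each candidate gene is scored by its
   multiple-factor-analysis (MFA) correlation-circle angle against
   GI50 across the training panel; genes within θ degrees of full
   direct (0°) or inverse (180°) correlation pass.
3. **Pathway expansion.** Passing curated genes recruit their network
   neighbours (1-node distant), which are scored and filtered
   identically and may recruit 2-node-distant genes. Failing genes are
   dead ends.
4. **Signature derivation.** For each (C, σ) pair of a fixed grid,
   greedy forward feature selection grows a gene list that minimizes a
   cross-validated criterion; a Gaussian-kernel SVM is trained on the
   selected genes.
5. **Validation and ensembling.** Signatures are scored on an
   independent labelled cohort (MCC-primary model selection), per-gene
   contributions are measured by leave-one-gene-out retraining, and
   top models are combined by AUC-weighted ±1 voting.

## GI50 dichotomization

GI50 is on the −log10 molar scale: a larger value means growth is
inhibited at a lower concentration, i.e. the line is *more sensitive*.
The default polarity therefore labels GI50 ≥ threshold as sensitive;
the opposite polarity is available as a flag since conventions differ
between screening datasets.

The threshold is the panel median when it is unique. When two or more
lines tie the median, a median split is ambiguous and the threshold
moves to the GI50 value bounding the widest gap between adjacent
sorted values (left edge; if that coincides with the panel minimum the
right edge is used so that both classes stay non-empty). Samples
exactly at the threshold are assigned to the sensitive class by the
≥ rule and logged.

## The correlation angle

For one gene, MFA is run on two variable blocks — the gene's data
(expression, optionally with copy number) and the GI50 outcome. All
variables are standardized; each block is weighted by the inverse of
its first singular value so neither block dominates; a global SVD is
taken; and every variable is placed on the correlation circle of the
first two global dimensions. The angle between the gene's variable and
the outcome variable summarizes their association.

Two properties anchor the statistic:

* **Closed form.** With a single expression variable against GI50 the
  angle is exactly `arccos(Pearson r)`. The test suite verifies this
  to 1e-9 degrees, along with sign symmetry (negating a vector maps
  θ → 180° − θ) and invariance under positive affine rescaling.
* **Filtering uses single-source angles only.** The joint GE+CN
  placement is reported for inspection but never decides pass/fail:
  when both variables project weakly onto the 2-D global plane, the
  angle between their (short) loading vectors can be small even for
  uncorrelated data, which inflates the null pass rate. The
  single-variable angles are exact correlations and keep the null
  false-pass probability negligible (|r| ≥ cos 20° ≈ 0.94 at n = 48).

Genes whose GI50 association comes only through copy number remain in
the qualified set for bookkeeping but are excluded from the SVM
feature pool: patient cohorts carry no copy-number data, so such a
feature could never be evaluated at prediction time.

## Expansion semantics

Expansion is a breadth-layered traversal. A gene's node distance is
the *minimum* distance at which it is recruited; a gene recruited at
layer 1 is never re-listed at layer 2. Genes failing the angle filter
are recorded in an audit table at the distance where they were scored,
and are not traversed through. Curated genes failing the filter stay
labelled distance 0 in the audit but leave the qualified set.

Six standard conditions cross maximum depth {0, 1, 2} with threshold
θ ∈ {10°, 20°}. The qualified set is monotone non-decreasing in both θ
and depth (asserted as a property test). Interaction edges are treated
as undirected regardless of the interaction type recorded in the SIF
file; an include-list filter on types is available.

Alias handling: seed lists and network nodes are mapped through the
alias table *before* traversal, and the final parent–child recruitment
list is re-checked against the network (`verify_associations`) as a
belt-and-braces audit — deprecated symbols reassigned to unrelated
genes otherwise create spurious neighbourhoods. An optional
per-gene neighbour cap (off by default) is available for hub damping.

## SVM learning

* **Grid.** C and σ range over decades 1…10⁵ with C ≥ σ: 21 pairs.
  The kernel is K(u, v) = exp(−‖u−v‖² / 2σ²); features are used on
  their log-expression scale without further standardization, since
  quantile normalization has already put cohorts on a common scale.
* **Criteria.** Stratified k-fold cross-validation (k = 5 by default;
  k must not exceed the smaller class) estimates either the
  misclassification rate or the log loss. The margin classifier emits
  no probabilities, so log loss uses a per-fold logistic (Platt-style)
  map of decision values fitted on the training folds; probabilities
  are clipped to [1e-15, 1 − 1e-15].
* **Forward selection.** Each round evaluates every remaining
  candidate appended to the incumbent list, in a seed-randomized
  order; ties go to the first candidate encountered in that order. The
  best candidate is accepted only on *strict* improvement (tolerance 0
  by default, configurable), and selection stops when no candidate
  improves or the criterion reaches its floor of 0. The first selected
  feature therefore attains the exhaustive single-feature minimum
  (property-tested on pools of 20).
* **Class encoding.** Resistant = +1, sensitive = −1, so a positive
  SVM decision value votes resistant — the orientation the ensemble
  sign rule expects. Decision functions are stored explicitly
  (support vectors, dual coefficients, intercept, γ), making the
  serialized signature self-contained and byte-reproducible.
* **Two-gene floor.** Pathway-extended runs exist to demonstrate value
  beyond single markers, so PE models with fewer than two genes are
  moved to an audit list rather than validated. Curated-only runs are
  exempt.

## Validation

The positive class is resistant throughout. MCC is the primary
selection metric because the validation cohorts are imbalanced
(some 3:1 or worse); its zero-denominator convention is 0. AUC is
computed by the rank statistic with midrank tie handling, oriented so
that higher decision values rank resistant samples first. Ties in
model selection break by higher overall accuracy, then fewer features.
Report percentages display to the nearest integer and MCC to 2 d.p.

Leave-one-gene-out importance retrains the signature minus each gene
at the model's own (C, σ) and reports the change in training
criterion, test overall accuracy and test MCC. A gene whose removal
*raises* test MCC is flagged as a candidate machine-learning false
positive.

## Ensembles

Members vote ±1 per sample; votes are weighted by each member's AUC on
the labelled cohort; the weighted-sum sign makes the call. An exactly
zero sum is called resistant with a warning — the sign rule defines
only the strict inequalities, and a non-response call is the safer
clinical default. The consensus flag marks samples where at least 75%
of members (unweighted) agree; weights are fitted on the same cohort
that is predicted, which mirrors common practice but is optimistic and
should be read as in-sample. Weight scaling never changes labels;
with equal weights and an odd member count the ensemble reduces to
simple majority vote (both property-tested).

## Synthetic study conditions

The generator defaults define the conditions under which the pipeline
is exercised:

| parameter | default | meaning |
| --- | --- | --- |
| `n_cell_lines` | 48 | training panel size typical of breast-cancer drug screens |
| `gi50_range` | [3.0, 6.5] | −log10 molar span covering the drugs' reported ranges |
| `planted_r` | 0.95 | exact in-sample \|r\| of planted genes with GI50 |
| `n_planted_angle_genes` | 14 | GI50-correlated genes (half direct, half inverse) |
| `n_curated` | 6 | planted genes designated as the curated seed list |
| `effect_size` | 2.0 | class-mean separation (SD units) of signature genes in patients |
| `imbalance` | 0.75 | resistant fraction of the patient cohort |
| `probe_dup_fraction` | 0.3 | genes emitted as two probes in the patient matrix |

The planted correlation is exact in-sample: the noise component is
residualized against GI50 and rescaled, so a planted gene's angle is
analytically `arccos(planted_r)` ≈ 18.2° for every seed. Recovery
under the 20° threshold is then a property of the traversal, not of
sampling luck, and the recovery criterion (≥90% of planted genes,
≤10% false inclusions over 20 seeds) tests the pipeline rather than
the generator. Planted chains never receive background edges between
their own members, so 1-node/2-node distances are unambiguous.

What the generator does *not* emulate: microarray-specific noise
(probe affinity, batch effects), correlated co-expression modules,
survival-type outcomes, or cohort-specific platform differences beyond
duplicate probes. Passing tests therefore show the machinery is
correct under its stated assumptions, not that real patient cohorts
will reach the same accuracies.

A note on the null: with `effect_size = 0` the patient cohort carries
no signal, and because the training panel is median-split (balanced),
an uninformative signature predicts roughly 50/50 — overall accuracy
falls to about 0.5, *below* the majority-class rate of an imbalanced
cohort. The null test asserts the correct bound (no better than
majority) rather than equality with the majority rate.

## Numerical choices and degenerate inputs

* Angle cosines are clipped to [−1, 1] before arccos; constant vectors
  raise a degenerate-variable error and the gene is skipped upstream
  with a report entry.
* Quantile normalization maps midranks onto the reference quantile
  grid by linear interpolation, so tied values receive the average of
  the quantiles they occupy; a reference of mismatched length is an
  error unless interpolation is explicitly enabled.
* A constant GI50 vector, a single-class label vector, or k larger
  than the smaller class are explicit errors, not silent degradations.
* All randomness (fold shuffling, candidate ordering, generators) is
  seeded; fixed seed ⇒ byte-identical outputs.

## Problem sizes

Unit tests run on down-scaled panels (30–40 lines, 30–40 genes); the
end-to-end acceptance checks use the full study conditions (48 lines,
120 genes, 20 seeds for recovery, one full 21-pair grid derivation for
patient prediction). The whole suite completes in well under a minute
on one CPU.

## Known limitations

* The MFA angle is measured in the plane of the first two global
  dimensions; with the per-gene block structure used here (≤3
  variables) that plane captures the variables essentially exactly,
  but the statistic is not a full multi-block MFA with partial axes.
* AUC-weighting on the prediction cohort is in-sample (see above).
* The per-gene MFA scores genes independently; co-expression between
  candidates is ignored at preselection and only handled implicitly
  by forward selection.
* Hub genes can recruit very large neighbourhoods; the optional
  neighbour cap is a blunt instrument and off by default.
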