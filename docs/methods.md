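# Methods

This note documents the models, conventions and numerical choices behind
`rationalqsar`, in the spirit of a statistical package's model description.

## The modelling problem

A qHTS campaign yields, per substance, a primary activity score (0–100), an
optional confirmatory retest score and an optional counterscreen score for
the assay's known artefact mechanism (luciferase stabilisation in
reporter-gene assays).  Typical campaigns test 10⁵–10⁶ substances of which
well under 1 % confirm active.  The package builds binary
structure–activity classifiers from such data while handling three
problems that dominate at this scale: label triage (artefact removal),
class imbalance, and the reliability (applicability domain) of predictions
far from the training chemistry.

## Curation

Rules are applied in a fixed order: parse → element whitelist (H, B, C, N,
O, F, Na, Mg, Si, P, S, Cl, K, Ca, Br, I; checked on the raw structure,
before desalting) → dissociation and neutralisation → mixture and
low-carbon filters → canonical SMILES → labelling → deduplication.

Neutralisation chemistry: components whose net formal charge is already
zero (including internal zwitterions such as charge-separated nitro groups)
are left untouched.  Net-charged *organic* components are neutralised by
protonating O⁻/S⁻/N⁻ anions and deprotonating N⁺ centres that carry a
hydrogen; a residual net charge (e.g. quaternary ammonium) removes the
record as a structural error.  Carbon-free components are treated as
dissociated counterions: they keep their charge and are discarded by the
parent selection.  "Organic" means "contains at least one carbon"; two or
more organic components is a mixture; a parent with fewer than two carbons
is removed.

Duplicates are grouped by canonical SMILES computed without stereo flags
(the models are 2-D).  Concordant groups keep one representative; groups
containing both an active and an inactive are removed entirely; a group
mixing inconclusive records with one conclusive label keeps a
representative carrying that conclusive label (and that representative is
chosen among the records whose own scores produce it, so stored labels
always re-derive from stored scores).

Inconclusive records survive curation but are excluded from modelling
datasets.

## Feature space

The substructure-key library is an open construction: the 163 MACCS keys
with concrete SMARTS definitions, extended by circular-environment
fragments (radii 1 and 2) mined from the training structures and kept when
they occur in at least 2 % of them (cap 300, most frequent first,
alphabetical tie-break).  The build is order-independent and the library is
serialised with every model, so fingerprints are reproducible.  Within one
workflow run the library is mined once from the training-side structures
(training actives plus the inactive selection pool) and held fixed across
the rational iterations, mirroring the fixed template libraries of
commercial engines; independent cross-validation instead rebuilds it from
each fold's own training portion.

Nine continuous descriptors accompany the keys: AlogP (Crippen), H-bond
acceptors and donors, Lipinski score (count of rule-of-five violations,
0–4), molecular weight (g/mol, of the input structure), parent atom number
(heavy atoms of the desalted parent), parent molecular weight, topological
polar surface area (Å²) and rotatable bonds.  For single-component inputs
MW equals parent MW.

Preselection keeps the top ⌈30 %⌉ of columns ranked by the Yates-corrected
χ² of feature presence against the label, ties broken by column order.
Continuous descriptors are binarised at their training-set median (strictly
greater → 1) *for the test only*; the continuous values enter the learner.
The χ² convention: zero when any margin is empty, and the continuity
correction clamps at zero.

## The learner

Partial logistic regression: the design matrix is standardised, PLS factors
are extracted against the centred binary response, and a logistic
regression on the factor scores yields the positive prediction probability
*p*.  The factor count (1…10) minimises PRESS over an internal 5-fold
split; within each fold the PLS is fitted once at the maximum factor count
and predictions for smaller counts are reconstructed from the NIPALS
weight/loading matrices (Bₖ = Wₖ(PₖᵀWₖ)⁻¹Qₖᵀ).  After the first fit,
features with effectively zero loadings (max |rotation| ≤ 1e-10) are
dropped and the model refitted once — a bounded stand-in for open-ended
iterative feature selection, capped for determinism.  A design with no
variable columns degenerates to an intercept-only model returning the
training base rate.

Ensembles: the *composite* model partitions the inactives at random
(seeded) into ⌈n_inactive/(ratio·n_active)⌉ chunks (default ratio 1:1) and
fits one sub-model per chunk on all actives plus that chunk; the *cocktail*
adds the full-training-set single model as an equal-weight member.  A
query's probability is the unweighted mean over the members whose
structural domain contains it; if no member qualifies the query is out of
the structural domain.

## Applicability domain and outcome categories

Structural domain, per member: maximum Jaccard similarity to that member's
training fingerprints ≥ 0.30 (inclusive; similarities are exact integer
ratios), all model descriptors computable, and at least one of the member's
selected key features present.  Class-probability refinement: NEG_IN for
p ≤ 0.3 and POS_IN for p ≥ 0.7 are in-domain; NEG_OUT (0.3, 0.4), INC_OUT
[0.4, 0.5) and POS_OUT [0.5, 0.7) are out.  The nominal grey-zone bands
overlap on [0.5, 0.6); since p ≥ 0.5 is a positive call, that interval is
assigned POS_OUT and INC_OUT ends at 0.5.  Coverage of a prediction set is
(#POS_IN + #NEG_IN)/N.

## Sampling design

Actives split 90/10 into training and external test (test count rounded to
nearest).  A fixed-size selection pool of inactives is drawn; the remainder
becomes test inactives.  The first model trains on a 2:1
inactive-to-active draw.  Each rational iteration predicts the untouched
pool in the current model and adds n/4 inactives from each of the four
informative strata — out of structural domain, POS_OUT, NEG_OUT, POS_IN —
drawing uniformly within a stratum.  A stratum short of its quota
contributes everything and the deficit moves to the largest remaining
stratum; if *all* strata run dry the draw returns what exists (the
workflow then stops the arm — the model has consumed every informative
candidate).  At desk scale the expansion size is rounded down to a multiple
of four.  The reference arm draws the same number of inactives purely at
random.  Final models fold the external test actives plus four random pool
inactives apiece back into the training set; external validation of a
final model is for specificity only, on inactives never seen in training.

All randomness flows from one master seed through named substreams
(split, draws, per-iteration expansions, sub-model partitions, folds), so
adding a stage never perturbs another, and reruns are byte-identical
(verified by output hashing in the workflow manifest).

## Validation conventions

Cooper statistics are computed on in-domain predictions: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), balanced accuracy their mean.
Reported percentages round half-up to one decimal, and the reported
balanced accuracy is the mean of the *rounded* sensitivity and
specificity — the convention printed validation tables follow (unrounded
values are retained).  PPV/NPV re-express a classifier under an assumed
prevalence π: PPV = sπ/(sπ + (1−c)(1−π)), NPV = c(1−π)/(c(1−π) + (1−s)π);
when reproducing printed table cells the rounded sensitivity/specificity
are the inputs.  Model agreement uses the standard MCC on the 2×2 table of
paired calls; a zero margin yields 0 by convention.

Cross-validation is 2×5 stratified and fully independent: each fold-model
rebuilds vocabulary, preselection and the cocktail from its own 80 %.
Pooled in-domain confusion counts are reported together with the mean ± sd
of sensitivity, specificity, balanced accuracy and coverage across the ten
fold-models (sd, not SEM).  Y-randomisation scrambles the labels into a
half/half assignment (⌈N/2⌉ actives) and repeats the cross-validation.

A note on Y-randomisation at small scale: under scrambled labels the
probability refinement retains few confident predictions, and those that
remain have calls independent of the scrambled truth — so sensitivity
approximates the positive-call rate q and specificity 1−q, each noisy,
while balanced accuracy self-centres at 50 %.  The chance-level check is
therefore asserted on balanced accuracy.

## The synthetic universe

The generator emulates the statistical structure the pipeline assumes, not
real medicinal chemistry.  Molecules are scaffold-plus-decoration strings
over whitelist elements (5–40 heavy atoms): actives carry planted
heteroarene alert scaffolds (indole, pyrrole, benzofuran, pyrimidine) with
probability `alert_penetrance`; inactives carry plain scaffolds, half of
them decorated with inactivating motifs (sulfonamide, carboxylic acid); a
`decoy_fraction` of inactives instead sit inside the actives' cluster —
alert scaffold, plain decorations — as false-positive bait, the situation
rational sampling is designed to exploit.  Label noise flips a fraction of
the actives plus an equal *number* of inactives, so a 0.4 %-active universe
is not swamped by flipped majority labels.  Contaminants (salts, mixtures,
low-carbon species, disallowed elements, concordant and conflicting
duplicates) are injected at configured rates with their expected curation
outcome tagged, and assay-score triples are generated consistently with the
labelling rules, including a configurable fraction of luciferase
interferers whose ground truth is inconclusive.

Defaults are the study conditions: 20 actives among 5,000 molecules
(0.4 % prevalence), penetrance 0.9, label noise 0.02, small contaminant
rates.  Tests exercising learner behaviour use explicitly passed
desk-scale configurations (e.g. a clean 200/800 separable set), stated in
each test.  What passing tests show about real data is deliberately
limited: the generator has no activity cliffs, no tautomerism, no
correlated assay noise, and its chemical diversity is a few scaffolds wide,
so results demonstrate correctness of the machinery and the *direction* of
the rational-sampling effect, not real-world performance levels.

## Problem sizes

The default test suite and the acceptance script run at desk scale by
design: statistics from published confusion tables are exact and instant;
model-level properties use 10²–10³-molecule fixtures; the end-to-end study
runs the full 0.4 %-prevalence universe of ~5,000 molecules; the
rational-vs-random comparison repeats a 960-molecule study over five seeds.
Full-scale splits (925/204,513 with a 50,000-inactive pool) are exercised
where only identifier bookkeeping is involved.

## Known limitations

* The PLR learner is a principled stand-in (PLS + logistic via
  scikit-learn); commercial implementations differ in feature libraries
  (≫10⁴ keys) and in their probability spread, which affects coverage under
  the probability refinement.
* Printed PPV/NPV cells at 5 % and 10 % prevalence in some published tables
  are not always consistent with the closed-form prevalence adjustment;
  only the 1 %-prevalence arithmetic is treated as an anchor.
* No tautomer standardisation, stereochemistry, 3-D descriptors or pKa.
* Diversity-based selection (maximin, clustering) and
  uncertainty-sampling active learning are out of scope; the four-stratum
  rule is the only rational selector.
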