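# rationalqsar

Binary QSAR classifiers for **large, highly imbalanced bioassay datasets** —
the situation faced when a quantitative high-throughput screen (qHTS) tests
hundreds of thousands of substances and well under 1 % confirm active.  The
package is aimed at computational toxicologists and cheminformaticians who
need global structure–activity classifiers (e.g. for nuclear-receptor or
reporter-gene endpoints such as AhR activation) together with an honest
applicability domain and audit-ready training-set provenance.

## What it does

* **Curation** — turns raw `id, smiles, score_primary, score_confirm,
  score_counter` tables (or SDF) into a unique, QSAR-ready dataset: element
  whitelist, error removal, dissociation + neutralisation, mixture and
  low-carbon filters, canonical SMILES, duplicate handling.  Activity labels
  follow the qHTS triage: *active* iff the confirmatory score is 10–100 **and**
  the luciferase counterscreen is 0; *inactive* iff the primary score is 0;
  everything else *inconclusive*.
* **Features** — a binary substructure-key fingerprint (open key library:
  the 163 concrete MACCS SMARTS plus fragments mined from the training
  structures) and nine continuous descriptors (AlogP, HBA, HBD, Lipinski
  score, MW, parent atom number, parent MW, PSA, rotatable bonds).
  Columns are preselected by the top 30 % of Yates-corrected χ² scores
  against the binary response.
* **Model** — partial logistic regression (PLR): PLS factors extracted on
  the binary response treated as continuous, the factor count chosen by
  minimising cross-validated PRESS, then logistic regression on the factor
  scores.  For imbalanced sets the **cocktail** ensemble combines the
  full-training-set model with balanced sub-models (all actives + one chunk
  of a random partition of the inactives); the positive prediction
  probability *p* is the unweighted mean over the members whose structural
  domain contains the query.
* **Applicability domain** — structural domain (Jaccard/Tanimoto ≥ 0.30 to a
  member's training structure, descriptors computable, ≥ 1 model feature)
  plus class-probability refinement: in-domain calls require *p* ≥ 0.7
  (POS_IN) or *p* ≤ 0.3 (NEG_IN); the grey zone splits into NEG_OUT, INC_OUT
  and POS_OUT.
* **Rational sampling** — iterative enrichment of the training inactives
  from four prediction strata of the previous model (out of structural
  domain, POS_OUT, NEG_OUT, and POS_IN = confirmed false positives), with a
  size-matched random reference arm and final-model assembly.
* **Validation** — Cooper statistics (sensitivity, specificity, balanced
  accuracy) on in-domain predictions, prevalence-adjusted PPV/NPV,
  independent repeated stratified k-fold cross-validation with full
  per-fold rebuilds, Y-randomisation, and model-agreement MCC.
* **Alerts** — activity alerts ranked by |baseline − x̄|·χ² and pure-inactivity
  alerts by χ².
* **Synthetic fixtures** — a seeded generator producing an imbalanced SMILES
  universe with planted heteroarene alerts, decoy inactives, label noise and
  curation contaminants, so the whole pipeline is testable offline.

## Worked example

```python
import numpy as np
from rationalqsar import (
    CocktailQSAR, FixtureConfig, build_vocabulary, curate, make_dataset,
    ConfusionCounts, cooper, predictive_values,
)

config = FixtureConfig(n_active=200, n_inactive=800, alert_penetrance=1.0,
                       label_noise=0.0, decoy_fraction=0.0,
                       interferer_fraction=0.0, contaminant_rates={}, seed=11)
kept = curate(make_dataset(config)).kept_frame()
labels = (kept["label"] == "ACTIVE").astype(int).to_numpy()
smiles = kept["canonical_smiles"].tolist()

vocabulary = build_vocabulary(smiles)
model = CocktailQSAR.from_smiles(smiles, labels, vocabulary, kept["id"].tolist())
results = model.fit(seed=3)
print(results.summary())
```

```
Cocktail QSAR results
====================================================
training set:      200 actives, 800 inactives
vocabulary size:   313 keys + 9 descriptors
members:           5 (1 full + 4 sub-models)
seed:              3
----------------------------------------------------
member      n_act  n_inact  factors  features
full          200      800       10        97
sub-0         200      200       10        97
...
```

The 800 inactives split into four balanced chunks, so the cocktail has five
members (one full model plus four sub-models), each keeping 97 features
after χ² preselection and zero-loading pruning.  Predictions carry the
probability, the call and the outcome category:

```python
print(results.predict(model.features)[["id", "p", "call", "category", "in_ad"]].head(3))
```

```
    id        p   call category  in_ad
a00000 0.999076 active   POS_IN      1
a00001 0.999076 active   POS_IN      1
a00002 0.999024 active   POS_IN      1
```

Validation statistics work directly from confusion counts.  For a test-set
confusion of TP 40 / TN 114,977 / FP 3,475 / FN 7:

```python
stats = cooper(ConfusionCounts(tp=40, tn=114_977, fp=3_475, fn=7)).rounded()
# sensitivity 85.1, specificity 97.1, balanced accuracy 91.1
ppv, npv = predictive_values(stats.sensitivity / 100, stats.specificity / 100, 0.01)
# PPV 22.9 %, NPV 99.8 % at an assumed 1 % prevalence of actives
```

A PPV of 22.9 % at 1 % prevalence is the practical meaning of a
high-specificity screen: roughly one in four positive calls is a true
active even though only one substance in a hundred is active at all.

The full study design (curation → split → 2:1 model → rational expansions →
random arm → final models → validation → alerts → screening) runs from one
config:

```bash
rationalqsar run-all config.yaml     # or: rationalqsar --help
```

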