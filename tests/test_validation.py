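"""Cooper statistics, predictive values, MCC, CV, Y-randomisation, external validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rationalqsar._util import round_half_up
from rationalqsar.validation import (
    ConfusionCounts,
    cooper,
    crossvalidate,
    external_validate,
    mcc_from_agreement,
    predictive_values,
    y_randomize,
)


def test_cooper_cocktail_crossvalidation_row():
    stats = cooper(ConfusionCounts(tp=544, tn=1264, fp=104, fn=68)).rounded()
    assert stats.sensitivity == 88.9
    assert stats.specificity == 92.4
    assert stats.balanced_accuracy == 90.7  # mean of the rounded components


def test_cooper_external_validation_column():
    stats = cooper(ConfusionCounts(tp=40, tn=114_977, fp=3_475, fn=7)).rounded()
    assert stats.sensitivity == 85.1
    assert stats.specificity == 97.1
    assert stats.balanced_accuracy == 91.1


def test_cooper_perfect_classifier():
    stats = cooper(ConfusionCounts(tp=10, tn=20, fp=0, fn=0))
    assert (stats.sensitivity, stats.specificity, stats.balanced_accuracy) == (100, 100, 100)


def test_cooper_requires_both_classes():
    with pytest.raises(ValueError):
        cooper(ConfusionCounts(tp=0, tn=5, fp=5, fn=0))


@settings(max_examples=1000, deadline=None, derandomize=True)
@given(st.tuples(st.integers(1, 500), st.integers(1, 500),
                 st.integers(0, 500), st.integers(0, 500)))
def test_cooper_matches_brute_force(counts):
    tp, tn, fp, fn = counts
    stats = cooper(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
    assert stats.sensitivity == pytest.approx(100 * tp / (tp + fn), abs=1e-9)
    assert stats.specificity == pytest.approx(100 * tn / (tn + fp), abs=1e-9)
    assert stats.balanced_accuracy == pytest.approx(
        (stats.sensitivity + stats.specificity) / 2, abs=1e-9
    )


def test_ppv_at_one_percent_prevalence():
    ppv, npv = predictive_values(0.851, 0.971, 0.01)
    assert round_half_up(ppv, 1) == 22.9
    assert round_half_up(npv, 1) == 99.8


def test_predictive_values_perfect_model():
    assert predictive_values(1.0, 1.0, 0.05) == (100.0, 100.0)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.floats(0.05, 0.99), st.floats(0.05, 0.99),
       st.floats(0.01, 0.5), st.floats(0.01, 0.49))
def test_ppv_monotone_in_prevalence(s, c, pi, delta):
    ppv_lo, _ = predictive_values(s, c, pi)
    ppv_hi, _ = predictive_values(s, c, min(pi + delta, 0.99))
    assert ppv_hi >= ppv_lo - 1e-12


def test_predictive_values_degenerate_prevalence():
    assert predictive_values(0.9, 0.9, 0.0) == (0.0, 100.0)


@settings(max_examples=500, deadline=None, derandomize=True)
@given(st.tuples(st.integers(0, 300), st.integers(0, 300),
                 st.integers(0, 300), st.integers(0, 300)))
def test_predictive_values_match_bayes_brute_force(counts):
    s_num, s_den, c_num, c_den = counts
    s = s_num / max(s_num + s_den, 1)
    c = c_num / max(c_num + c_den, 1)
    pi = 0.07
    ppv, npv = predictive_values(s, c, pi)
    den_p = s * pi + (1 - c) * (1 - pi)
    den_n = c * (1 - pi) + (1 - s) * pi
    assert ppv == pytest.approx(0.0 if den_p == 0 else 100 * s * pi / den_p, abs=1e-9)
    assert npv == pytest.approx(0.0 if den_n == 0 else 100 * c * (1 - pi) / den_n, abs=1e-9)


def test_model_agreement_mcc_printed_counts():
    assert mcc_from_agreement(1135, 38_305, 4, 34) == pytest.approx(0.983, abs=5e-4)


def test_mcc_perfect_agreement_and_symmetry():
    assert mcc_from_agreement(10, 20, 0, 0) == 1.0
    assert mcc_from_agreement(7, 11, 3, 5) == mcc_from_agreement(7, 11, 5, 3)


def test_mcc_zero_margin_convention():
    # both models call everything negative: a margin is empty
    assert mcc_from_agreement(0, 10, 0, 0) == 0.0


def test_mcc_total_disagreement_is_minus_one():
    assert mcc_from_agreement(0, 0, 3, 5) == -1.0


# ---------------------------------------------------------------------------
# model-level validation (heavier, seeded)


def test_crossvalidation_on_separable_fixture(separable_dataset):
    """Independent 2x5 CV on the planted-alert set: mean BA in [85, 100]."""
    kept, labels = separable_dataset
    report = crossvalidate(
        kept["canonical_smiles"].tolist(), labels, master_seed=17,
        prevalences=(0.01,),
    )
    assert 85.0 <= report.balanced_accuracy <= 100.0
    assert len(report.per_fold) == 10
    assert report.dispersion["balanced_accuracy"] >= 0.0
    # fold membership partitions the set per repeat
    for repeat in (0, 1):
        folds = report.per_fold[report.per_fold["repeat"] == repeat]
        assert folds["tp"].sum() + folds["fn"].sum() <= labels.sum()


def test_crossvalidation_label_permuted_control(separable_dataset):
    """Permuted labels collapse to chance: mean BA within 50 +/- 5."""
    kept, labels = separable_dataset
    rng = np.random.default_rng(23)
    permuted = labels.copy()
    rng.shuffle(permuted)
    report = crossvalidate(kept["canonical_smiles"].tolist(), permuted, master_seed=23)
    assert 45.0 <= report.balanced_accuracy <= 55.0


def test_y_randomization_collapses_to_chance(separable_dataset):
    """Half/half scrambled labels leave no predictive value: BA = 50 +/- 10.

    Scrambled labels are independent of the structure-driven calls, so the
    positive-call rate q gives sensitivity ~ q and specificity ~ 1-q; their
    mean self-centres at 50 % however few predictions survive the
    probability-refinement domain.
    """
    kept, labels = separable_dataset
    report = y_randomize(kept["canonical_smiles"].tolist(), labels, master_seed=31)
    assert report.confusion.total > 0
    assert 40.0 <= report.balanced_accuracy <= 60.0
    n = len(kept)
    assert f"{int(np.ceil(n / 2))} assigned active" in report.notes[0]


def test_y_randomization_rejects_tiny_sets():
    with pytest.raises(ValueError):
        y_randomize(["CCO"] * 5, np.array([1, 0, 1, 0, 1]))


def test_external_validation_leakage_rejected(fitted_cocktail):
    with pytest.raises(ValueError, match="leakage"):
        external_validate(
            fitted_cocktail, ["CCO"], np.array([0]), ["x1"], ["x1", "x2"]
        )


def test_external_validation_on_heldout(separable_dataset):
    from rationalqsar.features import build_vocabulary
    from rationalqsar.qsar import CocktailQSAR

    kept, labels = separable_dataset
    n = len(kept)
    rng = np.random.default_rng(13)
    holdout = np.sort(rng.choice(n, size=n // 5, replace=False))
    train = np.setdiff1d(np.arange(n), holdout)
    smiles = kept["canonical_smiles"].tolist()
    ids = kept["id"].tolist()
    train_smiles = [smiles[i] for i in train]
    vocabulary = build_vocabulary(train_smiles)
    results = CocktailQSAR.from_smiles(train_smiles, labels[train], vocabulary).fit(seed=2)
    report = external_validate(
        results,
        [smiles[i] for i in holdout],
        labels[holdout],
        [ids[i] for i in holdout],
        [ids[i] for i in train],
    )
    assert report.confusion.total > 0
    assert report.balanced_accuracy >= 85.0
    # coverage bookkeeping is internally consistent
    n_act = (labels[holdout] == 1).sum()
    n_inact = (labels[holdout] == 0).sum()
    recomputed = (report.coverage_actives * n_act + report.coverage_inactives * n_inact) / (
        n_act + n_inact
    )
    assert report.coverage == pytest.approx(recomputed)
    assert 0.01 in report.predictive
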