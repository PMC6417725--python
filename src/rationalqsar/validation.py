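"""Validation statistics: Cooper statistics, prevalence-adjusted predictive
values, independent repeated k-fold cross-validation, Y-randomisation,
external validation, and model-agreement MCC.

Cooper statistics (sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
balanced accuracy = their mean) are computed on in-domain predictions only.
Reported percentages are rounded half-up to one decimal, and the *reported*
balanced accuracy is the mean of the rounded sensitivity and specificity —
the convention printed validation tables follow; unrounded values are kept
alongside.  Positive and negative predictive values are re-expressed under
assumed prevalences π of actives in the screened universe:

    PPV = s·π / (s·π + (1−c)(1−π)),   NPV = c(1−π) / (c(1−π) + (1−s)π)

with s = sensitivity and c = specificity as fractions.

Cross-validation is fully independent: each fold-model rebuilds the key
vocabulary, the χ² preselection and the cocktail ensemble from its own 80 %
only, then predicts its held-out 20 %.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._util import round_half_up, substream
from .domain import OutcomeCategory
from .features import VocabConfig, build_vocabulary
from .qsar import CocktailQSAR, ModelConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class CooperStats:
    """Sensitivity/specificity/balanced accuracy in percent (unrounded)."""

    sensitivity: float
    specificity: float
    balanced_accuracy: float

    def rounded(self) -> "CooperStats":
        s = round_half_up(self.sensitivity, 1)
        c = round_half_up(self.specificity, 1)
        return CooperStats(s, c, round_half_up((s + c) / 2.0, 1))


def cooper(confusion: ConfusionCounts) -> CooperStats:
    """Cooper statistics from a confusion table, in percent."""
    if confusion.tp + confusion.fn == 0 or confusion.tn + confusion.fp == 0:
        raise ValueError("both classes must be present to compute Cooper statistics")
    sens = 100.0 * confusion.tp / (confusion.tp + confusion.fn)
    spec = 100.0 * confusion.tn / (confusion.tn + confusion.fp)
    return CooperStats(sens, spec, (sens + spec) / 2.0)


def predictive_values(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """(PPV, NPV) in percent from fractional sensitivity/specificity/prevalence."""
    s, c, pi = float(sensitivity), float(specificity), float(prevalence)
    for name, v in (("sensitivity", s), ("specificity", c), ("prevalence", pi)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
    if pi in (0.0, 1.0):
        logger.warning("degenerate prevalence %s; returning limit values", pi)
        return (0.0, 100.0) if pi == 0.0 else (100.0, 0.0)
    ppv_den = s * pi + (1 - c) * (1 - pi)
    npv_den = c * (1 - pi) + (1 - s) * pi
    ppv = 100.0 * s * pi / ppv_den if ppv_den > 0 else 0.0
    npv = 100.0 * c * (1 - pi) / npv_den if npv_den > 0 else 0.0
    return ppv, npv


def mcc_from_agreement(
    n_both_pos: int, n_both_neg: int, n_disagree_ab: int, n_disagree_ba: int
) -> float:
    """Matthews correlation between two models' calls on a shared set.

    ``n_disagree_ab`` counts items model A called positive and B negative,
    ``n_disagree_ba`` the reverse; the statistic is symmetric in the two
    models.  A zero margin yields 0 by convention.
    """
    a, d, b, c = n_both_pos, n_both_neg, n_disagree_ab, n_disagree_ba
    if min(a, b, c, d) < 0:
        raise ValueError("agreement counts must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("empty agreement table")
    denom = (a + b) * (a + c) * (d + b) * (d + c)
    if denom == 0:
        logger.warning("zero margin in agreement table; MCC set to 0")
        return 0.0
    return (a * d - b * c) / math.sqrt(denom)


# ---------------------------------------------------------------------------
# reports


@dataclass
class ValidationReport:
    """Statistics of one validation exercise (external or pooled CV)."""

    confusion: ConfusionCounts | None
    sensitivity: float | None
    specificity: float | None
    balanced_accuracy: float | None
    coverage: float | None
    coverage_actives: float | None = None
    coverage_inactives: float | None = None
    predictive: dict[float, tuple[float, float]] = field(default_factory=dict)
    per_fold: pd.DataFrame | None = None
    dispersion: dict[str, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "confusion": self.confusion.__dict__ if self.confusion else None,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "coverage": self.coverage,
            "coverage_actives": self.coverage_actives,
            "coverage_inactives": self.coverage_inactives,
            "predictive_values": {
                str(k): {"ppv": v[0], "npv": v[1]} for k, v in self.predictive.items()
            },
            "dispersion": self.dispersion,
            "notes": self.notes,
        }
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = ["Validation report", "=" * 40]
        if self.confusion:
            c = self.confusion
            lines.append(f"TP {c.tp}  TN {c.tn}  FP {c.fp}  FN {c.fn}")
        for name in ("sensitivity", "specificity", "balanced_accuracy"):
            value = getattr(self, name)
            if value is not None:
                sd = self.dispersion.get(name)
                tail = f" ± {sd:.1f}" if sd is not None else ""
                lines.append(f"{name:>18}: {round_half_up(value, 1):.1f}%{tail}")
        if self.coverage is not None:
            sd = self.dispersion.get("coverage")
            tail = f" ± {sd:.1f}" if sd is not None else ""
            lines.append(f"{'coverage':>18}: {round_half_up(self.coverage, 1):.1f}%{tail}")
        for prev, (ppv, npv) in self.predictive.items():
            lines.append(
                f"  prevalence {prev:.0%}: PPV {round_half_up(ppv, 1):.1f}%"
                f"  NPV {round_half_up(npv, 1):.1f}%"
            )
        lines.extend(self.notes)
        return "\n".join(lines)


def _confusion_from_predictions(predictions: pd.DataFrame, labels: np.ndarray) -> ConfusionCounts:
    """In-domain confusion counts from a prediction table and true labels."""
    in_ad = predictions["in_ad"].to_numpy(dtype=bool)
    pos = predictions["category"].to_numpy() == OutcomeCategory.POS_IN.value
    y = np.asarray(labels, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum(in_ad & pos & (y == 1))),
        tn=int(np.sum(in_ad & ~pos & (y == 0))),
        fp=int(np.sum(in_ad & pos & (y == 0))),
        fn=int(np.sum(in_ad & ~pos & (y == 1))),
    )


def crossvalidate(
    smiles: list[str],
    labels: np.ndarray,
    model_config: ModelConfig = ModelConfig(),
    vocab_config: VocabConfig = VocabConfig(),
    repeats: int = 2,
    folds: int = 5,
    master_seed: int = 0,
    prevalences: tuple[float, ...] = (),
) -> ValidationReport:
    """Repeated stratified k-fold CV with full per-fold model rebuilds.

    Vocabulary, preselection and the cocktail ensemble are rebuilt from each
    fold's own training 80 %; the held-out 20 % is predicted and pooled.
    Reported dispersion is the sd of each statistic across the fold-models.
    """
    labels = np.asarray(labels, dtype=int)
    smiles = list(smiles)
    fold_rows = []
    pooled = np.zeros(4, dtype=int)  # tp, tn, fp, fn
    for repeat in range(repeats):
        splitter = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=substream(master_seed, f"cv-{repeat}")
        )
        for fold, (train_idx, test_idx) in enumerate(splitter.split(smiles, labels)):
            for attempt in range(5):
                if len(np.unique(labels[train_idx])) == 2:
                    break
                rng_seed = substream(master_seed, f"cv-refold-{repeat}-{fold}-{attempt}")
                resplit = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
                train_idx, test_idx = next(iter(resplit.split(smiles, labels)))
            train_smiles = [smiles[i] for i in train_idx]
            vocabulary = build_vocabulary(train_smiles, vocab_config)
            spec = CocktailQSAR.from_smiles(
                train_smiles, labels[train_idx], vocabulary, config=model_config
            )
            results = spec.fit(seed=substream(master_seed, f"cv-fit-{repeat}-{fold}"))
            predictions = results.predict_smiles([smiles[i] for i in test_idx])
            assert not set(train_idx) & set(test_idx), "fold leakage"
            conf = _confusion_from_predictions(predictions, labels[test_idx])
            pooled += (conf.tp, conf.tn, conf.fp, conf.fn)
            in_ad_pct = 100.0 * predictions["in_ad"].mean()
            row = {"repeat": repeat, "fold": fold, "ad_pct": in_ad_pct, **conf.__dict__}
            if conf.tp + conf.fn > 0 and conf.tn + conf.fp > 0:
                stats = cooper(conf)
                row.update(
                    sensitivity=stats.sensitivity,
                    specificity=stats.specificity,
                    balanced_accuracy=stats.balanced_accuracy,
                )
            fold_rows.append(row)
    per_fold = pd.DataFrame(fold_rows)
    conf = ConfusionCounts(*[int(v) for v in pooled])
    dispersion = {
        name: float(per_fold[name].std(ddof=1))
        for name in ("sensitivity", "specificity", "balanced_accuracy")
        if name in per_fold
    }
    dispersion["coverage"] = float(per_fold["ad_pct"].std(ddof=1))
    report = ValidationReport(
        confusion=conf,
        sensitivity=float(per_fold["sensitivity"].mean()),
        specificity=float(per_fold["specificity"].mean()),
        balanced_accuracy=float(per_fold["balanced_accuracy"].mean()),
        coverage=float(per_fold["ad_pct"].mean()),
        per_fold=per_fold,
        dispersion=dispersion,
    )
    for prev in prevalences:
        report.predictive[prev] = predictive_values(
            report.sensitivity / 100.0, report.specificity / 100.0, prev
        )
    return report


def y_randomize(
    smiles: list[str],
    labels: np.ndarray,
    model_config: ModelConfig = ModelConfig(),
    vocab_config: VocabConfig = VocabConfig(),
    repeats: int = 2,
    folds: int = 5,
    master_seed: int = 0,
) -> ValidationReport:
    """Scramble labels into a random half/half assignment and re-validate.

    A sound pipeline collapses to chance level (sensitivity and specificity
    near 50 %), demonstrating the absence of chance correlation in the real
    model.  The caller's label array is not modified.
    """
    n = len(smiles)
    if n < 10:
        raise ValueError("Y-randomisation needs at least 10 substances")
    scrambled = np.zeros(n, dtype=int)
    scrambled[: int(np.ceil(n / 2))] = 1
    rng = np.random.default_rng(substream(master_seed, "y-randomize"))
    scrambled = scrambled[rng.permutation(n)]
    report = crossvalidate(
        smiles,
        scrambled,
        model_config,
        vocab_config,
        repeats=repeats,
        folds=folds,
        master_seed=substream(master_seed, "y-randomize-cv"),
    )
    report.notes.append(
        f"Y-randomisation: {int(scrambled.sum())} assigned active,"
        f" {int(n - scrambled.sum())} inactive"
    )
    return report


def external_validate(
    results,
    test_smiles: list[str],
    test_labels: np.ndarray,
    test_ids: list[str],
    train_ids: list[str],
    prevalences: tuple[float, ...] = (0.01, 0.05, 0.10),
) -> ValidationReport:
    """External validation on a disjoint test set; in-domain statistics only."""
    overlap = set(map(str, test_ids)) & set(map(str, train_ids))
    if overlap:
        raise ValueError(f"test/training leakage: {sorted(overlap)[:5]}")
    labels = np.asarray(test_labels, dtype=int)
    predictions = results.predict_smiles(list(test_smiles), list(test_ids))
    conf = _confusion_from_predictions(predictions, labels)
    in_ad = predictions["in_ad"].to_numpy(dtype=bool)
    cov_total = 100.0 * in_ad.mean()
    cov_act = 100.0 * in_ad[labels == 1].mean() if (labels == 1).any() else None
    cov_inact = 100.0 * in_ad[labels == 0].mean() if (labels == 0).any() else None
    report = ValidationReport(
        confusion=conf,
        sensitivity=None,
        specificity=None,
        balanced_accuracy=None,
        coverage=cov_total,
        coverage_actives=cov_act,
        coverage_inactives=cov_inact,
    )
    if conf.tp + conf.fn > 0 and conf.tn + conf.fp > 0:
        stats = cooper(conf)
        report.sensitivity = stats.sensitivity
        report.specificity = stats.specificity
        report.balanced_accuracy = stats.balanced_accuracy
        for prev in prevalences:
            report.predictive[prev] = predictive_values(
                stats.sensitivity / 100.0, stats.specificity / 100.0, prev
            )
    else:
        report.notes.append("a class is absent among in-domain predictions; Cooper statistics undefined")
        if conf.tn + conf.fp > 0:
            report.specificity = 100.0 * conf.tn / (conf.tn + conf.fp)
    return report
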