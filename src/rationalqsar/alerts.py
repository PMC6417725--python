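"""Structural-alert ranking from training-set feature statistics.

Activity alerts are ranked by ``|baseline − x̄| · χ²`` where ``x̄`` is the
fraction of actives among the training structures containing the feature,
``baseline`` the active fraction of the whole training set (0.2 for a 1:4
active:inactive set), and χ² the Yates-corrected independence test of the
feature/label table.  The score rewards features that are both strongly
over- (or under-)represented in one class and statistically significant; an
alert can be positive even when it occurs in more inactives than actives,
as long as x̄ clears the baseline significantly.

Inactivity alerts are ranked by χ² alone among the "pure" inactivity
features — those never occurring in an active structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import yates_chi2


@dataclass
class FeatureScore:
    feature: str
    index: int
    n_active_with: int
    n_inactive_with: int
    x_bar: float
    chi2: float
    activity_score: float
    pure_inactivity: bool

    @property
    def display_counts(self) -> str:
        """Counts shown 'n_active over n_inactive', the alert-card convention."""
        return f"{self.n_active_with} over {self.n_inactive_with}"


def _feature_counts(feature_matrix: np.ndarray, labels: np.ndarray):
    x = np.asarray(feature_matrix, dtype=np.int64)
    y = np.asarray(labels, dtype=np.int64)
    n_active_with = y @ x
    n_inactive_with = (1 - y) @ x
    return n_active_with, n_inactive_with, int(y.sum()), int((1 - y).sum())


def score_activity_features(
    feature_matrix: np.ndarray,
    labels: np.ndarray,
    feature_names: list[str] | None = None,
    baseline: float | None = None,
) -> list[FeatureScore]:
    """Rank features by |baseline − x̄|·χ², descending.

    ``baseline`` defaults to the active fraction of the scored training set.
    Features present in zero structures are excluded (x̄ undefined); ties
    break by χ² then feature order.
    """
    n_act_with, n_inact_with, n_active, n_inactive = _feature_counts(feature_matrix, labels)
    total = n_active + n_inactive
    if baseline is None:
        baseline = n_active / total
    if not (0.0 < baseline < 1.0):
        raise ValueError(f"baseline must lie in (0, 1), got {baseline}")
    names = feature_names or [f"f{i}" for i in range(len(n_act_with))]
    scores = []
    for i, (na, ni) in enumerate(zip(n_act_with, n_inact_with)):
        occurrences = int(na) + int(ni)
        if occurrences == 0:
            continue
        x_bar = int(na) / occurrences
        chi2 = yates_chi2(int(na), n_active - int(na), int(ni), n_inactive - int(ni))
        scores.append(
            FeatureScore(
                feature=names[i],
                index=i,
                n_active_with=int(na),
                n_inactive_with=int(ni),
                x_bar=x_bar,
                chi2=chi2,
                activity_score=abs(baseline - x_bar) * chi2,
                pure_inactivity=int(na) == 0,
            )
        )
    scores.sort(key=lambda s: (-s.activity_score, -s.chi2, s.index))
    return scores


def score_inactivity_features(
    feature_matrix: np.ndarray,
    labels: np.ndarray,
    feature_names: list[str] | None = None,
) -> list[FeatureScore]:
    """Rank pure-inactivity features (never in an active) by χ², descending."""
    n_act_with, n_inact_with, n_active, n_inactive = _feature_counts(feature_matrix, labels)
    names = feature_names or [f"f{i}" for i in range(len(n_act_with))]
    scores = []
    for i, (na, ni) in enumerate(zip(n_act_with, n_inact_with)):
        if int(na) != 0 or int(ni) == 0:
            continue
        chi2 = yates_chi2(0, n_active, int(ni), n_inactive - int(ni))
        scores.append(
            FeatureScore(
                feature=names[i],
                index=i,
                n_active_with=0,
                n_inactive_with=int(ni),
                x_bar=0.0,
                chi2=chi2,
                activity_score=0.0,
                pure_inactivity=True,
            )
        )
    scores.sort(key=lambda s: (-s.chi2, s.index))
    return scores


def report_top_features(
    activity_scores: list[FeatureScore],
    inactivity_scores: list[FeatureScore],
    k: int = 10,
) -> pd.DataFrame:
    """Top-k alert table for both directions, ready for CSV export."""
    rows = []
    for direction, scores in (("activity", activity_scores), ("inactivity", inactivity_scores)):
        for rank, s in enumerate(scores[: max(k, 0)], start=1):
            rows.append(
                {
                    "direction": direction,
                    "rank": rank,
                    "feature": s.feature,
                    "n_active": s.n_active_with,
                    "n_inactive": s.n_inactive_with,
                    "counts": s.display_counts,
                    "x_bar": s.x_bar,
                    "chi2": s.chi2,
                    "score": s.activity_score if direction == "activity" else s.chi2,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "direction",
            "rank",
            "feature",
            "n_active",
            "n_inactive",
            "counts",
            "x_bar",
            "chi2",
            "score",
        ],
    )
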