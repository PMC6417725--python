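"""Training/test splits and iterative rational training-set expansion.

The study design for a heavily imbalanced dataset: actives are split 90/10
into training and external test; a fixed-size selection pool of inactives is
drawn (the rest become test inactives); the first model trains on a 2:1
inactive:active draw from the pool; subsequent "rational" iterations predict
the remaining pool in the current model and add equal numbers of inactives
from four prediction strata — out of structural domain, POS_OUT, NEG_OUT and
POS_IN (the last being confirmed false positives) — while a reference arm
adds the same number of inactives purely at random.  Finally the held-out
test actives (plus a multiple of random pool inactives) are folded in to
assemble the final training set.

All randomness flows from one master seed through named substreams; every
drawn inactive carries a lineage record (iteration, stratum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import rng_for
from .domain import OutcomeCategory

logger = logging.getLogger(__name__)

#: The four prediction strata mined for rational inactive selection.
RATIONAL_STRATA = (
    OutcomeCategory.OUT_STRUCTURAL,
    OutcomeCategory.POS_OUT,
    OutcomeCategory.NEG_OUT,
    OutcomeCategory.POS_IN,
)


@dataclass
class SplitPlan:
    test_actives: list[str]
    train_actives: list[str]
    selection_pool: list[str]
    test_inactives: list[str]
    seed: int

    def validate(self) -> None:
        sets = [
            set(self.test_actives),
            set(self.train_actives),
            set(self.selection_pool),
            set(self.test_inactives),
        ]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise AssertionError("split sets are not pairwise disjoint")


@dataclass
class TrainingSetLineage:
    """Audit trail: which iteration and stratum each training inactive came from."""

    rows: list[tuple[str, int, str]] = field(default_factory=list)

    def add(self, ids, iteration: int, stratum: str) -> None:
        self.rows.extend((str(i), iteration, stratum) for i in ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["id", "iteration", "stratum"])

    def counts(self, iteration: int) -> dict[str, int]:
        frame = self.to_frame()
        sub = frame[frame["iteration"] == iteration]
        return sub["stratum"].value_counts().to_dict()


def make_split(
    actives: list[str],
    inactives: list[str],
    test_active_frac: float = 0.10,
    pool_size: int = 50_000,
    seed: int = 0,
) -> SplitPlan:
    """Random test/train split of actives and selection-pool draw of inactives.

    The test-active count rounds to nearest (e.g. 925 actives at 10 % ->
    93 test / 832 train); inactives outside the pool become test inactives.
    """
    if pool_size > len(inactives):
        raise ValueError(
            f"pool_size {pool_size} exceeds available inactives {len(inactives)}"
        )
    actives = [str(a) for a in actives]
    inactives = [str(i) for i in inactives]
    n_test = int(np.floor(len(actives) * test_active_frac + 0.5))
    rng = rng_for(seed, "split-actives")
    test_idx = set(rng.choice(len(actives), size=n_test, replace=False).tolist())
    test_actives = [a for i, a in enumerate(actives) if i in test_idx]
    train_actives = [a for i, a in enumerate(actives) if i not in test_idx]
    rng = rng_for(seed, "split-pool")
    pool_idx = set(rng.choice(len(inactives), size=pool_size, replace=False).tolist())
    selection_pool = [x for i, x in enumerate(inactives) if i in pool_idx]
    test_inactives = [x for i, x in enumerate(inactives) if i not in pool_idx]
    plan = SplitPlan(test_actives, train_actives, selection_pool, test_inactives, seed)
    plan.validate()
    return plan


def initial_inactive_draw(
    pool: list[str], n_actives: int, ratio: int = 2, seed: int = 0
) -> list[str]:
    """Seeded uniform draw of ``ratio * n_actives`` inactive ids without replacement."""
    n_draw = ratio * n_actives
    if n_draw > len(pool):
        raise ValueError(f"pool of {len(pool)} too small for draw of {n_draw}")
    rng = rng_for(seed, f"initial-draw-{ratio}")
    idx = rng.choice(len(pool), size=n_draw, replace=False)
    return [str(pool[i]) for i in sorted(idx)]


def stratified_rational_draw(
    predictions: pd.DataFrame, n_add: int, seed: int = 0, iteration: int = 1
) -> tuple[list[str], TrainingSetLineage]:
    """Draw ``n_add/4`` candidates from each of the four prediction strata.

    ``predictions`` must carry ``id`` and ``category`` columns for the
    candidate pool (selection pool minus current training inactives).  A
    stratum smaller than its quota contributes everything it has and the
    deficit is topped up from the largest remaining stratum (logged).
    """
    if n_add % len(RATIONAL_STRATA) != 0:
        raise ValueError(f"n_add must be divisible by {len(RATIONAL_STRATA)}")
    per_stratum = n_add // len(RATIONAL_STRATA)
    strata: dict[str, list[str]] = {
        c.value: predictions.loc[predictions["category"] == c.value, "id"].astype(str).tolist()
        for c in RATIONAL_STRATA
    }
    if all(len(v) == 0 for v in strata.values()):
        raise ValueError(
            "no candidates in any rational stratum; model leaves nothing to learn from"
        )
    lineage = TrainingSetLineage()
    chosen: list[str] = []
    deficits = 0
    for name, ids in strata.items():
        take = min(per_stratum, len(ids))
        if take < per_stratum:
            deficits += per_stratum - take
            logger.info(
                "stratum %s has %d candidates (< quota %d); topping up elsewhere",
                name,
                len(ids),
                per_stratum,
            )
        rng = rng_for(seed, f"expand-{iteration}-{name}")
        idx = rng.choice(len(ids), size=take, replace=False) if take else []
        picked = [ids[i] for i in sorted(idx)]
        chosen.extend(picked)
        lineage.add(picked, iteration, name)
        strata[name] = [x for x in ids if x not in set(picked)]
    while deficits > 0:
        largest = max(strata, key=lambda k: len(strata[k]))
        remaining = strata[largest]
        if not remaining:
            logger.warning(
                "all rational strata exhausted; drew %d of the requested %d",
                len(chosen),
                n_add,
            )
            break
        take = min(deficits, len(remaining))
        rng = rng_for(seed, f"expand-{iteration}-topup-{largest}")
        idx = rng.choice(len(remaining), size=take, replace=False)
        picked = [remaining[i] for i in sorted(idx)]
        chosen.extend(picked)
        lineage.add(picked, iteration, f"topup:{largest}")
        strata[largest] = [x for x in remaining if x not in set(picked)]
        deficits -= take
    return chosen, lineage


def rational_expand(
    results,
    candidate_features,
    candidate_ids: list[str],
    n_add: int,
    seed: int = 0,
    iteration: int = 1,
) -> tuple[list[str], TrainingSetLineage]:
    """Predict the candidate pool in the current model and draw by stratum.

    ``results`` is a fitted :class:`~rationalqsar.qsar.CocktailResults`;
    ``candidate_features`` their featurisation (spanning ``candidate_ids``).
    """
    predictions = results.predict(candidate_features)
    predictions = predictions.assign(id=[str(i) for i in candidate_ids])
    return stratified_rational_draw(predictions, n_add, seed=seed, iteration=iteration)


def assemble_final(
    train_actives: list[str],
    train_inactives: list[str],
    test_actives: list[str],
    pool_remaining: list[str],
    per_active_multiplier: int = 4,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Fold the external test actives (plus matched random inactives) into training.

    Returns the enlarged (actives, inactives) id lists; e.g. an 832 + 3,328
    training set plus 93 test actives and 4x93 = 372 pool inactives yields
    925 actives and 3,700 inactives (4,625 in total).
    """
    overlap = set(test_actives) & (set(train_actives) | set(train_inactives))
    if overlap:
        raise ValueError(f"test actives overlap the training set: {sorted(overlap)[:5]}")
    n_draw = per_active_multiplier * len(test_actives)
    if n_draw > len(pool_remaining):
        raise ValueError("selection pool exhausted for final assembly")
    rng = rng_for(seed, "final-assembly")
    idx = rng.choice(len(pool_remaining), size=n_draw, replace=False) if n_draw else []
    drawn = [str(pool_remaining[i]) for i in sorted(idx)]
    return list(train_actives) + list(test_actives), list(train_inactives) + drawn
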