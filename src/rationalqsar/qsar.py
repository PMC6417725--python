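"""Partial-logistic-regression QSAR models: single, composite and cocktail.

The learner emulates partial logistic regression (PLR): PLS factors are
extracted against the binary response treated as continuous, the number of
factors is chosen by minimising the cross-validated predictive residual sum
of squares (PRESS) on the training set, and a logistic regression on the
factor scores turns them into positive prediction probabilities.

Three modelling approaches are supported for imbalanced training sets:

* **single** — one model on the full training set;
* **composite** — the inactives are partitioned into balanced chunks and one
  sub-model is fitted per chunk (all actives shared across sub-models);
* **cocktail** — the single model plus the composite's sub-models, with the
  prediction being the unweighted mean of the probabilities of all members
  that contain the query in their structural domain.

The module exposes both the operational functions (``fit_single``,
``fit_composite``, ``fit_cocktail``, ``predict_probability``) and a
model/results facade (:class:`CocktailQSAR` / :class:`CocktailResults`) in
the style of statistical modelling packages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from ._util import substream
from .features import Featurizer, FeatureSpace, preselect

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    """Learner settings.

    max_factors: upper bound on PLS factors (chosen by PRESS below it).
    press_folds: internal folds for the PRESS criterion.
    ratio: actives:inactives per composite sub-model (1 = balanced).
    feature_fraction: share of columns kept by chi-squared preselection.
    drop_zero_loading: one refit after discarding features with ~zero PLS
        loadings (capped, for determinism).
    """

    max_factors: int = 10
    press_folds: int = 5
    ratio: int = 1
    feature_fraction: float = 0.30
    drop_zero_loading: bool = True


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _pls_coefficients(pls: PLSRegression, k: int) -> np.ndarray:
    """Regression coefficients using only the first ``k`` extracted factors.

    B_k = W_k (P_k' W_k)^{-1} Q_k' for a NIPALS fit on pre-scaled data.
    """
    w = pls.x_weights_[:, :k]
    p = pls.x_loadings_[:, :k]
    q = pls.y_loadings_[:, :k]
    return w @ np.linalg.solve(p.T @ w, q.T)


@dataclass
class SingleModel:
    """One fitted PLR model plus what its domain checks need.

    Carries its own training fingerprints (full-vocabulary binary keys) so
    the structural-domain test can be evaluated per ensemble member.
    """

    selected_columns: np.ndarray
    key_bit_indices: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    rotations: np.ndarray
    logit_coef: np.ndarray
    logit_intercept: float
    n_factors: int
    training_fingerprints: np.ndarray
    n_active: int
    n_inactive: int
    intercept_only: bool = False
    base_rate: float = 0.5

    def factor_scores(self, matrix: np.ndarray) -> np.ndarray:
        x = matrix[:, self.selected_columns]
        return ((x - self.x_mean) / self.x_std) @ self.rotations

    def predict_proba(self, features: FeatureSpace) -> np.ndarray:
        if self.intercept_only:
            return np.full(len(features.ids), self.base_rate)
        scores = self.factor_scores(features.matrix)
        return _sigmoid(scores @ self.logit_coef + self.logit_intercept)


@dataclass
class CompositeModel:
    sub_models: list[SingleModel]
    ratio: int
    inactive_partition: list[np.ndarray] = field(default_factory=list)

    @property
    def members(self) -> list[SingleModel]:
        return list(self.sub_models)


@dataclass
class CocktailModel:
    full_model: SingleModel
    sub_models: list[SingleModel]

    @property
    def members(self) -> list[SingleModel]:
        return [self.full_model, *self.sub_models]


# ---------------------------------------------------------------------------
# fitting


def _fit_pls_logistic(
    x: np.ndarray, y: np.ndarray, config: ModelConfig, seed: int
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """PRESS-selected PLS + logistic regression on the factor scores."""
    n, p = x.shape
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=1)
    std[std == 0] = 1.0
    xs = (x - mean) / std
    yf = y.astype(float)

    k_cap = int(min(config.max_factors, n - 1, p))
    n_splits = min(config.press_folds, n)
    press = np.zeros(k_cap + 1)
    counted = np.zeros(k_cap + 1, dtype=bool)
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed % (2**31))
    for train_idx, val_idx in kf.split(xs):
        k_fold = int(min(k_cap, len(train_idx) - 1))
        if k_fold < 1:
            continue
        pls = PLSRegression(n_components=k_fold, scale=False)
        pls.fit(xs[train_idx], yf[train_idx] - yf[train_idx].mean())
        y_mean = yf[train_idx].mean()
        for k in range(1, k_fold + 1):
            b = _pls_coefficients(pls, k)
            pred = xs[val_idx] @ b[:, 0] + y_mean
            press[k] += float(np.sum((yf[val_idx] - pred) ** 2))
            counted[k] = True
    usable = np.flatnonzero(counted)
    n_factors = int(usable[np.argmin(press[usable])]) if usable.size else 1

    pls = PLSRegression(n_components=n_factors, scale=False)
    pls.fit(xs, yf - yf.mean())
    rotations = np.asarray(pls.x_rotations_)
    scores = xs @ rotations
    logit = LogisticRegression(max_iter=1000)
    logit.fit(scores, y)
    return mean, std, rotations, logit, n_factors


def fit_single(
    features: FeatureSpace, labels: np.ndarray, config: ModelConfig = ModelConfig(), seed: int = 0
) -> SingleModel:
    """Fit one PLR model with chi-squared preselection on its own training set."""
    labels = np.asarray(labels, dtype=int)
    n_active = int(labels.sum())
    n_inactive = int(len(labels) - n_active)
    if n_active == 0 or n_inactive == 0:
        raise ValueError("training set must contain both classes")

    matrix = features.matrix
    mask = preselect(matrix, labels, config.feature_fraction, n_binary=features.n_keys)
    cols = np.flatnonzero(mask)
    key_bits = cols[cols < features.n_keys]

    x = matrix[:, cols]
    variable = x.std(axis=0) > 0
    if not variable.any():
        # degenerate contract: constant design -> intercept-only base-rate model
        logger.warning("constant feature matrix; fitting intercept-only model")
        return SingleModel(
            selected_columns=cols,
            key_bit_indices=key_bits,
            x_mean=np.zeros(len(cols)),
            x_std=np.ones(len(cols)),
            rotations=np.zeros((len(cols), 1)),
            logit_coef=np.zeros(1),
            logit_intercept=0.0,
            n_factors=0,
            training_fingerprints=features.key_matrix.copy(),
            n_active=n_active,
            n_inactive=n_inactive,
            intercept_only=True,
            base_rate=n_active / len(labels),
        )

    for _ in range(2):  # initial fit + at most one zero-loading refit
        mean, std, rotations, logit, n_factors = _fit_pls_logistic(x, labels, config, seed)
        if not config.drop_zero_loading:
            break
        keep = np.abs(rotations).max(axis=1) > 1e-10
        if keep.all() or keep.sum() < 2:
            break
        cols = cols[keep]
        key_bits = cols[cols < features.n_keys]
        x = matrix[:, cols]

    return SingleModel(
        selected_columns=cols,
        key_bit_indices=key_bits,
        x_mean=mean,
        x_std=std,
        rotations=rotations,
        logit_coef=np.asarray(logit.coef_[0]),
        logit_intercept=float(logit.intercept_[0]),
        n_factors=n_factors,
        training_fingerprints=features.key_matrix.copy(),
        n_active=n_active,
        n_inactive=n_inactive,
    )


def fit_composite(
    features: FeatureSpace,
    labels: np.ndarray,
    config: ModelConfig = ModelConfig(),
    seed: int = 0,
) -> CompositeModel:
    """Partition the inactives into balanced chunks; one sub-model per chunk.

    Every active appears in every sub-model; every inactive in exactly one.
    With fewer inactives than ``ratio * n_active`` a single sub-model covers
    everything.
    """
    labels = np.asarray(labels, dtype=int)
    active_rows = np.flatnonzero(labels == 1)
    inactive_rows = np.flatnonzero(labels == 0)
    n_active, n_inactive = len(active_rows), len(inactive_rows)
    if n_active == 0 or n_inactive == 0:
        raise ValueError("training set must contain both classes")

    if n_inactive < n_active:
        chunks = [inactive_rows]
    else:
        rng = np.random.default_rng(substream(seed, "composite-partition"))
        shuffled = inactive_rows[rng.permutation(n_inactive)]
        n_chunks = int(np.ceil(n_inactive / (config.ratio * n_active)))
        chunks = [np.sort(c) for c in np.array_split(shuffled, n_chunks)]

    sub_models = []
    for i, chunk in enumerate(chunks):
        rows = np.concatenate([active_rows, chunk])
        sub_models.append(
            fit_single(
                features.subset(rows),
                labels[rows],
                config,
                seed=substream(seed, f"sub-{i}"),
            )
        )
    return CompositeModel(sub_models=sub_models, ratio=config.ratio, inactive_partition=chunks)


def fit_cocktail(
    features: FeatureSpace,
    labels: np.ndarray,
    config: ModelConfig = ModelConfig(),
    seed: int = 0,
) -> CocktailModel:
    """Full-training-set single model combined with the composite's sub-models."""
    full = fit_single(features, labels, config, seed=substream(seed, "full"))
    composite = fit_composite(features, labels, config, seed=seed)
    return CocktailModel(full_model=full, sub_models=composite.sub_models)


# ---------------------------------------------------------------------------
# prediction


def predict_probability(
    model: SingleModel | CompositeModel | CocktailModel, features: FeatureSpace
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ensemble positive prediction probability per query row.

    Returns ``(p, n_contributing_members, max_similarity)``; ``p`` is NaN
    where no member's structural domain contains the query (out of
    structural domain).  For a single model the member set is itself.
    """
    from .domain import member_domain_mask  # local import to avoid a cycle

    members = model.members if hasattr(model, "members") else [model]
    n = len(features.ids)
    prob_sum = np.zeros(n)
    n_members = np.zeros(n, dtype=int)
    max_sim = np.zeros(n)
    for member in members:
        in_dom, sim = member_domain_mask(member, features)
        max_sim = np.maximum(max_sim, sim)
        if in_dom.any():
            p_member = member.predict_proba(features)
            prob_sum[in_dom] += p_member[in_dom]
            n_members[in_dom] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_members > 0, prob_sum / np.maximum(n_members, 1), np.nan)
    return p, n_members, max_sim


def predict_call(p: float | np.ndarray) -> np.ndarray | bool:
    """Binary call from the positive prediction probability (active iff p >= 0.5)."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("probability outside [0, 1]")
    call = arr >= 0.5
    return bool(call) if np.isscalar(p) or arr.ndim == 0 else call


# ---------------------------------------------------------------------------
# model / results facade


class CocktailQSAR:
    """Cocktail-ensemble QSAR model specification bound to training data.

    Parameters
    ----------
    features : FeatureSpace
        Training design (binary keys + continuous descriptors).
    labels : array-like of {0, 1}
        Binary activity, 1 = active.
    config : ModelConfig, optional
    """

    def __init__(self, features: FeatureSpace, labels, config: ModelConfig | None = None):
        self.features = features
        self.labels = np.asarray(labels, dtype=int)
        self.config = config or ModelConfig()

    @classmethod
    def from_smiles(
        cls,
        smiles: list[str],
        labels,
        vocabulary: list[str],
        ids: list[str] | None = None,
        config: ModelConfig | None = None,
    ) -> "CocktailQSAR":
        featurizer = Featurizer(vocabulary)
        return cls(featurizer.transform(smiles, ids), labels, config)

    def fit(self, seed: int = 0) -> "CocktailResults":
        model = fit_cocktail(self.features, self.labels, self.config, seed=seed)
        return CocktailResults(self, model, seed)


class CocktailResults:
    """Fitted cocktail ensemble with prediction, summary and persistence."""

    def __init__(self, spec: CocktailQSAR, model: CocktailModel, seed: int):
        self.model_spec = spec
        self.model = model
        self.seed = seed

    @property
    def vocabulary(self) -> list[str]:
        return self.model_spec.features.vocabulary

    @property
    def members(self) -> list[SingleModel]:
        return self.model.members

    def featurize(self, smiles: list[str], ids: list[str] | None = None) -> FeatureSpace:
        return Featurizer(self.vocabulary).transform(smiles, ids)

    def predict(self, features: FeatureSpace) -> pd.DataFrame:
        from .domain import predict_dataset

        return predict_dataset(self.model, features)

    def predict_smiles(self, smiles: list[str], ids: list[str] | None = None) -> pd.DataFrame:
        return self.predict(self.featurize(smiles, ids))

    def summary(self) -> str:
        lines = [
            "Cocktail QSAR results",
            "=" * 52,
            f"training set:      {self.model.full_model.n_active} actives,"
            f" {self.model.full_model.n_inactive} inactives",
            f"vocabulary size:   {len(self.vocabulary)} keys + 9 descriptors",
            f"members:           {len(self.members)} (1 full + {len(self.model.sub_models)} sub-models)",
            f"seed:              {self.seed}",
            "-" * 52,
            f"{'member':<10}{'n_act':>7}{'n_inact':>9}{'factors':>9}{'features':>10}",
        ]
        names = ["full"] + [f"sub-{i}" for i in range(len(self.model.sub_models))]
        for name, m in zip(names, self.members):
            lines.append(
                f"{name:<10}{m.n_active:>7}{m.n_inactive:>9}{m.n_factors:>9}"
                f"{len(m.selected_columns):>10}"
            )
        return "\n".join(lines)

    # -- persistence (plain-text bundle directory) --

    def save(self, directory) -> None:
        from .features import save_vocabulary

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_vocabulary(self.vocabulary, directory / "vocabulary.txt")
        manifest = {
            "format": "rationalqsar-model-1",
            "seed": self.seed,
            "config": self.model_spec.config.__dict__,
            "n_members": len(self.members),
        }
        names = ["full"] + [f"sub-{i}" for i in range(len(self.model.sub_models))]
        for name, m in zip(names, self.members):
            mdir = directory / name
            mdir.mkdir(exist_ok=True)
            np.savetxt(mdir / "selected_columns.csv", m.selected_columns, fmt="%d")
            np.savetxt(mdir / "x_mean.csv", m.x_mean)
            np.savetxt(mdir / "x_std.csv", m.x_std)
            np.savetxt(mdir / "rotations.csv", m.rotations.reshape(len(m.selected_columns), -1))
            np.savetxt(mdir / "logit_coef.csv", m.logit_coef)
            rows, cols = np.nonzero(m.training_fingerprints)
            np.savetxt(mdir / "train_fp.csv", np.column_stack([rows, cols]), fmt="%d")
            meta = {
                "logit_intercept": m.logit_intercept,
                "n_factors": m.n_factors,
                "n_active": m.n_active,
                "n_inactive": m.n_inactive,
                "intercept_only": m.intercept_only,
                "base_rate": m.base_rate,
                "fp_shape": list(m.training_fingerprints.shape),
            }
            (mdir / "meta.json").write_text(json.dumps(meta))
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "CocktailResults":
        from .features import load_vocabulary

        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        if manifest.get("format") != "rationalqsar-model-1":
            raise ValueError("unrecognised model bundle format")
        vocabulary = load_vocabulary(directory / "vocabulary.txt")
        n_keys = len(vocabulary)
        members = []
        names = ["full"] + [f"sub-{i}" for i in range(manifest["n_members"] - 1)]
        for name in names:
            mdir = directory / name
            meta = json.loads((mdir / "meta.json").read_text())
            cols = np.loadtxt(mdir / "selected_columns.csv", dtype=int, ndmin=1)
            fp = np.zeros(meta["fp_shape"], dtype=np.uint8)
            triplets = np.loadtxt(mdir / "train_fp.csv", dtype=int, ndmin=2)
            if triplets.size:
                fp[triplets[:, 0], triplets[:, 1]] = 1
            members.append(
                SingleModel(
                    selected_columns=cols,
                    key_bit_indices=cols[cols < n_keys],
                    x_mean=np.loadtxt(mdir / "x_mean.csv", ndmin=1),
                    x_std=np.loadtxt(mdir / "x_std.csv", ndmin=1),
                    rotations=np.loadtxt(mdir / "rotations.csv", ndmin=2),
                    logit_coef=np.loadtxt(mdir / "logit_coef.csv", ndmin=1),
                    logit_intercept=meta["logit_intercept"],
                    n_factors=meta["n_factors"],
                    training_fingerprints=fp,
                    n_active=meta["n_active"],
                    n_inactive=meta["n_inactive"],
                    intercept_only=meta["intercept_only"],
                    base_rate=meta["base_rate"],
                )
            )
        model = CocktailModel(full_model=members[0], sub_models=members[1:])
        config = ModelConfig(**manifest["config"])
        dummy_features = FeatureSpace(
            ids=[],
            smiles=[],
            vocabulary=vocabulary,
            key_matrix=np.zeros((0, n_keys), dtype=np.uint8),
            descriptors=pd.DataFrame(columns=list(range(9))),
            descriptor_ok=np.zeros(0, dtype=bool),
        )
        spec = CocktailQSAR(dummy_features, np.zeros(0, dtype=int), config)
        return cls(spec, model, manifest["seed"])
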