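"""End-to-end study orchestration: curate, split, iterate, validate, screen.

``run_full_study`` executes the whole design on one config: curation of the
raw table (or generation of a synthetic one), the train/test split with an
inactive selection pool, the initial 2:1 cocktail model, iterative rational
expansions (plus a size-matched random reference arm), final-model assembly,
external validation (and optional cross-validation and Y-randomisation),
structural-alert ranking and screening.  Every stage draws from a named
substream of one master seed, and a manifest records per-stage output hashes
so a rerun with the same config is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import round_half_up, substream
from .alerts import report_top_features, score_activity_features, score_inactivity_features
from .curation import curate, read_smiles_csv
from .domain import OutcomeCategory
from .features import Featurizer, VocabConfig, build_vocabulary
from .qsar import CocktailQSAR, ModelConfig
from .sampling import (
    assemble_final,
    initial_inactive_draw,
    make_split,
    stratified_rational_draw,
)
from .synth import FixtureConfig, make_dataset
from .validation import crossvalidate, external_validate, y_randomize

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Study configuration with the design's defaults pre-filled."""

    output_dir: str = "qsar_run"
    input_csv: str | None = None  # None -> generate a synthetic universe
    screen_csv: str | None = None
    seed: int = 0
    test_active_frac: float = 0.10
    pool_size: int | None = None  # None -> 25 % of the inactives
    schedule: tuple[int, ...] = (2, 3, 4)
    final_multiplier: int = 4
    run_rational_arm: bool = True
    run_random_arm: bool = True
    run_cv: bool = False
    run_y_randomization: bool = False
    cv_repeats: int = 2
    cv_folds: int = 5
    prevalences: tuple[float, ...] = (0.01, 0.05, 0.10)
    model: ModelConfig = field(default_factory=ModelConfig)
    vocab: VocabConfig = field(default_factory=VocabConfig)
    fixture: FixtureConfig = field(default_factory=FixtureConfig)

    def __post_init__(self):
        if list(self.schedule) != sorted(set(self.schedule)):
            raise ValueError("iteration schedule ratios must be strictly increasing")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub_cls in (("model", ModelConfig), ("vocab", VocabConfig), ("fixture", FixtureConfig)):
            if key in raw and isinstance(raw[key], dict):
                sub = raw[key]
                for name in ("radii",):
                    if name in sub and isinstance(sub[name], list):
                        sub[name] = tuple(sub[name])
                raw[key] = sub_cls(**sub)
        for name in ("schedule", "prevalences"):
            if name in raw and isinstance(raw[name], list):
                raw[name] = tuple(raw[name])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_screen(results, features, ids: list[str]) -> tuple[pd.DataFrame, dict]:
    """Screen a structure set through a fitted model.

    Returns the per-structure prediction table and a summary in the layout
    of screening reports: substances covered (% of screened), POS_IN and
    NEG_IN counts with their percentages of the covered subset.
    """
    if len(ids) == 0:
        raise ValueError("empty structure set")
    predictions = results.predict(features).assign(id=[str(i) for i in ids])
    n = len(predictions)
    covered = int(predictions["in_ad"].sum())
    pos_in = int((predictions["category"] == OutcomeCategory.POS_IN.value).sum())
    neg_in = int((predictions["category"] == OutcomeCategory.NEG_IN.value).sum())
    out_structural = int(
        (predictions["category"] == OutcomeCategory.OUT_STRUCTURAL.value).sum()
    )
    summary = {
        "n_screened": n,
        "covered": covered,
        "out_structural": out_structural,
        "covered_pct": round_half_up(100.0 * covered / n, 1),
        "pos_in": pos_in,
        "pos_in_pct_of_covered": round_half_up(100.0 * pos_in / covered, 1) if covered else None,
        "neg_in": neg_in,
        "neg_in_pct_of_covered": round_half_up(100.0 * neg_in / covered, 1) if covered else None,
    }
    return predictions, summary


class StudyArtifacts:
    """Handle to the outputs of :func:`run_full_study`."""

    def __init__(self, directory: Path):
        self.directory = Path(directory)
        self.models: dict[str, object] = {}
        self.reports: dict[str, object] = {}
        self.manifest: dict = {}


def _fit_model(name, features, rows, labels, config, seed, artifacts, outdir):
    spec = CocktailQSAR(features.subset(np.asarray(rows)), labels, config.model)
    results = spec.fit(seed=substream(seed, f"fit-{name}"))
    bundle_dir = outdir / "models" / name
    results.save(bundle_dir)
    artifacts.models[name] = results
    (outdir / "models" / name / "summary.txt").write_text(results.summary() + "\n")
    return results


def run_full_study(config: RunConfig) -> StudyArtifacts:
    """Execute the full workflow; returns handles to models and reports."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = StudyArtifacts(outdir)
    seed = config.seed
    stage_order: list[str] = []

    # -- curation ----------------------------------------------------------
    if config.input_csv:
        raw = read_smiles_csv(config.input_csv)
    else:
        fixture = dataclasses.replace(config.fixture, seed=substream(seed, "fixture"))
        raw = make_dataset(fixture)
        raw.to_csv(outdir / "synthetic_input.csv", index=False)
    dataset = curate(raw)
    kept = dataset.kept_frame()
    dataset.to_frame().to_csv(outdir / "curation_status.csv", index=False)
    kept.to_csv(outdir / "curated.csv", index=False)
    pd.DataFrame(dataset.provenance_log, columns=["id", "rule"]).to_csv(
        outdir / "provenance.csv", index=False
    )
    stage_order.append("curate")

    modelling = kept[kept["label"].isin(["ACTIVE", "INACTIVE"])].reset_index(drop=True)
    smiles_of = dict(zip(modelling["id"], modelling["canonical_smiles"]))
    label_of = dict(zip(modelling["id"], (modelling["label"] == "ACTIVE").astype(int)))
    actives = modelling.loc[modelling["label"] == "ACTIVE", "id"].tolist()
    inactives = modelling.loc[modelling["label"] == "INACTIVE", "id"].tolist()

    # -- split -------------------------------------------------------------
    pool_size = config.pool_size or max(int(0.25 * len(inactives)), 1)
    plan = make_split(
        actives, inactives, config.test_active_frac, pool_size, seed=substream(seed, "split")
    )
    (outdir / "split.json").write_text(
        json.dumps(
            {
                "test_actives": plan.test_actives,
                "train_actives": plan.train_actives,
                "selection_pool": plan.selection_pool,
                "test_inactives": plan.test_inactives,
            }
        )
    )
    stage_order.append("split")

    # -- featurisation on a fixed training-side vocabulary -----------------
    train_side_smiles = [smiles_of[i] for i in plan.train_actives + plan.selection_pool]
    vocabulary = build_vocabulary(train_side_smiles, config.vocab)
    featurizer = Featurizer(vocabulary)
    universe_ids = plan.train_actives + plan.selection_pool + plan.test_actives + plan.test_inactives
    universe = featurizer.transform([smiles_of[i] for i in universe_ids], universe_ids)
    row_of = {sid: i for i, sid in enumerate(universe_ids)}
    labels_arr = np.array([label_of[i] for i in universe_ids], dtype=int)
    stage_order.append("featurize")

    def rows_for(ids):
        return np.array([row_of[i] for i in ids], dtype=int)

    def labels_for(ids):
        return np.array([label_of[i] for i in ids], dtype=int)

    n_act = len(plan.train_actives)
    model_train_sets: dict[str, tuple[list[str], list[str]]] = {}

    # -- rational arm ------------------------------------------------------
    if config.run_rational_arm:
        r0 = config.schedule[0]
        train_inactives = initial_inactive_draw(
            plan.selection_pool, n_act, ratio=r0, seed=substream(seed, "rational-initial")
        )
        name = f"qsar{r0}to1"
        ids = plan.train_actives + train_inactives
        results = _fit_model(
            name, universe, rows_for(ids), labels_for(ids), config, seed, artifacts, outdir
        )
        model_train_sets[name] = (list(plan.train_actives), list(train_inactives))
        lineage_frames = []
        prev_ratio = r0
        for iteration, ratio in enumerate(config.schedule[1:], start=1):
            n_add = (ratio - prev_ratio) * n_act
            n_add -= n_add % 4  # stratum draws come in fours
            candidates = [i for i in plan.selection_pool if i not in set(train_inactives)]
            cand_rows = rows_for(candidates)
            predictions = results.predict(universe.subset(cand_rows))
            predictions = predictions.assign(id=candidates)
            try:
                new_ids, lineage = stratified_rational_draw(
                    predictions, n_add, seed=substream(seed, f"expand-{iteration}"),
                    iteration=iteration,
                )
            except ValueError:
                logger.warning(
                    "rational expansion %d found no candidates outside the "
                    "confident-negative region; stopping the arm early",
                    iteration,
                )
                break
            lineage_frames.append(lineage.to_frame())
            train_inactives = train_inactives + new_ids
            name = f"qsar{ratio}to1"
            ids = plan.train_actives + train_inactives
            results = _fit_model(
                name, universe, rows_for(ids), labels_for(ids), config, seed, artifacts, outdir
            )
            model_train_sets[name] = (list(plan.train_actives), list(train_inactives))
            prev_ratio = ratio
        if lineage_frames:
            pd.concat(lineage_frames, ignore_index=True).to_csv(
                outdir / "rational_lineage.csv", index=False
            )
        stage_order.append("rational-arm")

    # -- random reference arm ----------------------------------------------
    if config.run_random_arm:
        r_final = config.schedule[-1]
        random_inactives = initial_inactive_draw(
            plan.selection_pool, n_act, ratio=r_final, seed=substream(seed, "random-arm")
        )
        name = f"qsar{r_final}to1R"
        ids = plan.train_actives + random_inactives
        _fit_model(name, universe, rows_for(ids), labels_for(ids), config, seed, artifacts, outdir)
        model_train_sets[name] = (list(plan.train_actives), list(random_inactives))
        stage_order.append("random-arm")

    # -- final models -------------------------------------------------------
    finals = []
    for arm, base in (("rational", f"qsar{config.schedule[-1]}to1"),
                      ("random", f"qsar{config.schedule[-1]}to1R")):
        if base not in model_train_sets:
            continue
        base_act, base_inact = model_train_sets[base]
        pool_remaining = [i for i in plan.selection_pool if i not in set(base_inact)]
        final_act, final_inact = assemble_final(
            base_act,
            base_inact,
            plan.test_actives,
            pool_remaining,
            per_active_multiplier=config.final_multiplier,
            seed=substream(seed, f"final-{arm}"),
        )
        name = f"{arm}_final"
        ids = final_act + final_inact
        _fit_model(name, universe, rows_for(ids), labels_for(ids), config, seed, artifacts, outdir)
        model_train_sets[name] = (final_act, final_inact)
        finals.append(name)
    if finals:
        stage_order.append("final-models")

    # -- external validation -------------------------------------------------
    validation_dir = outdir / "validation"
    validation_dir.mkdir(exist_ok=True)
    for name, (train_act, train_inact) in model_train_sets.items():
        train_ids = set(train_act) | set(train_inact)
        test_ids = [
            i for i in plan.test_actives + plan.test_inactives if i not in train_ids
        ]
        if not test_ids:
            continue
        test_rows = rows_for(test_ids)
        report = external_validate(
            artifacts.models[name],
            [smiles_of[i] for i in test_ids],
            labels_for(test_ids),
            test_ids,
            sorted(train_ids),
            prevalences=config.prevalences,
        )
        report.to_json(validation_dir / f"external_{name}.json")
        (validation_dir / f"external_{name}.txt").write_text(report.summary() + "\n")
        artifacts.reports[f"external_{name}"] = report
    stage_order.append("external-validation")

    # -- cross-validation and Y-randomisation --------------------------------
    for name in finals:
        train_act, train_inact = model_train_sets[name]
        ids = train_act + train_inact
        smiles = [smiles_of[i] for i in ids]
        labels = labels_for(ids)
        if config.run_cv:
            report = crossvalidate(
                smiles, labels, config.model, config.vocab,
                repeats=config.cv_repeats, folds=config.cv_folds,
                master_seed=substream(seed, f"cv-{name}"),
                prevalences=config.prevalences,
            )
            report.to_json(validation_dir / f"cv_{name}.json")
            artifacts.reports[f"cv_{name}"] = report
        if config.run_y_randomization:
            report = y_randomize(
                smiles, labels, config.model, config.vocab,
                repeats=config.cv_repeats, folds=config.cv_folds,
                master_seed=substream(seed, f"yrand-{name}"),
            )
            report.to_json(validation_dir / f"yrand_{name}.json")
            artifacts.reports[f"yrand_{name}"] = report
    if config.run_cv or config.run_y_randomization:
        stage_order.append("cross-validation")

    # -- structural alerts ----------------------------------------------------
    for name in finals:
        results = artifacts.models[name]
        train_act, train_inact = model_train_sets[name]
        ids = train_act + train_inact
        rows = rows_for(ids)
        full = results.model.full_model
        key_cols = full.key_bit_indices
        matrix = universe.key_matrix[rows][:, key_cols]
        names = [vocabulary[i] for i in key_cols]
        labels = labels_for(ids)
        act_scores = score_activity_features(matrix, labels, names)
        inact_scores = score_inactivity_features(matrix, labels, names)
        report_top_features(act_scores, inact_scores, k=10).to_csv(
            outdir / f"alerts_{name}.csv", index=False
        )
    if finals:
        stage_order.append("alerts")

    # -- screening -------------------------------------------------------------
    if finals:
        if config.screen_csv:
            screen_table = pd.read_csv(config.screen_csv, dtype={"id": str})
            screen_ids = screen_table["id"].tolist()
            screen_features = featurizer.transform(screen_table["smiles"].tolist(), screen_ids)
        else:
            screen_ids = plan.test_actives + plan.test_inactives
            screen_features = universe.subset(rows_for(screen_ids))
        summaries = {}
        for name in finals:
            predictions, summary = run_screen(artifacts.models[name], screen_features, screen_ids)
            predictions.to_csv(outdir / f"screen_{name}.csv", index=False)
            summaries[name] = summary
        (outdir / "screen_summary.json").write_text(json.dumps(summaries, indent=2))
        artifacts.reports["screen"] = summaries
        stage_order.append("screen")

    # -- manifest ---------------------------------------------------------------
    manifest = {
        "seed": seed,
        "stages": stage_order,
        "config": {
            "schedule": list(config.schedule),
            "pool_size": pool_size,
            "final_multiplier": config.final_multiplier,
            "prevalences": list(config.prevalences),
        },
        "hashes": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts.manifest = manifest
    return artifacts
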