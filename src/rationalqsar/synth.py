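"""Seeded synthetic chemistry and assay data with planted structure.

The generator emulates the statistical shape of a large qHTS bioassay
universe so the whole pipeline is testable without downloads: a heavily
imbalanced labelled SMILES table (0.4 % actives by default) in which actives
preferentially carry planted heteroarene alert scaffolds (indole, pyrrole,
benzofuran, pyrimidine), inactives preferentially carry inactivating motifs
(sulfonamide, carboxylic acid), a configurable slice of "decoy" inactives
sits structurally close to the actives (alert scaffold plus an inactivating
motif — the false-positive-prone cluster rational sampling is meant to
mine), labels carry noise, and the table can be laced with the contaminants
the curation rules exist for (salts, mixtures, low-carbon species,
disallowed elements, concordant and conflicting duplicates).

Ground truth (true label, alert/decoy flags, expected curation status,
expected activity label) is stored alongside every record, so downstream
assertions never have to re-derive it through the code under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

from ._util import rng_for
from .curation import canonicalize

RDLogger.DisableLog("rdApp.*")

#: Alert scaffolds planted in actives (heteroarene cores).
ACTIVE_ALERT_SCAFFOLDS = (
    "c1ccc2[nH]ccc2c1",  # indole
    "c1cc[nH]c1",        # pyrrole
    "c1ccc2occc2c1",     # benzofuran
    "c1cncnc1",          # pyrimidine
)

#: Plain scaffolds carrying no planted activity signal.
PLAIN_SCAFFOLDS = (
    "c1ccccc1",
    "C1CCCCC1",
    "c1ccncc1",
    "c1ccc2ccccc2c1",
    "C1CCOC1",
    "C1CCNCC1",
)

#: Inactivating motifs appended as terminal decorations.
INACTIVE_MOTIFS = (
    "CS(=O)(=O)N",   # sulfonamide
    "CC(=O)O",       # carboxylic acid
)

#: Neutral decoration units; halogens as branches so chains stay extendable.
DECORATIONS = (
    "C",
    "CC",
    "CCO",
    "CN",
    "C(Cl)",
    "C(C)C",
    "CC(=O)N",
    "COC",
    "CCN(C)C",
    "C(Br)",
    "C(F)",
    "CCC",
    "COCC",
    "CNC",
)


@dataclass(frozen=True)
class FixtureConfig:
    """Study-condition defaults: a ~5,000-molecule universe at 0.4 % actives."""

    n_active: int = 20
    n_inactive: int = 4980
    active_alert_patterns: tuple[str, ...] = ACTIVE_ALERT_SCAFFOLDS
    inactive_feature_patterns: tuple[str, ...] = INACTIVE_MOTIFS
    alert_penetrance: float = 0.9
    label_noise: float = 0.02
    decoy_fraction: float = 0.05
    inactive_motif_fraction: float = 0.5
    interferer_fraction: float = 0.05
    contaminant_rates: dict = field(
        default_factory=lambda: {
            "salt": 0.02,
            "mixture": 0.01,
            "low_carbon": 0.005,
            "bad_element": 0.005,
            "duplicate_concordant": 0.01,
            "duplicate_conflict": 0.005,
        }
    )
    seed: int = 0

    def __post_init__(self):
        for name in ("alert_penetrance", "label_noise", "decoy_fraction",
                     "inactive_motif_fraction", "interferer_fraction"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_active < 0 or self.n_inactive < 0:
            raise ValueError("molecule counts must be nonnegative")


def _compose(rng: np.random.Generator, scaffold: str, motif: str | None = None) -> str:
    n_dec = int(rng.integers(1, 4))
    decorations = "".join(DECORATIONS[rng.integers(len(DECORATIONS))] for _ in range(n_dec))
    return scaffold + decorations + (motif or "")


def _unique_molecule(
    rng: np.random.Generator,
    scaffolds: tuple[str, ...],
    motifs: tuple[str, ...] | None,
    motif_p: float,
    seen: set[str],
) -> tuple[str, str]:
    """Draw a parseable molecule whose canonical form is new; returns (smiles, canonical)."""
    for _ in range(200):
        scaffold = scaffolds[rng.integers(len(scaffolds))]
        motif = None
        if motifs and rng.random() < motif_p:
            motif = motifs[rng.integers(len(motifs))]
        smiles = _compose(rng, scaffold, motif)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        canonical = canonicalize(mol)
        if canonical not in seen:
            seen.add(canonical)
            return smiles, canonical
    raise RuntimeError("could not generate a unique molecule; grammar too small for request")


def generate_molecules(config: FixtureConfig = FixtureConfig()) -> pd.DataFrame:
    """Labelled SMILES table with planted alerts, decoys and label noise.

    Columns: id, smiles, true_label (1/0, post-noise), has_alert, is_decoy,
    noise_flipped.  All structures are whitelist-clean, unique by canonical
    SMILES, and 5-40 heavy atoms.
    """
    rng = rng_for(config.seed, "generate-molecules")
    seen: set[str] = set()
    rows = []
    for i in range(config.n_active):
        planted = rng.random() < config.alert_penetrance
        scaffolds = config.active_alert_patterns if planted else PLAIN_SCAFFOLDS
        smiles, _ = _unique_molecule(rng, scaffolds, None, 0.0, seen)
        rows.append(
            {"id": f"a{i:05d}", "smiles": smiles, "true_label": 1,
             "has_alert": planted, "is_decoy": False}
        )
    n_decoy = int(round(config.decoy_fraction * config.n_inactive))
    for i in range(config.n_inactive):
        is_decoy = i < n_decoy
        if is_decoy:
            # decoys sit in the actives' chemical cluster: alert scaffold,
            # plain decorations, no inactivating motif — false-positive bait
            smiles, _ = _unique_molecule(rng, config.active_alert_patterns, None, 0.0, seen)
        else:
            smiles, _ = _unique_molecule(
                rng, PLAIN_SCAFFOLDS, config.inactive_feature_patterns,
                config.inactive_motif_fraction, seen,
            )
        rows.append(
            {"id": f"i{i:05d}", "smiles": smiles, "true_label": 0,
             "has_alert": is_decoy, "is_decoy": is_decoy}
        )
    table = pd.DataFrame(rows)
    table["noise_flipped"] = pd.Series([False] * len(table), dtype=bool)
    if len(table) and config.label_noise > 0:
        # class-balanced noise: flip a fraction of the actives and the same
        # *number* of inactives, so rare actives are not swamped by flipped
        # majority-class labels
        n_flip = int(round(config.label_noise * config.n_active))
        for label in (1, 0):
            eligible = (table["true_label"] == label) & ~table["noise_flipped"]
            candidates = table.index[eligible].to_numpy()
            if len(candidates) == 0 or n_flip == 0:
                continue
            picked = rng.choice(candidates, size=min(n_flip, len(candidates)), replace=False)
            table.loc[picked, "true_label"] = 1 - label
            table.loc[picked, "noise_flipped"] = True
    return table


def inject_contaminants(table: pd.DataFrame, config: FixtureConfig) -> pd.DataFrame:
    """Append curation-rule exercisers at the configured rates.

    Each appended record carries its ground-truth ``expected_status``; clean
    records are tagged KEPT.  Duplicate injections reference clean base
    records (concordant twins) or fresh conflicting pairs.
    """
    rng = rng_for(config.seed, "inject-contaminants")
    table = table.copy()
    table["expected_status"] = "KEPT"
    n = len(table)
    rates = config.contaminant_rates
    rows = []
    seen = {canonicalize(Chem.MolFromSmiles(s)) for s in table["smiles"]}

    def base_row() -> pd.Series:
        return table.iloc[int(rng.integers(n))]

    for j in range(int(np.floor(rates.get("salt", 0) * n))):
        base = base_row()
        counter = ".Cl" if rng.random() < 0.5 else ".[Na+].[Cl-]"
        rows.append(
            {"id": f"salt{j:04d}", "smiles": base["smiles"] + counter,
             "true_label": base["true_label"], "has_alert": base["has_alert"],
             "is_decoy": False, "noise_flipped": False,
             # desalting recovers the parent, which duplicates the base record
             "expected_status": "MERGED_DUPLICATE"}
        )
    for j in range(int(np.floor(rates.get("mixture", 0) * n))):
        base = base_row()
        rows.append(
            {"id": f"mix{j:04d}", "smiles": base["smiles"] + ".CCOCC",
             "true_label": base["true_label"], "has_alert": False, "is_decoy": False,
             "noise_flipped": False, "expected_status": "REMOVED_MIXTURE"}
        )
    for j in range(int(np.floor(rates.get("low_carbon", 0) * n))):
        rows.append(
            {"id": f"lowc{j:04d}", "smiles": ("C", "CO", "O=S(=O)(O)O")[j % 3],
             "true_label": 0, "has_alert": False, "is_decoy": False,
             "noise_flipped": False, "expected_status": "REMOVED_LOW_CARBON"}
        )
    for j in range(int(np.floor(rates.get("bad_element", 0) * n))):
        rows.append(
            {"id": f"badel{j:04d}", "smiles": ("CC[Se]CC", "CC[As](C)C", "CCO[Ti]")[j % 3],
             "true_label": 0, "has_alert": False, "is_decoy": False,
             "noise_flipped": False, "expected_status": "REMOVED_ELEMENT"}
        )
    for j in range(int(np.floor(rates.get("duplicate_concordant", 0) * n))):
        base = base_row()
        rows.append(
            {"id": f"dupc{j:04d}", "smiles": base["smiles"],
             "true_label": base["true_label"], "has_alert": base["has_alert"],
             "is_decoy": False, "noise_flipped": False,
             "expected_status": "MERGED_DUPLICATE"}
        )
    for j in range(int(np.floor(rates.get("duplicate_conflict", 0) * n))):
        smiles, _ = _unique_molecule(rng, PLAIN_SCAFFOLDS, None, 0.0, seen)
        for label, suffix in ((1, "a"), (0, "b")):
            rows.append(
                {"id": f"dupx{j:04d}{suffix}", "smiles": smiles, "true_label": label,
                 "has_alert": False, "is_decoy": False, "noise_flipped": False,
                 "expected_status": "REMOVED_DUPLICATE_CONFLICT"}
            )
    if rows:
        table = pd.concat([table, pd.DataFrame(rows)], ignore_index=True)
    return table


def generate_assay_scores(
    table: pd.DataFrame, seed: int = 0, interferer_fraction: float | None = None
) -> pd.DataFrame:
    """Score triples consistent with the labelling rules, plus interferers.

    Actives receive primary and confirmatory scores of 10-100 and a clean
    (zero) counterscreen; a configured fraction instead score 10-100 in the
    counterscreen — luciferase interferers whose ground truth is
    INCONCLUSIVE.  Inactives score 0 in the primary screen and are untested
    elsewhere.  Adds score columns and ``expected_label``.
    """
    rng = rng_for(seed, "assay-scores")
    table = table.copy()
    frac = 0.0 if interferer_fraction is None else interferer_fraction
    statuses = (
        table["expected_status"]
        if "expected_status" in table.columns
        else pd.Series(["KEPT"] * len(table))
    )
    primary, confirm, counter, expected = [], [], [], []
    for label, status in zip(table["true_label"], statuses):
        if label == 1:
            primary.append(int(rng.integers(10, 101)))
            confirm.append(int(rng.integers(10, 101)))
            # only clean records may be interferers: injected duplicates must
            # keep their tagged conflict/merge semantics
            if status == "KEPT" and rng.random() < frac:
                counter.append(int(rng.integers(10, 101)))
                expected.append("INCONCLUSIVE")
            else:
                counter.append(0)
                expected.append("ACTIVE")
        else:
            primary.append(0)
            confirm.append(None)
            counter.append(None)
            expected.append("INACTIVE")
    table["score_primary"] = primary
    table["score_confirm"] = confirm
    table["score_counter"] = counter
    table["expected_label"] = expected
    return table


def make_dataset(config: FixtureConfig = FixtureConfig()) -> pd.DataFrame:
    """Full fixture: molecules + contaminants + assay scores, curation-ready."""
    table = generate_molecules(config)
    table = inject_contaminants(table, config)
    return generate_assay_scores(
        table, seed=config.seed, interferer_fraction=config.interferer_fraction
    )
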