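"""Molecular descriptors, substructure-key fingerprints and χ² preselection.

The feature space mirrors what classical fragment-based QSAR engines use: a
binary occurrence matrix over a library of substructure keys plus nine
continuous whole-molecule descriptors (AlogP, H-bond acceptors/donors,
Lipinski score, molecular weight, parent atom number, parent molecular
weight, polar surface area, rotatable bonds).  The key library is an open
stand-in for commercial template libraries: a fixed public set (the 163
parseable MACCS SMARTS) extended with circular-environment fragments mined
from the training structures above a frequency floor.

Descriptor preselection keeps the top 30 % of columns ranked by a Yates-
corrected χ² test of feature presence against the binary activity label;
continuous descriptors are binarised at the training-set median for the test
only — the continuous values still enter the learner.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, MACCSkeys

RDLogger.DisableLog("rdApp.*")

DESCRIPTOR_NAMES = (
    "alogp",
    "hba",
    "hbd",
    "lipinski_score",
    "mw",
    "parent_atom_number",
    "parent_mw",
    "psa",
    "rotatable_bonds",
)

VOCABULARY_VERSION = "rationalqsar-vocab-1"


def maccs_smarts() -> list[str]:
    """The fixed public key set: every MACCS key with a concrete SMARTS."""
    return [s for _, (s, _) in sorted(MACCSkeys.smartsPatts.items()) if "?" not in s]


# ---------------------------------------------------------------------------
# descriptors


def compute_descriptors(mol: Chem.Mol, raw_mol: Chem.Mol | None = None) -> dict[str, float]:
    """Nine continuous descriptors; ``raw_mol`` carries any salt form.

    ``mw`` is computed on the raw (possibly multi-component) structure when
    given, ``parent_*`` always on the desalted parent; the two coincide for
    single-component inputs.  Raises on incalculable input — callers flag the
    structure descriptor-incalculable (feeds the applicability domain).
    """
    whole = raw_mol if raw_mol is not None else mol
    mw = Descriptors.MolWt(whole)
    parent_mw = Descriptors.MolWt(mol)
    alogp = Crippen.MolLogP(mol)
    hba = Lipinski.NumHAcceptors(mol)
    hbd = Lipinski.NumHDonors(mol)
    violations = sum(
        (parent_mw > 500.0, alogp > 5.0, hbd > 5, hba > 10)
    )
    return {
        "alogp": float(alogp),
        "hba": float(hba),
        "hbd": float(hbd),
        "lipinski_score": float(violations),
        "mw": float(mw),
        "parent_atom_number": float(mol.GetNumHeavyAtoms()),
        "parent_mw": float(parent_mw),
        "psa": float(Descriptors.TPSA(mol)),
        "rotatable_bonds": float(Lipinski.NumRotatableBonds(mol)),
    }


# ---------------------------------------------------------------------------
# vocabulary


@dataclass(frozen=True)
class VocabConfig:
    """Mining settings for the trained part of the key library.

    ``min_frequency`` is the fraction of structures a mined fragment must
    occur in; ``radii`` are the circular-environment sizes mined (0 disables
    mining); ``max_mined`` caps the mined tail, most frequent first.
    """

    min_frequency: float = 0.02
    radii: tuple[int, ...] = (1, 2)
    max_mined: int = 300
    include_fixed_keys: bool = True


def _environment_fragments(mol: Chem.Mol, radii: tuple[int, ...]) -> set[str]:
    frags: set[str] = set()
    for radius in radii:
        for atom_idx in range(mol.GetNumAtoms()):
            env = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom_idx)
            if not env:
                continue
            sub = Chem.PathToSubmol(mol, env)
            try:
                smiles = Chem.MolToSmiles(sub)
            except Exception:
                continue
            if smiles:
                frags.add(smiles)
    return frags


def build_vocabulary(smiles_list: list[str], config: VocabConfig = VocabConfig()) -> list[str]:
    """Fixed public keys plus fragments mined from the given structures.

    Deterministic and order-independent: mined fragments are selected by
    frequency across structures and sorted by (count desc, pattern).
    """
    if not smiles_list:
        raise ValueError("vocabulary requires at least one structure")
    vocabulary = maccs_smarts() if config.include_fixed_keys else []
    if config.radii and config.max_mined > 0:
        counts: Counter[str] = Counter()
        n_parsed = 0
        for smiles in smiles_list:
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                continue
            n_parsed += 1
            counts.update(_environment_fragments(mol, config.radii))
        floor = config.min_frequency * max(n_parsed, 1)
        mined = sorted(
            ((s, c) for s, c in counts.items() if c >= floor),
            key=lambda item: (-item[1], item[0]),
        )[: config.max_mined]
        existing = set(vocabulary)
        vocabulary += [s for s, _ in mined if s not in existing]
    return vocabulary


def compile_vocabulary(vocabulary: list[str]) -> list[Chem.Mol]:
    """Compile patterns to query molecules; invalid patterns fail here, never at query time."""
    queries = []
    for pattern in vocabulary:
        query = Chem.MolFromSmarts(pattern)
        if query is None:
            raise ValueError(f"unmatchable vocabulary pattern: {pattern!r}")
        queries.append(query)
    return queries


def save_vocabulary(vocabulary: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {VOCABULARY_VERSION}\n")
        fh.writelines(p + "\n" for p in vocabulary)


def load_vocabulary(path) -> list[str]:
    with open(path) as fh:
        header = fh.readline().strip()
        if header != f"# {VOCABULARY_VERSION}":
            raise ValueError(f"unrecognised vocabulary header: {header!r}")
        return [line.strip() for line in fh if line.strip()]


def fingerprint(mol: Chem.Mol, queries: list[Chem.Mol]) -> np.ndarray:
    """Binary key vector: bit i set iff key i matches at least once."""
    bits = np.zeros(len(queries), dtype=np.uint8)
    for i, query in enumerate(queries):
        if mol.HasSubstructMatch(query):
            bits[i] = 1
    return bits


# ---------------------------------------------------------------------------
# feature space


@dataclass
class FeatureSpace:
    """Design matrix for a set of structures on a fixed vocabulary.

    ``key_matrix`` holds the binary substructure keys, ``descriptors`` the
    nine continuous columns; ``matrix`` concatenates them in that order.
    ``descriptor_ok`` flags rows whose descriptors all computed.
    """

    ids: list[str]
    smiles: list[str]
    vocabulary: list[str]
    key_matrix: np.ndarray
    descriptors: pd.DataFrame
    descriptor_ok: np.ndarray
    selected_mask: np.ndarray | None = None

    @property
    def n_keys(self) -> int:
        return self.key_matrix.shape[1]

    @property
    def column_names(self) -> list[str]:
        return list(self.vocabulary) + list(DESCRIPTOR_NAMES)

    @property
    def matrix(self) -> np.ndarray:
        return np.hstack(
            [self.key_matrix.astype(float), self.descriptors.to_numpy(dtype=float)]
        )

    def subset(self, rows: np.ndarray) -> "FeatureSpace":
        rows = np.asarray(rows)
        return FeatureSpace(
            ids=[self.ids[i] for i in rows],
            smiles=[self.smiles[i] for i in rows],
            vocabulary=self.vocabulary,
            key_matrix=self.key_matrix[rows],
            descriptors=self.descriptors.iloc[rows].reset_index(drop=True),
            descriptor_ok=self.descriptor_ok[rows],
            selected_mask=self.selected_mask,
        )

    def to_csv(self, path) -> None:
        frame = pd.DataFrame(self.matrix, columns=self.column_names)
        frame.insert(0, "id", self.ids)
        frame.to_csv(path, index=False)

    def to_triplets(self, path) -> None:
        rows, cols = np.nonzero(self.key_matrix)
        pd.DataFrame({"row": rows, "col": cols}).to_csv(path, index=False)


class Featurizer:
    """Binds a vocabulary and maps structures to a :class:`FeatureSpace`."""

    def __init__(self, vocabulary: list[str]):
        self.vocabulary = list(vocabulary)
        self._queries = compile_vocabulary(self.vocabulary)

    def transform(self, smiles_list: list[str], ids: list[str] | None = None) -> FeatureSpace:
        ids = [str(i) for i in (ids if ids is not None else range(len(smiles_list)))]
        n = len(smiles_list)
        key_matrix = np.zeros((n, len(self._queries)), dtype=np.uint8)
        desc_rows = np.full((n, len(DESCRIPTOR_NAMES)), np.nan)
        desc_ok = np.zeros(n, dtype=bool)
        for i, smiles in enumerate(smiles_list):
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                continue
            key_matrix[i] = fingerprint(mol, self._queries)
            try:
                values = compute_descriptors(mol)
            except Exception:
                continue
            desc_rows[i] = [values[name] for name in DESCRIPTOR_NAMES]
            desc_ok[i] = True
        return FeatureSpace(
            ids=ids,
            smiles=list(smiles_list),
            vocabulary=self.vocabulary,
            key_matrix=key_matrix,
            descriptors=pd.DataFrame(desc_rows, columns=list(DESCRIPTOR_NAMES)),
            descriptor_ok=desc_ok,
        )


# ---------------------------------------------------------------------------
# Yates chi-squared and preselection


def yates_chi2(n11: int, n10: int, n01: int, n00: int) -> float:
    """Yates-corrected χ² for a 2x2 table; 0 when any margin is empty.

    chi2 = N * max(|n11*n00 - n10*n01| - N/2, 0)^2 / (r1 * r0 * c1 * c0)
    """
    counts = (n11, n10, n01, n00)
    if any(c < 0 for c in counts):
        raise ValueError(f"counts must be nonnegative, got {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("empty table")
    r1, r0 = n11 + n10, n01 + n00
    c1, c0 = n11 + n01, n10 + n00
    if 0 in (r1, r0, c1, c0):
        return 0.0
    num = max(abs(n11 * n00 - n10 * n01) - n / 2.0, 0.0)
    return n * num * num / (r1 * r0 * c1 * c0)


def chi2_per_column(binary_matrix: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorised Yates χ² of every binary column against a binary label."""
    x = np.asarray(binary_matrix, dtype=np.int64)
    y = np.asarray(labels, dtype=np.int64)
    n = x.shape[0]
    n11 = y @ x
    n01 = (1 - y) @ x
    n10 = y.sum() - n11
    n00 = (1 - y).sum() - n01
    r1, r0, c1, c0 = n11 + n10, n01 + n00, n11 + n01, n10 + n00
    denom = (r1 * r0 * c1 * c0).astype(float)
    num = np.maximum(np.abs(n11 * n00 - n10 * n01) - n / 2.0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * num * num / denom, 0.0)
    return chi2


def binarize_columns(matrix: np.ndarray, n_binary: int) -> np.ndarray:
    """Binarise trailing continuous columns at their column median (> median -> 1)."""
    out = np.asarray(matrix, dtype=float).copy()
    for j in range(n_binary, out.shape[1]):
        col = out[:, j]
        finite = col[np.isfinite(col)]
        median = np.median(finite) if finite.size else 0.0
        out[:, j] = np.where(np.isfinite(col) & (col > median), 1.0, 0.0)
    return (out > 0).astype(np.int64)


def preselect(
    matrix: np.ndarray,
    labels: np.ndarray,
    fraction: float = 0.30,
    n_binary: int | None = None,
) -> np.ndarray:
    """Boolean mask keeping the top ``ceil(fraction * n_cols)`` columns by χ².

    Continuous columns (index >= ``n_binary``) are binarised at the median
    for the test; ties break by column order.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise ValueError("preselection requires both classes present")
    if n_binary is None:
        n_binary = matrix.shape[1]
    binary = binarize_columns(matrix, n_binary)
    chi2 = chi2_per_column(binary, labels)
    n_cols = matrix.shape[1]
    quota = int(np.ceil(fraction * n_cols))
    order = np.lexsort((np.arange(n_cols), -chi2))
    mask = np.zeros(n_cols, dtype=bool)
    mask[order[:quota]] = True
    return mask
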