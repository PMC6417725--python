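"""Structure curation and activity labelling for qHTS bioassay tables.

Raw substance tables carry a structure (SMILES) and up to three PubChem-style
activity scores (0-100): a primary single-concentration screen, a confirmatory
triplicate retest, and a luciferase counterscreen that flags artefactual
positives in the reporter-gene readout.  This module turns such a table into a
unique, consistently labelled, QSAR-ready dataset:

1. parse / structural-error filter
2. element whitelist (applied to the raw structure, before desalting)
3. dissociation of ionic bonds and charge neutralisation
4. mixture (>= 2 organic components) and < 2-carbon filters
5. canonical SMILES (stereo ignored)
6. activity labelling from the score triple
7. duplicate handling (concordant groups merged, conflicting groups removed)

Every removal or merge is recorded in a provenance log so the arithmetic
|input| = |kept| + removals + merges is checkable after the fact.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Atoms a QSAR-ready structure may contain.
ALLOWED_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Na", "Mg", "Si", "P", "S", "Cl", "K", "Ca", "Br", "I"}
)


class Label(str, enum.Enum):
    ACTIVE = "ACTIVE"
    INACTIVE = "INACTIVE"
    INCONCLUSIVE = "INCONCLUSIVE"


class CurationStatus(str, enum.Enum):
    KEPT = "KEPT"
    REMOVED_ELEMENT = "REMOVED_ELEMENT"
    REMOVED_ERROR = "REMOVED_ERROR"
    REMOVED_MIXTURE = "REMOVED_MIXTURE"
    REMOVED_LOW_CARBON = "REMOVED_LOW_CARBON"
    REMOVED_DUPLICATE_CONFLICT = "REMOVED_DUPLICATE_CONFLICT"
    MERGED_DUPLICATE = "MERGED_DUPLICATE"


@dataclass
class SubstanceRecord:
    id: str
    raw_smiles: str
    primary_score: int | None = None
    confirm_score: int | None = None
    counter_score: int | None = None
    label: Label | None = None
    curation_status: CurationStatus | None = None
    canonical_smiles: str | None = None


@dataclass
class CuratedDataset:
    """Outcome of :func:`curate`: all records plus a per-rule provenance log."""

    records: list[SubstanceRecord]
    provenance_log: list[tuple[str, str]] = field(default_factory=list)

    @property
    def kept(self) -> list[SubstanceRecord]:
        return [r for r in self.records if r.curation_status is CurationStatus.KEPT]

    @property
    def modelling_records(self) -> list[SubstanceRecord]:
        """Kept records with a conclusive label (inconclusives are not modelled)."""
        return [r for r in self.kept if r.label in (Label.ACTIVE, Label.INACTIVE)]

    def removal_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {s.value: 0 for s in CurationStatus}
        for r in self.records:
            counts[r.curation_status.value] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "canonical_smiles": [r.canonical_smiles for r in self.records],
                "label": [r.label.value if r.label else None for r in self.records],
                "curation_status": [r.curation_status.value for r in self.records],
            }
        )

    def kept_frame(self) -> pd.DataFrame:
        frame = self.to_frame()
        return frame[frame["curation_status"] == CurationStatus.KEPT.value][
            ["id", "canonical_smiles", "label"]
        ].reset_index(drop=True)


# ---------------------------------------------------------------------------
# activity labelling


def _check_score(value: int | None, name: str) -> None:
    if value is None:
        return
    if not (0 <= int(value) <= 100):
        raise ValueError(f"{name} must lie in [0, 100], got {value!r}")


def assign_activity_label(
    primary_score: int | None,
    confirm_score: int | None,
    counter_score: int | None,
) -> Label:
    """Label a substance from its three assay scores.

    ACTIVE requires a confirmatory score of 10-100 together with a
    counterscreen score of exactly 0 (no luciferase interference); INACTIVE
    requires a primary score of exactly 0; everything else, including
    counterscreen-positive confirmed hits, is INCONCLUSIVE.
    """
    _check_score(primary_score, "primary_score")
    _check_score(confirm_score, "confirm_score")
    _check_score(counter_score, "counter_score")
    if confirm_score is not None and 10 <= confirm_score <= 100 and counter_score == 0:
        return Label.ACTIVE
    if primary_score == 0:
        return Label.INACTIVE
    return Label.INCONCLUSIVE


# ---------------------------------------------------------------------------
# structure rules


def check_elements(mol: Chem.Mol) -> tuple[bool, str | None]:
    """Whitelist check; returns (keep, first offending element symbol)."""
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in ALLOWED_ELEMENTS:
            return False, atom.GetSymbol()
    return True, None


def _neutralize_component(mol: Chem.Mol) -> Chem.Mol | None:
    """Neutralise the net formal charge of one connected component.

    Components already net-neutral (including internal zwitterions such as
    charge-separated nitro groups) are returned untouched.  Net-charged
    components are neutralised by protonating O/S/N anions and deprotonating
    protonated amines; permanent charges (quaternary nitrogen and the like)
    cannot be fixed this way and yield ``None``.
    """
    if Chem.GetFormalCharge(mol) == 0:
        return mol
    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        if Chem.GetFormalCharge(rw) == 0:
            break
        charge = atom.GetFormalCharge()
        if charge < 0 and atom.GetSymbol() in ("O", "S", "N"):
            atom.SetFormalCharge(charge + 1)
            atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
        elif charge > 0 and atom.GetSymbol() == "N" and atom.GetTotalNumHs() > 0:
            atom.SetFormalCharge(charge - 1)
            atom.SetNumExplicitHs(max(atom.GetNumExplicitHs() - 1, 0))
    out = rw.GetMol()
    if Chem.GetFormalCharge(out) != 0:
        return None
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _is_organic(mol: Chem.Mol) -> bool:
    return any(a.GetSymbol() == "C" for a in mol.GetAtoms())


def desalt_and_neutralize(mol: Chem.Mol) -> list[tuple[Chem.Mol, bool]] | None:
    """Break ionic bonds into components and neutralise each organic one.

    Inorganic (carbon-free) components are dissociated counterions — they
    keep whatever charge they carry and are dropped later by the parent
    selection.  Returns ``[(component, is_organic), ...]`` or ``None`` when
    an organic component's charge cannot be neutralised (record becomes
    REMOVED_ERROR), e.g. a permanent quaternary ammonium.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    out: list[tuple[Chem.Mol, bool]] = []
    for frag in frags:
        try:
            Chem.SanitizeMol(frag)
        except Exception:
            return None
        if not _is_organic(frag):
            out.append((frag, False))
            continue
        neutral = _neutralize_component(frag)
        if neutral is None:
            return None
        out.append((neutral, True))
    return out


def filter_mixture_and_low_carbon(
    components: list[tuple[Chem.Mol, bool]],
) -> tuple[Chem.Mol | None, CurationStatus | None]:
    """Keep the single organic parent, or report why there is none.

    Two or more organic components is a mixture; zero carbon-bearing
    components, or a parent with fewer than two carbons, is low-carbon.
    """
    organics = [m for m, is_org in components if is_org]
    if len(organics) >= 2:
        return None, CurationStatus.REMOVED_MIXTURE
    if not organics:
        return None, CurationStatus.REMOVED_LOW_CARBON
    parent = organics[0]
    n_carbon = sum(1 for a in parent.GetAtoms() if a.GetSymbol() == "C")
    if n_carbon < 2:
        return None, CurationStatus.REMOVED_LOW_CARBON
    return parent, None


def canonicalize(mol: Chem.Mol) -> str:
    """Deterministic canonical SMILES, stereo flags dropped (2D modelling)."""
    return Chem.MolToSmiles(mol, isomericSmiles=False)


def canonicalize_smiles(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else canonicalize(mol)


# ---------------------------------------------------------------------------
# deduplication


_CONCLUSIVE = (Label.ACTIVE, Label.INACTIVE)


def deduplicate(records: list[SubstanceRecord], provenance: list[tuple[str, str]]) -> None:
    """Resolve identical canonical structures in place.

    Concordant groups keep one representative (the rest become
    MERGED_DUPLICATE); groups mixing ACTIVE with INACTIVE are removed
    entirely.  A group mixing INCONCLUSIVE with exactly one conclusive label
    keeps that conclusive label on the representative.
    """
    groups: dict[str, list[SubstanceRecord]] = {}
    for rec in records:
        if rec.curation_status is CurationStatus.KEPT:
            groups.setdefault(rec.canonical_smiles, []).append(rec)
    for smiles, group in groups.items():
        if len(group) == 1:
            continue
        conclusive = {r.label for r in group if r.label in _CONCLUSIVE}
        if len(conclusive) > 1:
            for rec in group:
                rec.curation_status = CurationStatus.REMOVED_DUPLICATE_CONFLICT
                rec.canonical_smiles = None
                provenance.append((rec.id, "duplicate_conflict"))
            continue
        keep_label = conclusive.pop() if conclusive else Label.INCONCLUSIVE
        representative = next(
            (r for r in group if r.label is keep_label), group[0]
        )
        representative.label = keep_label
        for rec in group:
            if rec is not representative:
                rec.curation_status = CurationStatus.MERGED_DUPLICATE
                provenance.append((rec.id, "merged_duplicate"))


# ---------------------------------------------------------------------------
# full workflow


def _coerce_score(value) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return int(value)


def curate(table: pd.DataFrame) -> CuratedDataset:
    """Run the full curation workflow on a raw id/smiles/scores table.

    Applies, in order: parse -> element whitelist -> desalt/neutralise ->
    mixture & low-carbon filters -> canonicalise -> label -> deduplicate.
    Raises ``ValueError`` on an empty table.
    """
    if len(table) == 0:
        raise ValueError("cannot curate an empty table")
    records: list[SubstanceRecord] = []
    provenance: list[tuple[str, str]] = []

    for row in table.itertuples(index=False):
        rec = SubstanceRecord(
            id=str(row.id),
            raw_smiles=str(row.smiles),
            primary_score=_coerce_score(getattr(row, "score_primary", None)),
            confirm_score=_coerce_score(getattr(row, "score_confirm", None)),
            counter_score=_coerce_score(getattr(row, "score_counter", None)),
        )
        records.append(rec)

        mol = Chem.MolFromSmiles(rec.raw_smiles)
        if mol is None:
            rec.curation_status = CurationStatus.REMOVED_ERROR
            provenance.append((rec.id, "parse_error"))
            continue
        keep, element = check_elements(mol)
        if not keep:
            rec.curation_status = CurationStatus.REMOVED_ELEMENT
            provenance.append((rec.id, f"element:{element}"))
            continue
        components = desalt_and_neutralize(mol)
        if components is None:
            rec.curation_status = CurationStatus.REMOVED_ERROR
            provenance.append((rec.id, "neutralization_error"))
            continue
        parent, reason = filter_mixture_and_low_carbon(components)
        if parent is None:
            rec.curation_status = reason
            provenance.append(
                (rec.id, "mixture" if reason is CurationStatus.REMOVED_MIXTURE else "low_carbon")
            )
            continue
        try:
            rec.canonical_smiles = canonicalize(parent)
        except Exception:
            rec.curation_status = CurationStatus.REMOVED_ERROR
            provenance.append((rec.id, "canonicalization_error"))
            continue
        rec.label = assign_activity_label(
            rec.primary_score, rec.confirm_score, rec.counter_score
        )
        rec.curation_status = CurationStatus.KEPT

    deduplicate(records, provenance)

    dataset = CuratedDataset(records=records, provenance_log=provenance)
    counts = dataset.removal_counts()
    logger.info(
        "curation: %d in, %d kept, removals %s",
        len(records),
        counts["KEPT"],
        {k: v for k, v in counts.items() if v and k != "KEPT"},
    )
    return dataset


# ---------------------------------------------------------------------------
# IO


def read_smiles_csv(path) -> pd.DataFrame:
    """Read an id/smiles/score CSV (missing scores blank)."""
    table = pd.read_csv(path, dtype={"id": str})
    required = {"id", "smiles"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"input CSV lacks required columns: {sorted(missing)}")
    for col in ("score_primary", "score_confirm", "score_counter"):
        if col not in table.columns:
            table[col] = None
    return table


def read_sdf(path) -> pd.DataFrame:
    """Read an SDF whose property tags mirror the CSV columns."""
    rows = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            rows.append({"id": f"sdf_{i}", "smiles": ""})
            continue
        props = mol.GetPropsAsDict()
        rows.append(
            {
                "id": str(props.get("id", mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf_{i}")),
                "smiles": Chem.MolToSmiles(mol),
                "score_primary": props.get("score_primary"),
                "score_confirm": props.get("score_confirm"),
                "score_counter": props.get("score_counter"),
            }
        )
    return pd.DataFrame(rows)


def write_outputs(dataset: CuratedDataset, kept_path, provenance_path) -> None:
    dataset.kept_frame().to_csv(kept_path, index=False)
    pd.DataFrame(dataset.provenance_log, columns=["id", "rule"]).to_csv(
        provenance_path, index=False
    )
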