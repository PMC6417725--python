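"""Two-component applicability domain and prediction outcome categories.

A prediction is trusted only when (1) the query lies in the *structural
domain* of at least one ensemble member — at least 30 % Jaccard (Tanimoto)
similarity to one of that member's training structures, all model
descriptors computable, and at least one model feature present — and (2) the
ensemble probability is decisive: p >= 0.7 for an active call (POS_IN) or
p <= 0.3 for an inactive call (NEG_IN).  Structurally covered predictions in
the grey zone are out of the domain: NEG_OUT (0.3 < p < 0.4), INC_OUT
(0.4 <= p < 0.5) and POS_OUT (0.5 <= p < 0.7); queries no member covers are
OUT_STRUCTURAL.
"""

from __future__ import annotations

import enum

import numpy as np
import pandas as pd

from .features import FeatureSpace

#: Minimum Jaccard similarity to a training structure (inclusive).
SIMILARITY_THRESHOLD = 0.30
#: Probability band edges of the class-probability refinement.
NEG_IN_MAX, POS_IN_MIN = 0.3, 0.7


class OutcomeCategory(str, enum.Enum):
    OUT_STRUCTURAL = "OUT_STRUCTURAL"
    POS_IN = "POS_IN"
    NEG_IN = "NEG_IN"
    NEG_OUT = "NEG_OUT"
    INC_OUT = "INC_OUT"
    POS_OUT = "POS_OUT"


IN_AD_CATEGORIES = frozenset({OutcomeCategory.POS_IN, OutcomeCategory.NEG_IN})


def jaccard_similarity(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """|A ∩ B| / |A ∪ B| on binary fingerprints; 0 when both are empty."""
    a = np.asarray(fp_a).astype(bool)
    b = np.asarray(fp_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 0.0
    return int(np.logical_and(a, b).sum()) / union


def max_jaccard(query_fps: np.ndarray, train_fps: np.ndarray) -> np.ndarray:
    """Row-wise maximum Jaccard similarity of each query to any training row."""
    q = np.asarray(query_fps, dtype=np.int64)
    t = np.asarray(train_fps, dtype=np.int64)
    if t.shape[0] == 0:
        return np.zeros(q.shape[0])
    inter = q @ t.T
    union = q.sum(axis=1)[:, None] + t.sum(axis=1)[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return sim.max(axis=1)


def member_domain_mask(member, features: FeatureSpace) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised structural-domain membership for one ensemble member.

    Returns (in_domain boolean per row, max similarity per row).
    """
    sim = max_jaccard(features.key_matrix, member.training_fingerprints)
    has_feature = (
        features.key_matrix[:, member.key_bit_indices].any(axis=1)
        if len(member.key_bit_indices)
        else np.zeros(len(features.ids), dtype=bool)
    )
    in_domain = (sim >= SIMILARITY_THRESHOLD) & features.descriptor_ok & has_feature
    return in_domain, sim


def in_structural_domain(
    query_features: FeatureSpace, member, row: int = 0
) -> tuple[bool, list[str]]:
    """Structural-domain check for one query with failure reasons."""
    in_dom, sim = member_domain_mask(member, query_features)
    reasons = []
    if sim[row] < SIMILARITY_THRESHOLD:
        reasons.append(
            f"max similarity {sim[row]:.3f} below threshold {SIMILARITY_THRESHOLD}"
        )
    if not query_features.descriptor_ok[row]:
        reasons.append("descriptors incalculable")
    if len(member.key_bit_indices) == 0 or not query_features.key_matrix[
        row, member.key_bit_indices
    ].any():
        reasons.append("no model feature present")
    return bool(in_dom[row]), reasons


def classify_outcome(p: float | None, in_structural: bool = True) -> OutcomeCategory:
    """Map a probability (or structural-domain miss) to its outcome category.

    The printed grey-zone bands overlap on [0.5, 0.6); consistent with the
    call rule (p >= 0.5 is a positive call) that interval is POS_OUT and
    INC_OUT is [0.4, 0.5).
    """
    if not in_structural or p is None or (isinstance(p, float) and np.isnan(p)):
        return OutcomeCategory.OUT_STRUCTURAL
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability outside [0, 1]: {p}")
    if p <= NEG_IN_MAX:
        return OutcomeCategory.NEG_IN
    if p < 0.4:
        return OutcomeCategory.NEG_OUT
    if p < 0.5:
        return OutcomeCategory.INC_OUT
    if p < POS_IN_MIN:
        return OutcomeCategory.POS_OUT
    return OutcomeCategory.POS_IN


def coverage(categories) -> float:
    """In-domain fraction of a prediction set: (POS_IN + NEG_IN) / N."""
    cats = list(categories)
    if not cats:
        return 0.0
    in_ad = sum(1 for c in cats if OutcomeCategory(c) in IN_AD_CATEGORIES)
    return in_ad / len(cats)


def predict_dataset(model, features: FeatureSpace) -> pd.DataFrame:
    """Full prediction table for a feature set under one (ensemble) model.

    Columns: id, canonical_smiles, p (NaN if OUT_STRUCTURAL), call, category,
    in_ad, max_similarity, n_contributing_members.
    """
    from .qsar import predict_probability

    p, n_members, max_sim = predict_probability(model, features)
    categories = [
        classify_outcome(float(p[i]) if n_members[i] > 0 else None, n_members[i] > 0)
        for i in range(len(features.ids))
    ]
    calls = [
        ("active" if p[i] >= 0.5 else "inactive") if n_members[i] > 0 else None
        for i in range(len(features.ids))
    ]
    return pd.DataFrame(
        {
            "id": features.ids,
            "canonical_smiles": features.smiles,
            "p": p,
            "call": calls,
            "category": [c.value for c in categories],
            "in_ad": [int(c in IN_AD_CATEGORIES) for c in categories],
            "max_similarity": max_sim,
            "n_contributing_members": n_members,
        }
    )
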