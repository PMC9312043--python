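"""Feature importance from per-sample tailored weights.

For a fixed subtype's weight vectors w(n), the sample-wise importance of
feature k for case n is s_k(n) = |w_k(n) x_k(n)|. Each case contributes its
top 10% of features by s (m = ceil(0.1 d), ties broken toward the lower
feature index); the feature-level importance score is the fraction of cases
whose top set contains the feature. Features with a score of at least 0.30
are reported, ranked by score, together with the median tailored weight so
the direction of the association can be read off. Features are finally
grouped into the disease's three clinical components: autonomic dysfunction
(A), parkinsonism (P), and cerebellar ataxia (C).

Sign semantics: two-level registry items are encoded as absence indicators
(presence -> 0, absence -> 1), so a NEGATIVE median weight on such a feature
means its presence pushes the case toward the subtype; for graded and one-hot
features a positive weight marks the stronger association.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
import yaml

from .encoding import FeatureCodebook
from .registry import SUBTYPES

__all__ = ["samplewise_scores", "top_fraction_mask", "importance_scores",
           "median_weights", "important_features", "feature_importance",
           "assign_components", "DEFAULT_COMPONENT_MAP", "load_component_map"]


def samplewise_scores(weights: np.ndarray, x: np.ndarray) -> np.ndarray:
    """s_k(n) = |w_k(n) x_k(n)| elementwise; shapes must match."""
    weights = np.asarray(weights, dtype=float)
    x = np.asarray(x, dtype=float)
    if weights.shape != x.shape:
        raise ValueError(f"shape mismatch: {weights.shape} vs {x.shape}")
    return np.abs(weights * x)


def _top_m(d: int, fraction: float) -> int:
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    return ceil(fraction * d)


def top_fraction_mask(s_row: np.ndarray, fraction: float = 0.10) -> np.ndarray:
    """Boolean mask of the ceil(fraction*d) largest entries of one row.

    Ties are broken toward the lower feature index (stable descending sort).
    """
    s_row = np.asarray(s_row, dtype=float)
    if s_row.size == 0:
        raise ValueError("empty importance row")
    m = _top_m(s_row.size, fraction)
    order = np.argsort(-s_row, kind="stable")
    mask = np.zeros(s_row.size, dtype=bool)
    mask[order[:m]] = True
    return mask


def importance_scores(S: np.ndarray, fraction: float = 0.10) -> np.ndarray:
    """Per-feature rate of membership in the samples' top-fraction sets."""
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] < 1:
        raise ValueError("S must be a non-empty n x d matrix")
    n, d = S.shape
    m = _top_m(d, fraction)
    order = np.argsort(-S, axis=1, kind="stable")[:, :m]
    counts = np.bincount(order.ravel(), minlength=d)
    return counts / n


def median_weights(weights: np.ndarray) -> np.ndarray:
    """Per-feature median of the tailored weights (even n: mean of middle two)."""
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or weights.shape[0] < 1:
        raise ValueError("weights must be a non-empty n x d matrix")
    return np.median(weights, axis=0)


def feature_importance(class_weights: np.ndarray, X: np.ndarray,
                       codebook: FeatureCodebook, fraction: float = 0.10,
                       weight_population: str = "all") -> pd.DataFrame:
    """Full importance table for one subtype's weight vectors.

    ``class_weights`` is the n x d matrix w_c(n) of one class. The median
    weight is taken over ``weight_population``: "all" samples (default) or
    "topset" (only samples whose top set contains the feature; a feature in
    no top set falls back to the all-sample median). Restriction to the
    subtype's own cases is done by the caller via row selection.
    """
    S = samplewise_scores(class_weights, X)
    scores = importance_scores(S, fraction)
    if weight_population == "all":
        med = median_weights(class_weights)
    elif weight_population == "topset":
        n, d = S.shape
        m = _top_m(d, fraction)
        order = np.argsort(-S, axis=1, kind="stable")[:, :m]
        member = np.zeros((n, d), dtype=bool)
        np.put_along_axis(member, order, True, axis=1)
        med = median_weights(class_weights)
        for k in range(d):
            if member[:, k].any():
                med[k] = np.median(class_weights[member[:, k], k])
    else:
        raise ValueError("weight_population must be 'all' or 'topset'")
    df = pd.DataFrame({
        "feature": codebook.names,
        "score": scores,
        "median_weight": med,
    })
    return df


def important_features(records: pd.DataFrame, threshold: float = 0.30
                       ) -> pd.DataFrame:
    """Filter at score >= threshold (inclusive) and rank by descending score.

    Ties keep codebook order (stable sort). Adds a 1-based ``rank`` column.
    """
    kept = records[records["score"] >= threshold]
    kept = kept.sort_values("score", ascending=False, kind="stable")
    kept = kept.reset_index(drop=True)
    kept.insert(0, "rank", np.arange(1, len(kept) + 1))
    return kept


# Component attribution of the form items: A = autonomic dysfunction,
# P = parkinsonism, C = cerebellar ataxia. Items whose clinical reading is
# not specific to one component are left unassigned.
DEFAULT_COMPONENT_MAP: dict[str, str] = {
    "onset_autonomic": "A",
    "auto_head_up_tilt": "A",
    "auto_syncope": "A",
    "auto_urinary_disturbance": "A",
    "auto_urinary_incontinence": "A",
    "auto_erectile_dysfunction": "A",
    "auto_severe_constipation": "A",
    "oth_respiratory_failure": "A",
    "onset_parkinsonism": "P",
    "neuro_gait_parkinsonism": "P",
    "neuro_tremor_at_rest": "P",
    "neuro_rigidity": "P",
    "neuro_finger_taps": "P",
    "neuro_bent_posture": "P",
    "img_striatal_abnormality": "P",
    "onset_ataxia": "C",
    "neuro_finger_to_nose": "C",
    "neuro_knee_tibia": "C",
    "img_cerebellar_atrophy": "C",
    "img_brainstem_atrophy": "C",
    "img_hot_cross_bun": "C",
}


def load_component_map(path) -> dict[str, str]:
    """Read an item -> component mapping from YAML (same keys as the default)."""
    with open(path) as fh:
        m = yaml.safe_load(fh)
    bad = {k: v for k, v in m.items() if v not in ("A", "P", "C")}
    if bad:
        raise ValueError(f"components must be A/P/C: {bad}")
    return m


def assign_components(records: pd.DataFrame, codebook: FeatureCodebook,
                      component_map: dict[str, str] | None = None
                      ) -> pd.DataFrame:
    """Annotate an importance table with components and P/N sign labels.

    The component is looked up by the feature's source item (so one-hot level
    columns inherit their item's component); unmapped items get "unassigned".
    The sign label is P (positive: strong relationship with the subtype) when
    the median weight indicates a stronger association under the feature's
    encoding direction — negative for absence-coded binary indicators,
    positive for everything else — and N otherwise.
    """
    cmap = DEFAULT_COMPONENT_MAP if component_map is None else component_map
    by_name = {f.name: f for f in codebook.features}
    comps, signs = [], []
    for _, row in records.iterrows():
        f = by_name[row["feature"]]
        comps.append(cmap.get(f.source_item_id, "unassigned"))
        mw = row["median_weight"]
        stronger = mw < 0 if f.encoding == "B" else mw > 0
        signs.append("P" if stronger else "N")
    out = records.copy()
    out["component"] = comps
    out["sign"] = signs
    return out
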