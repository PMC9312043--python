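"""Design-matrix construction from registry cohorts.

Two encodings of the same form are supported:

* variant ``a`` keeps the rank order of graded items: each ordinal item is one
  column holding its raw level (1, 2, 3, ...), mode of onset is ordinal, and
  the total is 58 feature variables;
* variant ``b`` discards rank order: every graded item and mode of onset is
  expanded to one-hot indicators over its full scale, for 126 feature
  variables.

Both variants encode two-level registry items as ``code - 1``. Because the
registry codes presence = 1 / absence = 2, the encoded indicator marks
ABSENCE (presence -> 0, absence -> 1); this is deliberate and preserves the
sign semantics of the model's weights (a negative weight on such a column
means the finding's presence favours the class). Age, the only quantitative
variable, is standardised with training-set statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import (
    ABSENCE,
    LABEL_COLUMN,
    SUBTYPES,
    CaseRecord,
    Cohort,
    ItemDef,
    form_schema,
    modelling_items,
)

__all__ = [
    "FeatureVar",
    "FeatureCodebook",
    "NormStats",
    "DesignMatrix",
    "build_codebook",
    "fit_normalization",
    "encode_cohort",
    "decode_row",
]

SD_FLOOR = 1e-8

#: mapping of subtype label to class index used throughout the model
LABEL_INDEX = {lab: i for i, lab in enumerate(SUBTYPES)}


@dataclass(frozen=True)
class FeatureVar:
    index: int
    name: str
    source_item_id: str
    encoding: str  # B | C_level | O | Q
    level: int | None = None  # for C_level only


@dataclass(frozen=True)
class FeatureCodebook:
    variant: str
    features: tuple[FeatureVar, ...]

    def __len__(self) -> int:
        return len(self.features)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def block(self, group: str) -> list[FeatureVar]:
        """Features whose source item belongs to a form group."""
        by_id = {it.item_id: it for it in form_schema()}
        return [f for f in self.features
                if by_id[f.source_item_id].group == group]

    def onehot_groups(self) -> dict[str, list[FeatureVar]]:
        groups: dict[str, list[FeatureVar]] = {}
        for f in self.features:
            if f.encoding == "C_level":
                groups.setdefault(f.source_item_id, []).append(f)
        return groups


@dataclass
class NormStats:
    """Training-set mean/sd for each quantitative feature, by feature name."""

    mean: dict[str, float]
    sd: dict[str, float]


@dataclass
class DesignMatrix:
    values: np.ndarray  # n x d, float
    codebook: FeatureCodebook
    labels: np.ndarray  # n, subtype strings
    norm_stats: NormStats
    case_ids: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Integer class labels (SND=0, SDS=1, OPCA=2)."""
        return np.asarray([LABEL_INDEX[l] for l in self.labels])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.codebook.names)
        df[LABEL_COLUMN] = self.labels
        return df


_LEVEL_TAGS = {
    "mode_of_onset": {1: "mild", 2: "subacute", 3: "acute"},
    "progression": {1: "progressive", 2: "arrested", 3: "improved", 4: "other"},
    "oth_tendon_reflex": {1: "increased", 2: "decreased", 3: "normal"},
}


def _onehot_vars(item: ItemDef, start: int) -> list[FeatureVar]:
    tags = _LEVEL_TAGS.get(item.item_id, {})
    return [FeatureVar(start + j, f"{item.item_id}={tags.get(lv, lv)}",
                       item.item_id, "C_level", lv)
            for j, lv in enumerate(item.levels)]


def build_codebook(variant: str) -> FeatureCodebook:
    """Ordered feature variables for encoding variant ``a`` or ``b``.

    Variant a yields 58 features, variant b 126; medication, the free-text
    item and the label contribute none.
    """
    if variant not in ("a", "b"):
        raise ValueError(f"unknown variant {variant!r} (expected 'a' or 'b')")
    feats: list[FeatureVar] = []
    for item in modelling_items():
        i = len(feats)
        if item.kind == "Q":
            feats.append(FeatureVar(i, item.item_id, item.item_id, "Q"))
        elif item.kind == "B":
            feats.append(FeatureVar(i, item.item_id, item.item_id, "B"))
        elif item.kind == "C":
            if item.item_id == "mode_of_onset" and variant == "a":
                feats.append(FeatureVar(i, item.item_id, item.item_id, "O"))
            else:
                feats.extend(_onehot_vars(item, i))
        elif item.kind == "O":
            if variant == "a":
                feats.append(FeatureVar(i, item.item_id, item.item_id, "O"))
            else:
                feats.extend(_onehot_vars(item, i))
    return FeatureCodebook(variant, tuple(feats))


def _raw_columns(cohort: Cohort, codebook: FeatureCodebook) -> np.ndarray:
    """Encode all non-Q features; Q columns hold raw values (un-normalised)."""
    df = cohort.df
    n = len(df)
    X = np.empty((n, len(codebook)), dtype=np.float64)
    female = df["sex"].to_numpy() == 2
    for f in codebook.features:
        if f.source_item_id in df.columns:
            col = df[f.source_item_id].to_numpy(dtype=float)
        else:
            col = np.full(n, np.nan)
        if f.source_item_id == "auto_erectile_dysfunction":
            # structurally absent for female cases -> absence code
            col = np.where(female & np.isnan(col), float(ABSENCE), col)
        if np.isnan(col).any():
            bad = df.loc[np.isnan(col), "case_id"].iloc[0]
            raise ValueError(
                f"missing answer for {f.source_item_id} (case {bad}); "
                "run exclude_incomplete first")
        if f.encoding == "B":
            X[:, f.index] = col - 1.0  # presence(1)->0, absence(2)->1
        elif f.encoding == "C_level":
            X[:, f.index] = (col == f.level).astype(float)
        else:  # O and raw Q
            X[:, f.index] = col
    return X


def fit_normalization(cohort: Cohort, codebook: FeatureCodebook) -> NormStats:
    """Training-set mean/sd for the quantitative features (sd floored)."""
    X = _raw_columns(cohort, codebook)
    mean, sd = {}, {}
    for f in codebook.features:
        if f.encoding == "Q":
            mean[f.name] = float(X[:, f.index].mean())
            sd[f.name] = float(max(X[:, f.index].std(), SD_FLOOR))
    return NormStats(mean, sd)


def encode_cohort(cohort: Cohort, codebook: FeatureCodebook,
                  norm_stats: NormStats) -> DesignMatrix:
    """Encode a complete-case cohort into a design matrix.

    Row order follows the cohort; a missing answer raises (complete-case
    exclusion happens upstream). Quantitative columns are standardised with
    the supplied (training-set) statistics.
    """
    X = _raw_columns(cohort, codebook)
    for f in codebook.features:
        if f.encoding == "Q":
            X[:, f.index] = (X[:, f.index] - norm_stats.mean[f.name]) \
                / norm_stats.sd[f.name]
    labels = cohort.df[LABEL_COLUMN].to_numpy(dtype=object)
    case_ids = cohort.df["case_id"].to_numpy(dtype=object)
    return DesignMatrix(X, codebook, labels, norm_stats, case_ids)


def decode_row(row: np.ndarray, codebook: FeatureCodebook) -> CaseRecord:
    """Invert the encoding of one design-matrix row (partial record).

    Binary, ordinal and one-hot features are mapped back to registry codes;
    quantitative features keep their standardised value. A one-hot group with
    anything other than exactly one 1 is malformed and raises.
    """
    row = np.asarray(row, dtype=float)
    if row.shape != (len(codebook),):
        raise ValueError("row length does not match codebook")
    answers: dict = {}
    for f in codebook.features:
        if f.encoding == "B":
            answers[f.source_item_id] = int(row[f.index]) + 1
        elif f.encoding == "O":
            answers[f.source_item_id] = int(row[f.index])
        elif f.encoding == "Q":
            answers[f.source_item_id] = float(row[f.index])
    for item_id, group in codebook.onehot_groups().items():
        hot = [f for f in group if row[f.index] == 1.0]
        zeros = [f for f in group if row[f.index] == 0.0]
        if len(hot) != 1 or len(hot) + len(zeros) != len(group):
            raise ValueError(f"malformed one-hot group for {item_id}")
        answers[item_id] = hot[0].level
    return CaseRecord("decoded", answers, None)
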