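"""Registration-form schema for the national MSA case registry.

The registry form records one case of multiple-system atrophy per submission:
demographics, symptoms at onset, mode of onset and progression, graded
neurological findings (ICARS/UPDRS/UMSARS-derived items), autonomic findings,
other neurological findings, brain imaging flags, activities of daily living
(ADL), medication, and the neurologist's subtype diagnosis (SND = striatonigral
degeneration, SDS = Shy-Drager syndrome, OPCA = olivopontocerebellar atrophy).

Registry coding conventions this module enforces:

* two-level (binary) items are coded ``1 = presence, 2 = absence`` — note this
  is reversed from the usual 1/0 indicator convention;
* graded items are coded with small positive integers starting at 1
  (walking capacity 1-9, standing capacity 1-8, other neurological grades 1-5,
  ADL 1-3 except walking 1-4);
* erectile dysfunction is asked of male cases only;
* medication items and the free-text "other findings" item are carried in the
  schema but excluded from modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import json
import numpy as np
import pandas as pd

__all__ = [
    "ItemDef",
    "CaseRecord",
    "Cohort",
    "Violation",
    "SUBTYPES",
    "LABEL_COLUMN",
    "form_schema",
    "modelling_items",
    "validate_case",
    "exclude_incomplete",
]

SUBTYPES = ("SND", "SDS", "OPCA")
LABEL_COLUMN = "diagnosis"

#: registry code for a present finding on a two-level item
PRESENCE = 1
#: registry code for an absent finding on a two-level item
ABSENCE = 2


@dataclass(frozen=True)
class ItemDef:
    """One item of the registration form.

    ``kind`` follows the dataset taxonomy: B(inary), C(ategorical), O(rdinal),
    Q(uantitative); the free-text item uses T(ext) and is never modelled.
    """

    item_id: str
    group: str  # sex|age|onset|mode|progression|neuro|autonomic|other_neuro|brain|adl|medication|diagnosis
    kind: str  # B | C | O | Q | T
    levels: tuple[int, ...]
    label: str
    male_only: bool = False
    modelled: bool = True
    is_label: bool = False

    def is_legal(self, code) -> bool:
        if self.kind == "Q":
            try:
                return float(code) > 0
            except (TypeError, ValueError):
                return False
        if self.kind == "T":
            return True
        try:
            return int(code) in self.levels
        except (TypeError, ValueError):
            return False


@dataclass
class CaseRecord:
    """One registry submission: raw coded answers plus the subtype label."""

    case_id: str
    answers: dict
    label: str | None = None


@dataclass(frozen=True)
class Violation:
    case_id: str
    item_id: str
    code: object
    message: str


def _b(item_id, group, label, **kw) -> ItemDef:
    return ItemDef(item_id, group, "B", (PRESENCE, ABSENCE), label, **kw)


def _o(item_id, group, lo, hi, label) -> ItemDef:
    return ItemDef(item_id, group, "O", tuple(range(lo, hi + 1)), label)


_NEURO = [
    ("neuro_walking_capacity", 1, 9, "Walking capacity"),
    ("neuro_gait_parkinsonism", 1, 5, "Gait abnormalities due to parkinsonism"),
    ("neuro_standing_capacity", 1, 8, "Standing capacity, eyes open"),
    ("neuro_bent_posture", 1, 5, "Bent posture"),
    ("neuro_posture_stability", 1, 5, "Posture stability"),
    ("neuro_finger_to_nose", 1, 5, "Finger-to-nose test"),
    ("neuro_knee_tibia", 1, 5, "Knee-tibia test"),
    ("neuro_tremor_at_rest", 1, 5, "Tremor at rest"),
    ("neuro_rigidity", 1, 5, "Rigidity"),
    ("neuro_finger_taps", 1, 5, "Finger taps"),
    ("neuro_rising_from_chair", 1, 5, "Rising from a chair"),
]

_OTHER_NEURO_BINARY = [
    ("oth_dementia", "Dementia"),
    ("oth_hallucination", "Hallucination (non-drug-induced)"),
    ("oth_aphasia", "Aphasia"),
    ("oth_apraxia", "Apraxia"),
    ("oth_agnosia", "Agnosia"),
    ("oth_alien_hand", "Alien hand sign"),
    ("oth_vertical_gaze_palsy", "Vertical supranuclear gaze palsy"),
    ("oth_nystagmus", "Persistent spontaneous nystagmus"),
    ("oth_dysphagia", "Dysphagia"),
    ("oth_dysarthria", "Dysarthria"),
    ("oth_respiratory_failure", "Respiratory failure"),
    ("oth_babinski_reflex", "Babinski reflex"),
]

_BRAIN = [
    ("img_ct_examination", "CT examination"),
    ("img_mri_examination", "MRI examination"),
    ("img_cerebellar_atrophy", "Cerebellar atrophy"),
    ("img_brainstem_atrophy", "Brain-stem atrophy"),
    ("img_hot_cross_bun", "Hot-cross-bun sign"),
    ("img_striatal_abnormality", "Striatal atrophy/signal abnormality"),
    ("img_third_ventricle", "Enlargement of 3rd ventricle"),
    ("img_cerebral_atrophy", "Cerebral atrophy"),
    ("img_white_matter_lesion", "Cerebral white-matter lesion"),
]

_ADL = [
    ("adl_eating", 1, 3, "Eating"),
    ("adl_bathing", 1, 3, "Bathing"),
    ("adl_hygiene", 1, 3, "Hygiene"),
    ("adl_dressing", 1, 3, "Dressing"),
    ("adl_toileting", 1, 3, "Toileting"),
    ("adl_walking", 1, 4, "Walking (more than 50 m)"),
    ("adl_climbing_stairs", 1, 3, "Climbing stairs"),
]

_MEDICATION = [
    ("med_taltirelin", "Taltirelin hydrate"),
    ("med_protirelin", "Protirelin tartrate hydrate"),
    ("med_levodopa", "Levodopa"),
    ("med_dopamine_agonist", "Dopamine receptor agonists"),
    ("med_amantadine", "Amantadine hydrochloride"),
    ("med_anticholinergic", "Anticholinergics"),
    ("med_maob_inhibitor", "MAO-B inhibitors"),
    ("med_droxidopa", "Droxidopa"),
]


def form_schema() -> list[ItemDef]:
    """The full registration form, in form order.

    Medication items and the free-text other-findings item are returned with
    ``modelled=False``; the diagnosis item carries ``is_label=True``.
    """
    items: list[ItemDef] = [
        _b("sex", "sex", "Sex (1 male, 2 female)"),
        ItemDef("age", "age", "Q", (), "Age at registration (years)"),
        _b("onset_ataxia", "onset", "Symptoms at onset: ataxia"),
        _b("onset_parkinsonism", "onset", "Symptoms at onset: parkinsonism"),
        _b("onset_autonomic", "onset", "Symptoms at onset: autonomic dysfunction"),
        ItemDef("mode_of_onset", "mode", "C", (1, 2, 3),
                "Mode of onset (1 mild, 2 subacute, 3 acute)"),
        ItemDef("progression", "progression", "C", (1, 2, 3, 4),
                "Progression (1 progressive, 2 arrested, 3 improved, 4 other)"),
    ]
    items += [_o(i, "neuro", lo, hi, lab) for i, lo, hi, lab in _NEURO]
    items += [
        _b("auto_head_up_tilt", "autonomic", "Head-up tilt test (positive)"),
        _b("auto_syncope", "autonomic", "Syncope"),
        _b("auto_urinary_disturbance", "autonomic", "Urinary disturbances"),
        _b("auto_urinary_incontinence", "autonomic", "Urinary incontinence"),
        _b("auto_erectile_dysfunction", "autonomic",
           "Erectile dysfunction (males only)", male_only=True),
        _b("auto_severe_constipation", "autonomic", "Severe constipation"),
    ]
    other = [_b(i, "other_neuro", lab) for i, lab in _OTHER_NEURO_BINARY]
    # tendon reflex sits at position 12 of the other-neurological block
    other.insert(11, ItemDef(
        "oth_tendon_reflex", "other_neuro", "C", (1, 2, 3),
        "Tendon reflex (1 increased, 2 decreased, 3 normal)"))
    items += other
    items.append(ItemDef("oth_other_findings", "other_neuro", "T", (),
                         "Other neurological findings (free text)",
                         modelled=False))
    items += [_b(i, "brain", lab) for i, lab in _BRAIN]
    items += [_o(i, "adl", lo, hi, lab) for i, lo, hi, lab in _ADL]
    items += [ItemDef(i, "medication", "C", (1, 2, 3),
                      f"{lab} (1 not used, 2 used, 3 unknown)", modelled=False)
              for i, lab in _MEDICATION]
    items.append(ItemDef(LABEL_COLUMN, "diagnosis", "C", (1, 2, 3),
                         "Diagnosis (SND / SDS / OPCA)", modelled=False,
                         is_label=True))
    return items


def modelling_items(schema: Sequence[ItemDef] | None = None) -> list[ItemDef]:
    """Items that enter the design matrix (medication/free text/label excluded)."""
    schema = form_schema() if schema is None else schema
    return [it for it in schema if it.modelled and not it.is_label]


def schema_by_id(schema: Sequence[ItemDef] | None = None) -> dict[str, ItemDef]:
    schema = form_schema() if schema is None else schema
    return {it.item_id: it for it in schema}


class Cohort:
    """A set of registry cases, stored as one row per case.

    Columns are item_ids plus ``case_id`` and ``diagnosis``; a missing answer
    is an empty cell (pandas NA). A JSON sidecar records provenance and seed.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = "file",
                 seed: int | None = None):
        if df["case_id"].duplicated().any():
            raise ValueError("case_ids must be unique")
        self.df = df.reset_index(drop=True)
        self.provenance = provenance
        self.seed = seed

    def __len__(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> pd.Series:
        return self.df[LABEL_COLUMN]

    def records(self) -> Iterable[CaseRecord]:
        item_cols = [c for c in self.df.columns
                     if c not in ("case_id", LABEL_COLUMN)]
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            answers = {c: d[c] for c in item_cols if not pd.isna(d[c])}
            yield CaseRecord(str(d["case_id"]), answers, d.get(LABEL_COLUMN))

    @classmethod
    def from_records(cls, records: Sequence[CaseRecord], **kw) -> "Cohort":
        rows = []
        for r in records:
            row = {"case_id": r.case_id, LABEL_COLUMN: r.label}
            row.update(r.answers)
            rows.append(row)
        df = pd.DataFrame(rows)
        return cls(df, **kw)

    def to_csv(self, path, sidecar: bool = True) -> None:
        self.df.to_csv(path, index=False)
        if sidecar:
            meta = {"provenance": self.provenance, "seed": self.seed,
                    "n_cases": len(self)}
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def read_csv(cls, path) -> "Cohort":
        df = pd.read_csv(path)
        prov, seed = "file", None
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
            prov, seed = meta.get("provenance", "file"), meta.get("seed")
        except FileNotFoundError:
            pass
        return cls(df, provenance=prov, seed=seed)


def validate_case(record: CaseRecord, schema: Sequence[ItemDef] | None = None
                  ) -> list[Violation]:
    """Check every answer of one record against the form schema.

    Returns an empty list iff the record is legal. Unknown item_ids, illegal
    codes, a non-positive age, an answer on a male-only item for a female
    case, and a missing/unknown label each produce one violation.
    """
    schema = form_schema() if schema is None else schema
    by_id = {it.item_id: it for it in schema}
    out: list[Violation] = []
    sex = record.answers.get("sex")
    is_female = (not pd.isna(sex)) and int(sex) == 2 if sex is not None else False
    for item_id, code in record.answers.items():
        if pd.isna(code):
            continue
        it = by_id.get(item_id)
        if it is None:
            out.append(Violation(record.case_id, item_id, code,
                                 "unknown item"))
            continue
        if it.male_only and is_female:
            out.append(Violation(record.case_id, item_id, code,
                                 "answer on a male-only item for a female case"))
            continue
        if not it.is_legal(code):
            out.append(Violation(
                record.case_id, item_id, code,
                f"illegal code for {item_id} (legal: {it.levels or 'positive number'})"))
    if record.label not in SUBTYPES:
        out.append(Violation(record.case_id, LABEL_COLUMN, record.label,
                             "missing or unknown diagnosis label"))
    return out


def _required_mask(df: pd.DataFrame, required: Sequence[ItemDef]) -> np.ndarray:
    """Boolean mask of rows with a missing answer on any required item.

    A male-only item counts as required only for male cases (structural
    absence for females is not missing data).
    """
    missing = np.zeros(len(df), dtype=bool)
    female = df["sex"].to_numpy() == 2 if "sex" in df else np.zeros(len(df), bool)
    for it in required:
        if it.item_id not in df.columns:
            col_missing = np.ones(len(df), dtype=bool)
        else:
            col_missing = df[it.item_id].isna().to_numpy()
        if it.male_only:
            col_missing &= ~female
        missing |= col_missing
    return missing


def exclude_incomplete(cohort: Cohort,
                       required_items: Sequence[ItemDef] | None = None
                       ) -> tuple[Cohort, int]:
    """Complete-case filter applied before modelling.

    Drops every case with a missing answer on any required item (default: all
    modelling items). Returns the kept cohort, in the original order, and the
    number excluded. Idempotent; kept + excluded partition the input.
    """
    if len(cohort) == 0:
        return cohort, 0
    required = modelling_items() if required_items is None else list(required_items)
    missing = _required_mask(cohort.df, required)
    kept = Cohort(cohort.df.loc[~missing], provenance=cohort.provenance,
                  seed=cohort.seed)
    return kept, int(missing.sum())
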