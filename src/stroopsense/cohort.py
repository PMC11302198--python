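"""Synthetic multimodal wearable cohort generator.

Emulates a case-control study in which each participant (control group CG,
experimental group EG) performs a series of Stroop tests while a wrist-worn
sensor records electrodermal activity (EDA), heart-rate variability (HRV)
and skin temperature (ST).  Proprietary per-test feature extraction is not
modelled; instead each (participant, test) row carries a fused feature
vector drawn from an additive Gaussian model whose structure matches what
the downstream screening and classification stages assume:

* same-type tests (e.g. the three colour-word variants) are nearly
  exchangeable at the individual level — they share a per-(feature, type)
  offset and differ only by residual noise;
* different test types are shifted against each other through those
  offsets;
* a group effect (a standardized mean shift for EG) is planted in a
  type-specific fraction of the features, concentrated by default in the
  number-test features.

The value for participant *i*, feature *f*, test *t* of type *T* is

    mu_f + a_i + b_{f,T} + effect_size * sigma_eps * z_{f,T} * 1[group=EG]
         + eps_{i,f,t}

with a_i ~ N(0, subject_scale), b_{f,T} ~ N(0, type_shift_scale) shared by
all tests of type T, eps ~ N(0, within_type_noise = sigma_eps), and
z_{f,T} an indicator planted for exactly round(effect_fraction[T] * n_features)
features.  Gaussian marginals suffice because every downstream statistic is
rank-based, distribution-free, or standardized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import round_half_up
from .errors import InvalidSpecError

__all__ = [
    "CohortSpec",
    "ParticipantRecord",
    "FeatureTable",
    "generate_cohort",
    "planted_truth",
]

#: default ordered test labels and their type map
DEFAULT_TEST_LABELS = ("C1", "C2", "C3", "N-S", "N-V", "E")
DEFAULT_TEST_TYPES = {"C1": "C", "C2": "C", "C3": "C", "N-S": "N", "N-V": "N", "E": "E"}


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of the synthetic generative model.

    Defaults mirror the emulated study: 44 controls and 32 cases analysed,
    191 fused features (103 EDA + 77 HRV + 11 ST), six Stroop tests in
    three types, group effects planted in 52% of number-test features but
    only 10.4% / 3.6% of colour-word / emotion-test features, and 19
    additional participants generated then dropped (4 incomplete, 15 with
    unretrievable data) so the recruitment bookkeeping (95 enrolled -> 76
    analysed) is reproducible.
    """

    n_cg: int = 44
    n_eg: int = 32
    n_features_per_modality: dict[str, int] = field(
        default_factory=lambda: {"EDA": 103, "HRV": 77, "ST": 11}
    )
    test_labels: tuple[str, ...] = DEFAULT_TEST_LABELS
    test_types: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TEST_TYPES))
    effect_fraction: dict[str, float] = field(
        default_factory=lambda: {"C": 0.104, "N": 0.52, "E": 0.036}
    )
    effect_size: float = 1.5
    type_shift_scale: float = 1.0
    subject_scale: float = 0.5
    within_type_noise: float = 1.0
    n_incomplete: int = 4
    n_unretrievable: int = 15
    dropout_cg: int = 14  # of the dropouts, how many belong to the control group
    age_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"CG": (35.18, 11.14), "EG": (32.58, 11.39)}
    )
    gender_params: dict[str, float] = field(
        default_factory=lambda: {"CG": 32 / 58, "EG": 24 / 37}
    )  # male fraction per group
    seed: int = 0

    @property
    def n_features(self) -> int:
        return sum(self.n_features_per_modality.values())

    @property
    def feature_names(self) -> list[str]:
        """Fused feature order: modality blocks concatenated."""
        return [
            f"{mod}_f{k + 1}"
            for mod, n in self.n_features_per_modality.items()
            for k in range(n)
        ]

    @property
    def n_dropout(self) -> int:
        return self.n_incomplete + self.n_unretrievable

    def validate(self) -> None:
        if self.n_cg < 0 or self.n_eg < 0:
            raise InvalidSpecError("group sizes must be non-negative")
        if any(v < 0 for v in self.n_features_per_modality.values()):
            raise InvalidSpecError("feature counts must be non-negative")
        if len(set(self.test_labels)) != len(self.test_labels):
            raise InvalidSpecError("duplicate test labels")
        if set(self.test_labels) != set(self.test_types):
            raise InvalidSpecError("test_types must map exactly the test labels")
        for t, frac in self.effect_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise InvalidSpecError(f"effect fraction for {t!r} outside [0, 1]")
        for name in ("type_shift_scale", "subject_scale", "within_type_noise"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be non-negative")
        if self.n_incomplete < 0 or self.n_unretrievable < 0:
            raise InvalidSpecError("dropout counts must be non-negative")
        if not 0 <= self.dropout_cg <= self.n_dropout:
            raise InvalidSpecError("dropout_cg must lie within the total dropout count")
        if any(self.effect_fraction.values()):
            if (self.n_cg == 0 or self.n_eg == 0) and self.n_features > 0:
                raise InvalidSpecError(
                    "group effects requested but one group is empty"
                )

    def with_(self, **kwargs) -> "CohortSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    group: str  # "CG" | "EG"
    age: float
    gender: str  # "M" | "F"
    completed: bool
    data_retrievable: bool

    @property
    def analyzed(self) -> bool:
        return self.completed and self.data_retrievable


@dataclass
class FeatureTable:
    """Labelled per-(participant, test) multimodal feature vectors.

    ``data`` holds one row per (participant, test) with columns
    ``participant_id``, ``group``, ``test`` followed by the feature
    columns; ``modalities`` maps each modality to its ordered feature
    names.  Fusion is the concatenation of the modality blocks, so the
    full feature order is fixed across rows.
    """

    data: pd.DataFrame
    modalities: dict[str, list[str]]

    ID_COLUMNS = ("participant_id", "group", "test")

    @property
    def feature_names(self) -> list[str]:
        return [f for names in self.modalities.values() for f in names]

    @property
    def test_labels(self) -> list[str]:
        return list(dict.fromkeys(self.data["test"]))

    def matrix(self) -> np.ndarray:
        """Feature values as a (rows, features) float array in fused order."""
        return self.data[self.feature_names].to_numpy(dtype=float)

    def select_modalities(self, modalities: list[str] | tuple[str, ...]) -> "FeatureTable":
        """Restrict the feature blocks to a subset of modalities (order kept)."""
        keep = {m: list(self.modalities[m]) for m in self.modalities if m in set(modalities)}
        cols = list(self.ID_COLUMNS) + [f for names in keep.values() for f in names]
        return FeatureTable(self.data[cols].reset_index(drop=True), keep)

    def select_tests(self, tests: list[str] | tuple[str, ...]) -> "FeatureTable":
        """Restrict the rows to a subset of test labels."""
        mask = self.data["test"].isin(set(tests))
        return FeatureTable(self.data.loc[mask].reset_index(drop=True), dict(self.modalities))


def _planting_rng(spec: CohortSpec) -> np.random.Generator:
    # dedicated stream so planted_truth never consumes the data-noise stream
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), 7]))


def planted_truth(spec: CohortSpec) -> dict[str, set[str]]:
    """Ground-truth affected feature sets per test type.

    Returns exactly the indicator sets used by :func:`generate_cohort` for
    the same spec and seed: for each test type ``T``,
    ``round(effect_fraction[T] * n_features)`` feature names (round half
    up), chosen by a seed-derived random priority with ties broken by
    feature index order.
    """
    spec.validate()
    names = spec.feature_names
    rng = _planting_rng(spec)
    types = list(dict.fromkeys(spec.test_types[t] for t in spec.test_labels))
    truth: dict[str, set[str]] = {}
    for t in types:
        frac = spec.effect_fraction.get(t, 0.0)
        m = round_half_up(frac * len(names))
        priority = rng.random(len(names))
        order = np.argsort(priority, kind="stable")  # ties fall back to index order
        truth[t] = {names[j] for j in order[:m]}
    return truth


def _truncated_normal_ages(
    rng: np.random.Generator, mean: float, sd: float, n: int, lower: float = 18.0
) -> np.ndarray:
    """Rejection-sample ages from N(mean, sd) truncated below at ``lower``."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 8)
        draw = draw[draw >= lower]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return np.round(out, 1)


def generate_cohort(spec: CohortSpec) -> tuple[list[ParticipantRecord], FeatureTable]:
    """Generate participant records and the fused feature table.

    Dropout participants (incomplete or with unretrievable data) are
    generated and flagged but excluded from the feature table, so the
    recruitment flow counts are reproducible as bookkeeping.  Bit-identical
    output for identical specs.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 11]))
    names = spec.feature_names
    n_feat = len(names)
    types = list(dict.fromkeys(spec.test_types[t] for t in spec.test_labels))
    truth = planted_truth(spec)

    # --- participants ---------------------------------------------------
    dropout_groups = ["CG"] * spec.dropout_cg + ["EG"] * (spec.n_dropout - spec.dropout_cg)
    rng.shuffle(dropout_groups)
    groups = ["CG"] * spec.n_cg + ["EG"] * spec.n_eg + dropout_groups
    records: list[ParticipantRecord] = []
    n_total = len(groups)
    width = len(str(max(n_total, 1)))
    for idx, group in enumerate(groups):
        mean, sd = spec.age_params[group]
        age = float(_truncated_normal_ages(rng, mean, sd, 1)[0])
        gender = "M" if rng.random() < spec.gender_params[group] else "F"
        n_analyzed = spec.n_cg + spec.n_eg
        dropout_rank = idx - n_analyzed  # >= 0 for dropout participants
        incomplete = 0 <= dropout_rank < spec.n_incomplete
        unretrievable = dropout_rank >= spec.n_incomplete
        records.append(
            ParticipantRecord(
                participant_id=f"P{idx + 1:0{width}d}",
                group=group,
                age=age,
                gender=gender,
                completed=not incomplete,
                data_retrievable=not unretrievable,
            )
        )

    # --- feature values for analysed participants -----------------------
    analyzed = [r for r in records if r.analyzed]
    n_sub = len(analyzed)
    mu = rng.normal(0.0, 1.0, size=n_feat)  # per-feature baseline
    subject_effect = rng.normal(0.0, spec.subject_scale, size=n_sub)
    type_shift = {t: rng.normal(0.0, spec.type_shift_scale, size=n_feat) for t in types}
    z = {
        t: np.array([1.0 if f in truth[t] else 0.0 for f in names]) for t in types
    }
    delta = spec.effect_size * spec.within_type_noise

    rows = []
    values = []
    for i, rec in enumerate(analyzed):
        is_eg = 1.0 if rec.group == "EG" else 0.0
        for test in spec.test_labels:
            t = spec.test_types[test]
            eps = rng.normal(0.0, spec.within_type_noise, size=n_feat)
            vec = mu + subject_effect[i] + type_shift[t] + delta * z[t] * is_eg + eps
            rows.append((rec.participant_id, rec.group, test))
            values.append(vec)

    data = pd.DataFrame(rows, columns=list(FeatureTable.ID_COLUMNS))
    data = pd.concat(
        [data, pd.DataFrame(np.asarray(values), columns=names)], axis=1
    )
    modalities = {}
    offset = 0
    for mod, n in spec.n_features_per_modality.items():
        modalities[mod] = names[offset : offset + n]
        offset += n
    return records, FeatureTable(data, modalities)
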