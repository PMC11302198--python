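"""Two-step univariate feature screening.

Step one works *within* each group: for every pair of Stroop tests, a
two-sided Wilcoxon signed-rank test is run per feature on the paired
per-participant values, and the fraction of features significant at the
cutoff is recorded.  Pairs of tests whose significant-feature ratio is low
in both groups had minimal impact at the individual level, so their rows
can be pooled ("bundled") under a common label.

Step two works *between* groups: for each bundle, the rows of its member
tests are pooled per group and each feature is compared CG vs EG with a
two-sample Kolmogorov-Smirnov test.  The bundle with the largest fraction
of significantly different features is selected as the input to the
classification stage.

Pooled rows of a bundle are treated as independent samples in the KS test;
this mirrors the screening design being emulated (low within-type pairwise
ratios are taken to justify treating the paired data as uncorrelated) and
is a documented approximation, not a statistical endorsement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import FeatureTable, ParticipantRecord
from .errors import (
    InsufficientSampleError,
    InvalidParameterError,
    MissingBundleError,
)

__all__ = [
    "PairwiseRatioMatrix",
    "BundleMap",
    "GroupDifferenceReport",
    "DemographicsSummary",
    "FIXED_BUNDLES",
    "pairwise_within_group_ratio",
    "bundle_tests",
    "ks_between_group_ratio",
    "demographic_comparison",
]

#: the fixed test bundling used by the default pipeline: colour-word tests
#: merge into C, number tests into N, the emotion test stands alone.
FIXED_BUNDLES: dict[str, str] = {
    "C1": "C",
    "C2": "C",
    "C3": "C",
    "N-S": "N",
    "N-V": "N",
    "E": "E",
}


@dataclass
class PairwiseRatioMatrix:
    """Fraction of features significantly different per pair of tests."""

    group: str
    test_labels: list[str]
    ratios: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]
    alpha: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ratios, index=self.test_labels, columns=self.test_labels)


@dataclass
class BundleMap:
    """Total mapping of original test labels onto bundle labels."""

    mapping: dict[str, str]

    @property
    def bundles(self) -> list[str]:
        return list(dict.fromkeys(self.mapping.values()))

    def members(self, bundle: str) -> list[str]:
        return [t for t, b in self.mapping.items() if b == bundle]


@dataclass
class GroupDifferenceReport:
    """Per-bundle CG-vs-EG significant-feature ratios and the selected bundle."""

    overall: dict[str, float]  # bundle -> ratio over all features
    per_modality: dict[str, dict[str, float]]  # bundle -> modality -> ratio
    significant: dict[str, set[str]]  # bundle -> significant feature names
    selected_bundle: str
    alpha: float


@dataclass
class DemographicsSummary:
    group_sizes: dict[str, int]
    age_mean: dict[str, float]
    age_std: dict[str, float]
    gender_table: pd.DataFrame  # groups x {M, F}
    t_statistic: float
    t_df: int
    t_pvalue: float
    chi2_statistic: float
    chi2_df: int
    chi2_n: int
    chi2_pvalue: float


def _paired_matrices(
    table: FeatureTable, group: str, test_a: str, test_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-participant paired value matrices for two tests within one group."""
    df = table.data
    sub = df[df["group"] == group]
    a = sub[sub["test"] == test_a].set_index("participant_id")
    b = sub[sub["test"] == test_b].set_index("participant_id")
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise InsufficientSampleError(
            f"no common participants for tests {test_a!r} and {test_b!r} in {group}"
        )
    if len(common) < 5:
        raise InsufficientSampleError(
            f"only {len(common)} paired participants for {test_a!r} vs {test_b!r}"
        )
    feats = table.feature_names
    return (
        a.loc[common, feats].to_numpy(float),
        b.loc[common, feats].to_numpy(float),
    )


def pairwise_within_group_ratio(
    table: FeatureTable, group: str, alpha: float = 0.1
) -> PairwiseRatioMatrix:
    """Wilcoxon signed-rank significant-feature ratios for all test pairs.

    For each feature and each unordered pair of tests, the paired
    per-participant differences are tested two-sided; zero differences are
    dropped before ranking (the classic Wilcoxon convention) and a feature
    whose differences are all zero counts as non-significant.  The matrix
    entry is the fraction of features with P <= alpha (inclusive cutoff).
    """
    labels = table.test_labels
    n = len(labels)
    ratios = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            va, vb = _paired_matrices(table, group, labels[i], labels[j])
            diffs = va - vb
            sig = 0
            for col in range(diffs.shape[1]):
                d = diffs[:, col]
                if np.all(d == 0):
                    continue  # identical paired values: non-significant
                p = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided").pvalue
                if p <= alpha:
                    sig += 1
            ratios[i, j] = ratios[j, i] = sig / diffs.shape[1]
    return PairwiseRatioMatrix(group=group, test_labels=labels, ratios=ratios, alpha=alpha)


def _bundle_name(members: list[str]) -> str:
    """Shared type prefix when unambiguous, else concatenated labels."""
    if len(members) == 1:
        return members[0]
    prefix = members[0]
    for m in members[1:]:
        while not m.startswith(prefix):
            prefix = prefix[:-1]
    prefix = prefix.rstrip("-_")
    return prefix if prefix else "+".join(members)


def bundle_tests(
    cg: PairwiseRatioMatrix, eg: PairwiseRatioMatrix, tau: float = 0.2
) -> BundleMap:
    """Merge tests whose pairwise ratio is <= tau in BOTH groups.

    Builds a graph on test labels with an edge where both groups' ratios
    are at or below the threshold; bundles are the connected components.
    """
    if not 0.0 <= tau <= 1.0:
        raise InvalidParameterError(f"tau must lie in [0, 1], got {tau}")
    if cg.test_labels != eg.test_labels:
        raise InvalidParameterError("matrices must share test labels")
    labels = cg.test_labels
    n = len(labels)
    # union-find over test labels
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if cg.ratios[i, j] <= tau and eg.ratios[i, j] <= tau:
                parent[find(i)] = find(j)

    components: dict[int, list[str]] = {}
    for i, lab in enumerate(labels):
        components.setdefault(find(i), []).append(lab)
    mapping: dict[str, str] = {}
    for members in components.values():
        members = sorted(members, key=labels.index)
        name = _bundle_name(members)
        for m in members:
            mapping[m] = name
    return BundleMap({lab: mapping[lab] for lab in labels})


def ks_between_group_ratio(
    table: FeatureTable,
    bundles: BundleMap | dict[str, str],
    alpha: float = 0.1,
    method: str = "asymp",
) -> GroupDifferenceReport:
    """Two-sample KS CG-vs-EG screening per bundle.

    Rows of a bundle's member tests are pooled per group and each feature
    is tested two-sided; the report carries the overall and per-modality
    significant-feature ratios and selects the argmax bundle (ties broken
    by bundle order).  P-values use the asymptotic KS distribution by
    default; the pooled per-group sample sizes here are comfortably large
    for it.
    """
    if isinstance(bundles, dict):
        bundles = BundleMap(dict(bundles))
    df = table.data
    present = set(df["test"])
    feats = table.feature_names
    overall: dict[str, float] = {}
    per_modality: dict[str, dict[str, float]] = {}
    significant: dict[str, set[str]] = {}
    for bundle in bundles.bundles:
        members = [t for t in bundles.members(bundle) if t in present]
        if not members:
            raise MissingBundleError(f"bundle {bundle!r} has no rows in the table")
        sub = df[df["test"].isin(members)]
        cg = sub[sub["group"] == "CG"]
        eg = sub[sub["group"] == "EG"]
        sig: set[str] = set()
        for f in feats:
            p = stats.ks_2samp(
                cg[f].to_numpy(float), eg[f].to_numpy(float), method=method
            ).pvalue
            if p <= alpha:
                sig.add(f)
        significant[bundle] = sig
        overall[bundle] = len(sig) / len(feats)
        per_modality[bundle] = {
            mod: len(sig.intersection(names)) / len(names)
            for mod, names in table.modalities.items()
        }
    selected = max(overall, key=lambda b: (overall[b], -bundles.bundles.index(b)))
    return GroupDifferenceReport(
        overall=overall,
        per_modality=per_modality,
        significant=significant,
        selected_bundle=selected,
        alpha=alpha,
    )


def demographic_comparison(records: list[ParticipantRecord]) -> DemographicsSummary:
    """Group demographic comparison: pooled-variance t-test on age and a
    Yates-corrected Pearson chi-square on the 2x2 gender table.

    The t statistic uses the pooled variance, so its degrees of freedom are
    n1 + n2 - 2; the chi-square on a 2x2 table has one degree of freedom.
    """
    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise InsufficientSampleError("exactly two groups required")
    by_group = {g: [r for r in records if r.group == g] for g in groups}
    for g, members in by_group.items():
        if len(members) < 2:
            raise InsufficientSampleError(f"group {g!r} has fewer than 2 members")

    ages = {g: np.array([r.age for r in members]) for g, members in by_group.items()}
    g1, g2 = groups
    t_stat, t_p = stats.ttest_ind(ages[g1], ages[g2], equal_var=True)
    gender_table = pd.DataFrame(
        {
            "M": [sum(r.gender == "M" for r in by_group[g]) for g in groups],
            "F": [sum(r.gender == "F" for r in by_group[g]) for g in groups],
        },
        index=groups,
    )
    chi2, chi2_p, chi2_df, _ = stats.chi2_contingency(
        gender_table.to_numpy(), correction=True
    )
    return DemographicsSummary(
        group_sizes={g: len(by_group[g]) for g in groups},
        age_mean={g: float(np.mean(ages[g])) for g in groups},
        age_std={g: float(np.std(ages[g], ddof=1)) for g in groups},
        gender_table=gender_table,
        t_statistic=float(t_stat),
        t_df=len(ages[g1]) + len(ages[g2]) - 2,
        t_pvalue=float(t_p),
        chi2_statistic=float(chi2),
        chi2_df=int(chi2_df),
        chi2_n=int(gender_table.to_numpy().sum()),
        chi2_pvalue=float(chi2_p),
    )
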