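"""Formats, configuration, orchestration and reporting glue.

All tables are delimited text with an explicit schema header line, so every
artifact is human-readable, diff-able and fully portable.  A pipeline run
is described by a :class:`RunConfig` and leaves behind a
:class:`RunManifest` recording the config snapshot, seed, per-stage output
paths and checksums — enough to regenerate any artifact bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec, FeatureTable, ParticipantRecord, generate_cohort
from .errors import IntegrityError, InvalidParameterError, SchemaError
from .iknn import NeighborhoodConfig, filter_points
from .pipeline import (
    MetricsEntry,
    MetricsReport,
    PipelineConfig,
    balanced_accuracy_change,
    evaluate_config,
    tune_and_evaluate,
)
from .screening import (
    FIXED_BUNDLES,
    BundleMap,
    bundle_tests,
    ks_between_group_ratio,
    pairwise_within_group_ratio,
)

__all__ = [
    "RunConfig",
    "RunManifest",
    "read_feature_table",
    "write_feature_table",
    "read_participants",
    "write_participants",
    "load_printed_metrics_fixture",
    "run_full_pipeline",
]

_TABLE_SCHEMA = "stroopsense feature-table v1"
_PARTICIPANT_SCHEMA = "stroopsense participants v1"
_GROUPS = ("CG", "EG")

#: sha256 of the bundled printed-metrics fixture (see data/printed_metrics.csv)
_FIXTURE_SHA256 = "c73f3958cce5c12cfcb043f1e44f184a27075ce182735077535e05b67e09762c"


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(table: FeatureTable, path) -> None:
    """Serialize a feature table as TSV with a schema header line."""
    path = Path(path)
    mod_spec = ";".join(f"{m}={len(names)}" for m, names in table.modalities.items())
    tests = ",".join(table.test_labels)
    with path.open("w") as fh:
        fh.write(f"# {_TABLE_SCHEMA}\tmodalities={mod_spec}\ttests={tests}\n")
        table.data.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_feature_table(path) -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`.

    Round-trips values at full precision and validates the schema: known
    group and test labels, no duplicate (participant, test) rows, and every
    feature column declared by the header present.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(f"# {_TABLE_SCHEMA}"):
            raise SchemaError(f"{path}: missing schema header")
        fields = dict(
            part.split("=", 1) for part in header.split("\t")[1:] if "=" in part
        )
        modalities: dict[str, list[str]] = {}
        for spec in fields.get("modalities", "").split(";"):
            mod, n = spec.split("=")
            modalities[mod] = [f"{mod}_f{k + 1}" for k in range(int(n))]
        known_tests = fields.get("tests", "").split(",")
        data = pd.read_csv(fh, sep="\t")

    feature_names = [f for names in modalities.values() for f in names]
    missing = [c for c in FeatureTable.ID_COLUMNS if c not in data.columns]
    if missing:
        raise SchemaError(f"{path}: missing id columns {missing}")
    missing_feats = [f for f in feature_names if f not in data.columns]
    if missing_feats:
        raise SchemaError(f"{path}: missing feature columns {missing_feats[:5]}")
    bad_group = set(data["group"]) - set(_GROUPS)
    if bad_group:
        raise SchemaError(f"{path}: unknown group labels {sorted(bad_group)}")
    bad_test = set(data["test"]) - set(known_tests)
    if bad_test:
        raise SchemaError(f"{path}: unknown test labels {sorted(bad_test)}")
    dup = data.duplicated(subset=["participant_id", "test"])
    if dup.any():
        row = data.loc[dup.idxmax()]
        raise SchemaError(
            f"{path}: duplicate row for ({row['participant_id']}, {row['test']})"
        )
    cols = list(FeatureTable.ID_COLUMNS) + feature_names
    return FeatureTable(data[cols], modalities)


def write_participants(records: list[ParticipantRecord], path) -> None:
    path = Path(path)
    df = pd.DataFrame([asdict(r) for r in records])
    with path.open("w") as fh:
        fh.write(f"# {_PARTICIPANT_SCHEMA}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_participants(path) -> list[ParticipantRecord]:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if _PARTICIPANT_SCHEMA not in header:
            raise SchemaError(f"{path}: missing schema header")
        df = pd.read_csv(fh, sep="\t")
    return [
        ParticipantRecord(
            participant_id=str(r.participant_id),
            group=str(r.group),
            age=float(r.age),
            gender=str(r.gender),
            completed=bool(r.completed),
            data_retrievable=bool(r.data_retrievable),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# printed-metrics fixture


def load_printed_metrics_fixture() -> tuple[MetricsReport, MetricsReport]:
    """The published evaluation tables as (original, reduced) reports.

    The 96 metric values (4 datasets x 4 classifiers x 2 variants x 3
    metrics) are bundled as a checksummed CSV and returned on the percent
    scale exactly as printed.  The balanced-accuracy comparison is
    invariant to that scale.
    """
    ref = resources.files("stroopsense").joinpath("data/printed_metrics.csv")
    content = ref.read_bytes()
    digest = hashlib.sha256(content).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise IntegrityError(
            f"printed-metrics fixture checksum mismatch: {digest}"
        )
    df = pd.read_csv(ref.open("r"))
    reports = {}
    for variant in ("original", "reduced"):
        entries = [
            MetricsEntry(
                dataset=r.dataset,
                classifier=r.classifier,
                variant=variant,
                accuracy=float(r.accuracy),
                sensitivity=float(r.sensitivity),
                specificity=float(r.specificity),
            )
            for r in df[df["variant"] == variant].itertuples()
        ]
        reports[variant] = MetricsReport(entries)
    return reports["original"], reports["reduced"]


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end pipeline run.

    Exactly one of ``spec`` (generate a synthetic cohort) or ``table_path``
    (load an existing feature table; participants then come from
    ``participants_path``) must be supplied.  Numeric defaults mirror the
    emulated study: significance cutoff 0.1, 5% point discard, 100 folds,
    30% test fraction.
    """

    spec: CohortSpec | None = None
    table_path: str | None = None
    participants_path: str | None = None
    alpha: float = 0.1
    tau: float = 0.2
    bundling: str = "fixed"  # "fixed" (C/N/E map) | "data-driven" (tau rule)
    neighborhood: NeighborhoodConfig = field(default_factory=NeighborhoodConfig)
    classifiers: tuple[str, ...] = ("LR", "RF", "KNN", "SVM")
    n_folds: int = 100
    test_fraction: float = 0.3
    tune: bool = False
    signal_sets: tuple[str, ...] = ("EDA", "HRV", "ST", "fusion")
    stages: tuple[str, ...] = ("simulate", "screen", "filter", "evaluate", "compare")
    out_dir: str = "stroopsense_run"
    seed: int = 0

    def validate(self) -> None:
        if (self.spec is None) == (self.table_path is None):
            raise InvalidParameterError(
                "exactly one of spec or table_path must be supplied"
            )
        if self.bundling not in ("fixed", "data-driven"):
            raise InvalidParameterError(f"unknown bundling mode {self.bundling!r}")


@dataclass
class RunManifest:
    """Record of a completed run: config snapshot, artifacts, checksums, timing."""

    version: str
    seed: int
    config: dict
    artifacts: dict[str, dict]  # name -> {path, sha256}
    timings: dict[str, float]
    selected_bundle: str | None = None
    comparison: dict | None = None  # classifier -> mean relative change (%)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))

    def verify(self) -> None:
        """Check that every referenced artifact exists and matches its checksum."""
        for name, art in self.artifacts.items():
            p = Path(art["path"])
            if not p.exists():
                raise IntegrityError(f"artifact {name!r} missing: {p}")
            digest = hashlib.sha256(p.read_bytes()).hexdigest()
            if digest != art["sha256"]:
                raise IntegrityError(f"artifact {name!r} checksum mismatch")


def _register(manifest: RunManifest, name: str, path: Path) -> None:
    manifest.artifacts[name] = {
        "path": str(path),
        "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
    }


def _default_params(classifier: str) -> dict:
    return {
        "LR": {"C": 1.0},
        "KNN": {"n_neighbors": 5},
        "RF": {"n_estimators": 100},
        "SVM": {"C": 1.0, "gamma": "scale"},
    }[classifier]


def run_full_pipeline(config: RunConfig) -> RunManifest:
    """Execute simulate -> screen/bundle -> subset selection -> per-signal
    i-KNN filtering -> evaluation on full and reduced variants -> comparison.

    Intermediates are written to ``config.out_dir`` and checksummed into
    the returned manifest.  Deterministic given the seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        seed=config.seed,
        config={
            k: v
            for k, v in asdict(config).items()
            if k not in ("spec", "neighborhood")
        },
        artifacts={},
        timings={},
    )
    if config.spec is not None:
        manifest.config["spec"] = asdict(config.spec)
    manifest.config["neighborhood"] = asdict(config.neighborhood)

    # --- simulate or load ------------------------------------------------
    t0 = time.perf_counter()
    if config.spec is not None:
        records, table = generate_cohort(config.spec.with_(seed=config.seed))
        write_participants(records, out / "participants.tsv")
        write_feature_table(table, out / "features.tsv")
        _register(manifest, "participants", out / "participants.tsv")
        _register(manifest, "features", out / "features.tsv")
    else:
        table = read_feature_table(config.table_path)
        records = (
            read_participants(config.participants_path)
            if config.participants_path
            else []
        )
    manifest.timings["simulate"] = time.perf_counter() - t0
    if "screen" not in config.stages:
        manifest.write(out / "manifest.json")
        return manifest

    # --- screening and bundling -----------------------------------------
    t0 = time.perf_counter()
    if config.bundling == "data-driven":
        cg = pairwise_within_group_ratio(table, "CG", alpha=config.alpha)
        eg = pairwise_within_group_ratio(table, "EG", alpha=config.alpha)
        for m in (cg, eg):
            p = out / f"wilcoxon_{m.group.lower()}.tsv"
            m.as_frame().to_csv(p, sep="\t")
            _register(manifest, f"wilcoxon_{m.group.lower()}", p)
        bundles = bundle_tests(cg, eg, tau=config.tau)
    else:
        bundles = BundleMap(
            {t: FIXED_BUNDLES.get(t, t) for t in table.test_labels}
        )
    report = ks_between_group_ratio(table, bundles, alpha=config.alpha)
    manifest.selected_bundle = report.selected_bundle
    ks_path = out / "ks_report.yaml"
    ks_path.write_text(
        yaml.safe_dump(
            {
                "alpha": report.alpha,
                "selected_bundle": report.selected_bundle,
                "overall": report.overall,
                "per_modality": report.per_modality,
            }
        )
    )
    _register(manifest, "ks_report", ks_path)
    manifest.timings["screen"] = time.perf_counter() - t0
    if "filter" not in config.stages and "evaluate" not in config.stages:
        manifest.write(out / "manifest.json")
        return manifest

    # --- per-signal filtering and evaluation ----------------------------
    selected = table.select_tests(bundles.members(report.selected_bundle))
    originals, reduceds = [], []
    for signal in config.signal_sets:
        sub = (
            selected
            if signal == "fusion"
            else selected.select_modalities([signal])
        )
        x = sub.matrix()
        y = sub.data["group"].to_numpy()

        t0 = time.perf_counter()
        filt = filter_points(x, y, config.neighborhood)
        sbar = pd.DataFrame(
            {
                "participant_id": sub.data["participant_id"],
                "test": sub.data["test"],
                "s_bar": filt.scores.s_bar,
                "retained": np.isin(np.arange(len(y)), filt.retained),
            }
        )
        p = out / f"sbar_{signal}.tsv"
        sbar.to_csv(p, sep="\t", index=False)
        _register(manifest, f"sbar_{signal}", p)
        manifest.timings[f"filter_{signal}"] = time.perf_counter() - t0
        if "evaluate" not in config.stages:
            continue

        t0 = time.perf_counter()
        for variant, (xv, yv) in {
            "full": (x, y),
            "reduced": (x[filt.retained], y[filt.retained]),
        }.items():
            for clf in config.classifiers:
                base = PipelineConfig(
                    classifier=clf,
                    classifier_params=tuple(sorted(_default_params(clf).items())),
                    n_folds=config.n_folds,
                    test_fraction=config.test_fraction,
                    seed=config.seed,
                    dataset_variant=variant,
                    signal_set=signal,
                )
                if config.tune:
                    _, entry = tune_and_evaluate(xv, yv, base)
                else:
                    entry = evaluate_config(xv, yv, base)
                (originals if variant == "full" else reduceds).append(entry)
        manifest.timings[f"evaluate_{signal}"] = time.perf_counter() - t0

    if "evaluate" in config.stages:
        original = MetricsReport(originals)
        reduced = MetricsReport(reduceds)
        for name, rep in (("metrics_full", original), ("metrics_reduced", reduced)):
            p = out / f"{name}.tsv"
            rep.as_frame().to_csv(p, sep="\t", index=False)
            _register(manifest, name, p)
        if "compare" in config.stages:
            comparison = balanced_accuracy_change(original, reduced)
            p = out / "comparison.tsv"
            comparison.table.to_csv(p, sep="\t", index=False)
            _register(manifest, "comparison", p)
            manifest.comparison = comparison.mean_relative_change_pct

    manifest.write(out / "manifest.json")
    return manifest
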