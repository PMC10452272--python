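"""Experiment grid: datasets x classifiers under LOPO evaluation.

A dataset is one of: the clinical vector alone, one of the 27 texture
descriptors, or clinical + texture concatenated — 55 datasets in all.
Crossed with the 34 registered classifier families this yields the full
34 x 55 = 1870-cell grid; any subset can be run. Each cell derives its
own seed from the master seed so cells are independently reproducible,
and a crashing cell is recorded as failed without stopping the grid.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clinical import encode_clinical
from .cohort import Patient, SLICE_ROLES
from .harness import SliceDataset, lopo_cv
from .registry import REGISTRY
from .texture import enumerate_texture_configs, get_texture_config

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ("kappa", "accuracy", "sensitivity", "specificity",
                  "precision", "f1", "auc")


def extract_cohort_features(
    patients: Sequence[Patient],
    descriptor_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-slice texture features, long format.

    One row per (patient, slice, descriptor); value columns f_000... are
    padded with NaN up to the longest requested descriptor.
    """
    if descriptor_ids is None:
        descriptor_ids = [c.descriptor_id for c in enumerate_texture_configs()]
    configs = [get_texture_config(d) for d in descriptor_ids]
    width = max(c.length for c in configs)
    rows = []
    for patient in patients:
        by_role = {s.role: s for s in patient.slices}
        for role in SLICE_ROLES:
            for cfg in configs:
                vec = cfg.extract(by_role[role])
                padded = np.full(width, np.nan)
                padded[: len(vec)] = vec.values
                rows.append((patient.patient_id, role, cfg.descriptor_id, *padded))
    columns = ["patient_id", "slice_role", "descriptor_id"] + [
        f"f_{i:03d}" for i in range(width)
    ]
    return pd.DataFrame(rows, columns=columns)


def _texture_matrix(
    patients: Sequence[Patient], features: pd.DataFrame, descriptor_id: str
) -> np.ndarray:
    sub = features[features["descriptor_id"] == descriptor_id]
    if sub.empty:
        raise ValueError(f"no precomputed features for descriptor {descriptor_id!r}")
    value_cols = [c for c in features.columns if c.startswith("f_")]
    indexed = sub.set_index(["patient_id", "slice_role"])
    blocks = []
    for patient in patients:
        per_slice = []
        for role in SLICE_ROLES:
            try:
                row = indexed.loc[(patient.patient_id, role), value_cols]
            except KeyError:
                raise ValueError(
                    f"missing features for patient {patient.patient_id} slice {role}"
                ) from None
            vals = row.to_numpy(dtype=float)
            per_slice.append(vals[np.isfinite(vals)])
        blocks.append(np.stack(per_slice))
    return np.stack(blocks)


def build_dataset(
    patients: Sequence[Patient],
    dataset_id: str,
    features: pd.DataFrame | None = None,
) -> SliceDataset:
    """Assemble the per-slice design matrix for one dataset id.

    ``"clinical"`` is one 9-value vector per patient (no per-cut voting
    is involved for clinical-only input); ``"<descriptor>"`` uses the
    texture features of each of the three cuts;
    ``"clinical+<descriptor>"`` concatenates clinical values in front of
    each cut's texture features.
    """
    y = np.array([p.label for p in patients], dtype=int)
    ids = tuple(p.patient_id for p in patients)
    clin = np.stack([encode_clinical(p.clinical).values for p in patients])
    if dataset_id == "clinical":
        X = clin[:, None, :]
    else:
        descriptor = dataset_id.removeprefix("clinical+")
        if features is None:
            features = extract_cohort_features(patients, [descriptor])
        X = _texture_matrix(patients, features, descriptor)
        if dataset_id.startswith("clinical+"):
            X = np.concatenate([np.repeat(clin[:, None, :], 3, axis=1), X], axis=2)
    return SliceDataset(patient_ids=ids, X=X, y=y, dataset_id=dataset_id)


@dataclass(frozen=True)
class ExperimentGrid:
    dataset_ids: tuple[str, ...]
    classifier_ids: tuple[str, ...]
    seed: int = 0

    @property
    def cells(self) -> list[tuple[str, str]]:
        return [(d, c) for c in self.classifier_ids for d in self.dataset_ids]

    def __len__(self) -> int:
        return len(self.dataset_ids) * len(self.classifier_ids)


def default_dataset_ids() -> list[str]:
    """clinical + 27 texture + 27 clinical+texture = 55 dataset ids."""
    texture = [c.descriptor_id for c in enumerate_texture_configs()]
    return ["clinical"] + texture + [f"clinical+{t}" for t in texture]


def build_grid(
    dataset_ids: Sequence[str] | None = None,
    classifier_ids: Sequence[str] | None = None,
    seed: int = 0,
) -> ExperimentGrid:
    """Validated grid; defaults to the full 55 x 34 = 1870 cells."""
    datasets = list(dataset_ids) if dataset_ids is not None else default_dataset_ids()
    classifiers = list(classifier_ids) if classifier_ids is not None else list(REGISTRY)
    if not classifiers:
        raise ValueError("classifier list must not be empty")
    if not datasets:
        raise ValueError("dataset list must not be empty")
    valid = set(default_dataset_ids())
    for d in datasets:
        if d not in valid:
            raise ValueError(f"unknown dataset id {d!r}")
    for c in classifiers:
        if c not in REGISTRY:
            raise ValueError(f"unknown classifier family {c!r}")
    return ExperimentGrid(tuple(datasets), tuple(classifiers), seed)


def cell_seed(master_seed: int, dataset_id: str, classifier_id: str) -> int:
    """Stable per-cell seed below 2**31, independent of grid composition."""
    tag = zlib.crc32(f"{dataset_id}|{classifier_id}".encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0] % (2**31))


def run_cell(
    patients: Sequence[Patient],
    dataset_id: str,
    classifier_id: str,
    seed: int,
    features: pd.DataFrame | None = None,
) -> dict:
    """One LOPO evaluation; returns a flat results row."""
    dataset = build_dataset(patients, dataset_id, features)
    t0 = time.perf_counter()
    _, report = lopo_cv(dataset, classifier_id, seed=cell_seed(seed, dataset_id, classifier_id))
    row = {"dataset": dataset_id, "classifier": classifier_id, "error": ""}
    row.update({k: report.as_dict()[k] for k in METRIC_COLUMNS})
    row["wall_time_s"] = round(time.perf_counter() - t0, 3)
    return row


def run_grid(
    grid: ExperimentGrid,
    patients: Sequence[Patient],
    features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run every cell; failures are recorded in the ``error`` column.

    Texture features for all descriptors in the grid must be supplied
    (or are computed up front), so a missing descriptor fails before any
    cell runs.
    """
    needed = {d.removeprefix("clinical+") for d in grid.dataset_ids if d != "clinical"}
    if needed and features is None:
        features = extract_cohort_features(patients, sorted(needed))
    if needed and features is not None:
        have = set(features["descriptor_id"].unique())
        missing = needed - have
        if missing:
            raise ValueError(f"features missing for descriptors {sorted(missing)}")
    rows = []
    for dataset_id, classifier_id in grid.cells:
        try:
            row = run_cell(patients, dataset_id, classifier_id, grid.seed, features)
        except Exception as exc:  # noqa: BLE001 -- failure isolation by design
            logger.warning("cell (%s, %s) failed: %s", dataset_id, classifier_id, exc)
            row = {"dataset": dataset_id, "classifier": classifier_id,
                   "error": f"{type(exc).__name__}: {exc}"}
            row.update({k: np.nan for k in METRIC_COLUMNS})
            row["wall_time_s"] = np.nan
        rows.append(row)
        logger.info("cell (%s, %s): kappa=%s", dataset_id, classifier_id,
                    row.get("kappa"))
    return pd.DataFrame(rows)


def summarize_by_classifier(table: pd.DataFrame) -> pd.DataFrame:
    """min/median/mean/max kappa per classifier over all its datasets."""
    ok = table[table["error"] == ""]
    agg = ok.groupby("classifier")["kappa"].agg(["min", "median", "mean", "max"])
    return agg.sort_values("median", ascending=False).reset_index()


def report_top_k(table: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Best (dataset, classifier) combinations by kappa.

    Sorted by kappa descending, ties broken by accuracy then dataset id;
    asking for more rows than exist returns the whole table.
    """
    if table.empty:
        raise ValueError("results table is empty")
    ok = table[table["error"] == ""].copy()
    ok = ok.sort_values(
        by=["kappa", "accuracy", "dataset"], ascending=[False, False, True],
        kind="mergesort",
    )
    cols = ["dataset", "classifier", "kappa", "accuracy"]
    return ok.head(k)[cols].reset_index(drop=True)


def format_top_k(top: pd.DataFrame) -> str:
    lines = [f"{'#':>2}  {'kappa%':>7}  {'acc%':>6}  {'classifier':<16} dataset"]
    for i, row in top.iterrows():
        lines.append(
            f"{i + 1:>2}  {row.kappa:>7.1f}  {row.accuracy:>6.1f}  "
            f"{row.classifier:<16} {row.dataset}"
        )
    return "\n".join(lines)
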