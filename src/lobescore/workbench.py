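"""Experiment orchestration: cohorts -> samples -> training -> evaluation.

Two regimes mirror the study design: a *universal* classifier trained on
all lobes jointly (five-fold patient-grouped cross-validation) and
*lobe-expert* classifiers trained per lobe (two-fold).  Patient leakage
between training and evaluation partitions is a hard error everywhere.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from ._tables import LOBE_NAMES, PATHOLOGIES
from .cohort_split import balanced_patient_split, grouped_kfold
from .explain import aggregate_examination, overall_score
from .metrics import EvalReport, evaluate_predictions
from .model import DualViewLobeClassifier, PredictionRecord
from .phantom import CohortManifest, PhantomConfig, generate_cohort
from .preprocess import LobeSample, PreprocessConfig, extract_lobe_samples

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "build_samples",
    "run_experiment",
    "run_holdout_experiment",
    "read_scores_csv",
    "records_to_frame",
]


@dataclass
class RunConfig:
    """One experiment run: pathology, regime and all nested settings."""

    pathology: str = "mucus"
    regime: str = "universal"  # "universal" | "lobe_expert"
    folds: int | None = None  # default: 5 universal, 2 lobe-expert
    seed: int = 0
    phantom: PhantomConfig = dc_field(default_factory=PhantomConfig)
    preprocess: PreprocessConfig = dc_field(default_factory=PreprocessConfig)
    model_params: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pathology not in PATHOLOGIES:
            raise ValueError(f"unknown pathology {self.pathology!r}")
        if self.regime not in ("universal", "lobe_expert"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.folds is None:
            self.folds = 5 if self.regime == "universal" else 2


def build_samples(
    manifest: CohortManifest,
    config: PreprocessConfig | None = None,
    lobe_maps: dict[str, np.ndarray] | None = None,
) -> dict[str, list[LobeSample]]:
    """Preprocess every examination of a cohort into labelled lobe samples.

    ``lobe_maps`` optionally maps exam_id -> coronal lobe map (e.g. from
    atlas transfer); by default the phantom ground-truth lobe maps are used,
    so classifier experiments are not confounded by lobe-approximation error.
    """
    out: dict[str, list[LobeSample]] = {p: [] for p in PATHOLOGIES}
    for exam, truth in manifest.exams:
        lm = (lobe_maps or {}).get(exam.exam_id, truth.lobe_map_coronal)
        labels = {p: truth.scores[p] for p in PATHOLOGIES}
        samples = extract_lobe_samples(exam, lm, labels=labels, config=config)
        for p in PATHOLOGIES:
            out[p].extend(samples[p])
    return out


def _subset(samples, patients) -> list[LobeSample]:
    patients = set(patients)
    return [s for s in samples if s.patient_id in patients]


def _assert_no_leak(train, eval_):
    leak = {s.patient_id for s in train} & {s.patient_id for s in eval_}
    if leak:
        raise RuntimeError(f"patient leakage across partitions: {sorted(leak)[:5]}")


def _evaluate_records(
    samples: list[LobeSample], records: list[PredictionRecord], bootstrap: int = 0,
    seed: int = 0,
) -> EvalReport:
    y_true = np.array([s.label for s in samples])
    y_pred = np.array([r.predicted_score for r in records])
    probs = np.stack([r.probabilities for r in records])
    exam_ids = np.array([s.exam_id for s in samples])

    # overall 0-12 scores where the predictions cover complete exams
    by_exam: dict[str, list[int]] = {}
    truth_by_exam: dict[str, dict[int, int]] = {}
    for s, r in zip(samples, records):
        by_exam.setdefault(s.exam_id, []).append(r.predicted_score)
        truth_by_exam.setdefault(s.exam_id, {})[s.lobe_id] = s.label
    overall_true, overall_pred = [], []
    for eid, preds in by_exam.items():
        if len(preds) == 6:
            overall_pred.append(sum(preds))
            overall_true.append(overall_score(
                [truth_by_exam[eid][l] for l in range(1, 7)]
            ))
    kw = {}
    if len(overall_true) >= 3:
        kw = {"overall_true": overall_true, "overall_pred": overall_pred}
    return evaluate_predictions(
        y_true, y_pred, probs, exam_ids, bootstrap=bootstrap, seed=seed, **kw
    )


def _fit_predict(
    train: list[LobeSample],
    val: list[LobeSample],
    test: list[LobeSample],
    model_params: dict,
    seed: int,
) -> tuple[DualViewLobeClassifier, list[PredictionRecord]]:
    _assert_no_leak(train, test)
    _assert_no_leak(val, test)
    clf = DualViewLobeClassifier(seed=seed, **model_params)
    clf.fit(train, X_val=val)
    return clf, clf.predict_records(test)


def _carve_validation(patients: list[str], seed: int, frac: float = 0.25):
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_val = max(1, int(round(frac * len(patients))))
    val = [patients[i] for i in order[:n_val]]
    train = [patients[i] for i in order[n_val:]]
    return train, val


def run_experiment(config: RunConfig, manifest: CohortManifest | None = None) -> dict:
    """Cross-validated experiment in the configured regime.

    Returns ``{"folds": [EvalReport...], "pooled": EvalReport, "records":
    DataFrame}`` (lobe-expert: reports additionally keyed per lobe).  Every
    examination is predicted exactly once, by a model that never saw its
    patient.
    """
    if manifest is None:
        manifest = generate_cohort(config.phantom)
    samples = build_samples(manifest, config.preprocess)[config.pathology]
    patients = sorted({s.patient_id for s in samples})
    folds = grouped_kfold(patients, config.folds, seed=config.seed)

    all_records: list[PredictionRecord] = []
    all_samples: list[LobeSample] = []
    fold_reports = []
    lobe_reports: dict[str, list] = {}
    for f, held_out in enumerate(folds):
        rest = [p for p in patients if p not in set(held_out)]
        tr_pat, val_pat = _carve_validation(rest, seed=config.seed + f)
        test = _subset(samples, held_out)
        if config.regime == "universal":
            _, records = _fit_predict(
                _subset(samples, tr_pat), _subset(samples, val_pat), test,
                config.model_params, seed=config.seed + f,
            )
        else:
            records = []
            test_ordered = []
            for lobe_id in range(1, 7):
                tr = [s for s in _subset(samples, tr_pat) if s.lobe_id == lobe_id]
                va = [s for s in _subset(samples, val_pat) if s.lobe_id == lobe_id]
                te = [s for s in test if s.lobe_id == lobe_id]
                _, recs = _fit_predict(tr, va, te, config.model_params,
                                       seed=config.seed + f)
                records.extend(recs)
                test_ordered.extend(te)
                lobe_reports.setdefault(LOBE_NAMES[lobe_id - 1], []).append(
                    _evaluate_records(te, recs)
                )
            test = test_ordered
        fold_reports.append(_evaluate_records(test, records))
        all_records.extend(records)
        all_samples.extend(test)

    predicted_exams = [r.exam_id for r in all_records]
    expected = len({s.exam_id for s in samples}) * 6
    if len(predicted_exams) != expected:
        raise RuntimeError("cross-validation did not predict every lobe exactly once")
    pooled = _evaluate_records(all_samples, all_records, seed=config.seed)
    out = {
        "folds": fold_reports,
        "pooled": pooled,
        "records": records_to_frame(all_records),
    }
    if lobe_reports:
        out["per_lobe"] = lobe_reports
    return out


def run_holdout_experiment(
    manifest: CohortManifest,
    pathology: str,
    model_params: dict | None = None,
    preprocess: PreprocessConfig | None = None,
    split_iterations: int = 2000,
    seed: int = 0,
    bootstrap: int = 0,
) -> dict:
    """Single balanced 60/20/20 train/val/test run.

    The patient split is found by the iterative balanced-split search on
    the cohort's lobe score table; the model trains on the train set with
    early stopping on val, and is evaluated once on the held-out test set.
    Returns the trained model, the test samples/records and the report.
    """
    samples = build_samples(manifest, preprocess)[pathology]
    patients = sorted({s.patient_id for s in samples})
    assignment = balanced_patient_split(
        patients, manifest.scores, iterations=split_iterations, seed=seed
    )
    train = _subset(samples, assignment.patients("train"))
    val = _subset(samples, assignment.patients("val"))
    test = _subset(samples, assignment.patients("test"))
    clf, records = _fit_predict(train, val, test, model_params or {}, seed=seed)
    report = _evaluate_records(test, records, bootstrap=bootstrap, seed=seed)
    return {
        "model": clf,
        "assignment": assignment,
        "test_samples": test,
        "records": records,
        "report": report,
    }


def records_to_frame(records: list[PredictionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id, "exam_id": r.exam_id,
            "lobe": LOBE_NAMES[r.lobe_id - 1], "pathology": r.pathology,
            "prob_0": r.probabilities[0], "prob_1": r.probabilities[1],
            "prob_2": r.probabilities[2], "predicted_score": r.predicted_score,
        })
    return pd.DataFrame(rows)


_SCORE_COLUMNS = ("patient_id", "exam_id", "pathology", "lobe", "score")


def read_scores_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a lobe score table.

    Required columns: patient_id, exam_id, pathology, lobe, score.  Scores
    must be 0/1/2, lobes must come from the canonical six, and every
    (exam, pathology) must have a complete lobe set; violations raise with
    the offending column / (exam, lobe) named.
    """
    df = pd.read_csv(path)
    missing = [c for c in _SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"scores CSV missing columns: {missing}")
    bad_scores = df.loc[~df["score"].isin([0, 1, 2])]
    if len(bad_scores):
        raise ValueError(
            f"invalid score values (must be 0/1/2): {sorted(bad_scores['score'].unique())}"
        )
    bad_lobes = sorted(set(df["lobe"]) - set(LOBE_NAMES))
    if bad_lobes:
        raise ValueError(f"unknown lobe names: {bad_lobes}")
    incomplete = []
    for (eid, path_), grp in df.groupby(["exam_id", "pathology"]):
        absent = set(LOBE_NAMES) - set(grp["lobe"])
        for lobe in sorted(absent):
            incomplete.append((eid, lobe))
    if incomplete:
        raise ValueError(f"incomplete lobe sets (exam, lobe): {incomplete[:10]}")
    return df


def save_report(report: EvalReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
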