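"""Cross-day identification protocol, One-vs-Rest metrics, experiment grid.

The protocol trains on all day-1 trials and tests on all day-2 trials of the
same subjects (or the reverse), which removes the within-session priming and
muscle-memory bias single-day splits suffer from.  Identification quality is
summarised by macro F1 plus One-vs-Rest AUC/FAR/FRR: each subject in turn is
the positive class against all others, and per-class values are averaged
unweighted.  FAR and FRR come from the argmax decision, not a score
threshold; for balanced test sets this implies the exact identity

    mean FAR = mean FRR / (K - 1)

because total false positives equal total false negatives and each class's
negative pool is (K-1) times its positive pool.

Each (model family, modality) cell of the experiment grid is trained
``repetitions`` times with seeds derived from the master seed, and per-run
metrics are averaged to damp weight-initialisation luck.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score

from .datasets_io import FeatureTensorSet, ModalityConfig, assemble_features
from .models import ModelSpec, TrainConfig, build_model, predict_scores, train

__all__ = [
    "MetricsReport",
    "cross_day_split",
    "macro_f1",
    "ovr_metrics",
    "evaluate_cell",
    "run_experiment_grid",
    "grid_heat_table",
]


@dataclass
class MetricsReport:
    """Per-repetition and aggregated metrics for one experiment cell."""

    model_family: str
    modality: str
    per_repetition: pd.DataFrame  # columns: repetition, seed, f1, auc, far, frr
    metadata: dict = field(default_factory=dict)

    @property
    def mean(self) -> pd.Series:
        return self.per_repetition[["f1", "auc", "far", "frr"]].mean()


def cross_day_split(
    manifest: pd.DataFrame, train_day: int = 1, test_day: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean row masks (train, test) splitting a manifest by day.

    Every subject must appear on both days; subjects missing either day are
    listed in the error.  The split is disjoint and exhaustive over the two
    days; no subject is excluded.
    """
    days = manifest["day"].to_numpy()
    missing = []
    for subject, sub in manifest.groupby("subject_id"):
        have = set(sub["day"])
        if not {train_day, test_day} <= have:
            missing.append(str(subject))
    if missing:
        raise ValueError(
            f"subjects missing day {train_day} or {test_day}: {', '.join(missing)}"
        )
    return days == train_day, days == test_day


def macro_f1(y_true, y_pred) -> float:
    """Unweighted mean of per-class F1; classes never predicted score 0."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("labels must be equal-length and non-empty")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    return float(
        f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)
    )


def ovr_metrics(y_true, scores) -> tuple[float, float, float]:
    """One-vs-Rest (mean AUC, mean FAR, mean FRR) from probability rows.

    AUC per class uses the class's score column against binary membership
    (trapezoidal ROC).  FAR/FRR per class come from the argmax decision:
    FAR_c = FP_c/(FP_c+TN_c), FRR_c = FN_c/(FN_c+TP_c).  Classes with no
    positive test trials are excluded from the AUC mean with a warning.
    Argmax ties break towards the lowest class index (numpy argmax).
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or len(scores) != len(y_true):
        raise ValueError("scores must be (n_trials, n_classes) matching labels")
    if scores.shape[1] < 2:
        raise ValueError("need at least 2 classes")
    row_sums = scores.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-6):
        raise ValueError("score rows must sum to 1 (probability rows)")

    k = scores.shape[1]
    preds = scores.argmax(axis=1)
    aucs, fars, frrs = [], [], []
    for c in range(k):
        positive = y_true == c
        n_pos = positive.sum()
        n_neg = len(y_true) - n_pos
        if n_pos == 0 or n_neg == 0:
            warnings.warn(
                f"class {c} has no {'positive' if n_pos == 0 else 'negative'} "
                "trials; AUC undefined, class excluded",
                stacklevel=2,
            )
        else:
            aucs.append(roc_auc_score(positive, scores[:, c]))
        if n_pos > 0:
            frrs.append(np.sum(positive & (preds != c)) / n_pos)
        if n_neg > 0:
            fars.append(np.sum(~positive & (preds == c)) / n_neg)
    return float(np.mean(aucs)), float(np.mean(fars)), float(np.mean(frrs))


def evaluate_cell(
    features: FeatureTensorSet,
    family: str,
    cfg: TrainConfig,
    master_seed: int,
    train_day: int = 1,
    test_day: int = 2,
    modality_label: str = "",
) -> MetricsReport:
    """Train/evaluate one (model, modality) cell over the repetition budget.

    Repetition ``r`` uses seed ``master_seed + r`` for both weight
    initialisation and batch shuffling; the cross-day split itself is
    deterministic.
    """
    train_mask = features.groups == train_day
    test_mask = features.groups == test_day
    if not train_mask.any() or not test_mask.any():
        raise ValueError("both days must be present in the feature set")
    tr = features.subset(train_mask)
    te = features.subset(test_mask)

    shapes = tuple((a.shape[1], a.shape[2]) for a in features.arrays)
    rows = []
    for rep in range(cfg.repetitions):
        seed = master_seed + rep
        spec = ModelSpec(
            family=family,
            input_shapes=shapes,
            n_classes=len(features.class_names),
            seed=seed,
        )
        fitted = train(build_model(spec), tr, cfg, seed)
        scores = predict_scores(fitted, te)
        auc, far, frr = ovr_metrics(te.labels, scores)
        rows.append(
            {
                "repetition": rep,
                "seed": seed,
                "f1": macro_f1(te.labels, scores.argmax(axis=1)),
                "auc": auc,
                "far": far,
                "frr": frr,
            }
        )
    return MetricsReport(
        model_family=family,
        modality=modality_label,
        per_repetition=pd.DataFrame(rows),
        metadata={"train_day": train_day, "test_day": test_day,
                  "master_seed": master_seed},
    )


def run_experiment_grid(
    manifest: pd.DataFrame,
    families: list[str],
    modalities: list[ModalityConfig],
    cfg: TrainConfig,
    master_seed: int,
    *,
    base_dir=None,
    recordings=None,
    train_day: int = 1,
    test_day: int = 2,
) -> pd.DataFrame:
    """Evaluate every (family, modality) cell; return a tidy results table.

    Columns: model, modality, cutoff, repetition, f1, auc, far, frr.  A cell
    that fails is recorded with NaN metrics and its error message rather than
    aborting the grid.  Identical master seeds give identical tables.
    """
    cross_day_split(manifest, train_day, test_day)  # validate coverage early
    out = []
    for m_idx, modality in enumerate(modalities):
        features = assemble_features(
            manifest, modality, base_dir=base_dir, train_day=train_day,
            recordings=recordings,
        )
        for f_idx, family in enumerate(families):
            cell_seed = master_seed + 1000 * (m_idx * len(families) + f_idx)
            try:
                report = evaluate_cell(
                    features, family, cfg, cell_seed, train_day, test_day,
                    modality_label=modality.label,
                )
            except Exception as exc:  # noqa: BLE001 - cell failures are data
                out.append(
                    pd.DataFrame(
                        [{"model": family, "modality": modality.label,
                          "cutoff": modality.lowpass_cutoff, "repetition": 0,
                          "f1": np.nan, "auc": np.nan, "far": np.nan,
                          "frr": np.nan, "error": str(exc)}]
                    )
                )
                continue
            tidy = report.per_repetition.copy()
            tidy.insert(0, "model", family)
            tidy.insert(1, "modality", modality.label)
            tidy.insert(2, "cutoff", modality.lowpass_cutoff)
            tidy["error"] = ""
            out.append(tidy.drop(columns=["seed"]))
    return pd.concat(out, ignore_index=True)


def grid_heat_table(results: pd.DataFrame, metric: str = "f1") -> pd.DataFrame:
    """Pivot a tidy grid table into a model x modality mean-metric heat table."""
    return results.pivot_table(index="model", columns="modality", values=metric,
                               aggfunc="mean")
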