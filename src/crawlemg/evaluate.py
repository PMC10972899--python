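"""Evaluation protocols, confusion matrices, embeddings and gait statistics.

Three pattern-recognition protocols are supported:

* participant-specific — stratified 3-fold cross-validation within each
  participant, accuracies averaged across participants;
* multi-participant — stratified 3-fold cross-validation over the pooled
  cohort (folds stratified jointly by mode and participant);
* participant-independent — leave-one-participant-out: train on all other
  participants, test on the held-out one.

Each protocol can run at a single speed or at "mixed" speed (all speeds
pooled).  Accuracy is the percentage of correctly identified samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .classify import ClassifierSpec, flatten_features, train
from .features import EnvelopeCycle
from .gait import duty_factor
from .segment import CycleBoundaries, detect_cycles, phase_durations
from .synth import Trial

__all__ = ["PROTOCOLS", "EvaluationResult", "run_protocol", "confusion",
           "embed_2d", "proportions", "analyze_self_selected", "summarize_gait"]

PROTOCOLS = ("participant_specific", "multi_participant", "participant_independent")


@dataclass
class EvaluationResult:
    """Per-fold accuracies and the pooled confusion matrix of one protocol run."""

    protocol: str
    classifier: str
    speed: str
    fold_accuracies: list[float]
    confusion: np.ndarray
    labels: list[str]
    seed: int
    fold_ids: list[str] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def overall_accuracy(self) -> float:
        """Pooled accuracy: 100 × trace / total of the confusion matrix."""
        return float(np.trace(self.confusion) / self.confusion.sum() * 100.0)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "classifier": self.classifier,
            "speed": self.speed,
            "seed": self.seed,
            "fold_ids": self.fold_ids,
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "overall_accuracy": self.overall_accuracy,
            "labels": self.labels,
            "confusion": self.confusion.tolist(),
        }


def _select_speed(dataset: list[EnvelopeCycle], speed: str) -> list[EnvelopeCycle]:
    if speed == "mixed":
        return list(dataset)
    return [s for s in dataset if s.speed == speed]


def _accuracy(true, pred) -> float:
    return float(np.mean(np.asarray(true) == np.asarray(pred)) * 100.0)


def confusion(true_labels, predicted_labels, labels: list[str] | None = None
              ) -> np.ndarray:
    """Count matrix with entry (i, j) = samples of true class i predicted as j."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    if labels is None:
        labels = sorted(set(true_labels) | set(predicted_labels))
    else:
        unknown = (set(true_labels) | set(predicted_labels)) - set(labels)
        if unknown:
            raise ValueError(f"labels outside the declared set: {sorted(unknown)}")
    return confusion_matrix(true_labels, predicted_labels, labels=labels)


def run_protocol(
    dataset: list[EnvelopeCycle],
    protocol: str,
    spec: ClassifierSpec,
    speed: str = "mixed",
    seed: int = 0,
) -> EvaluationResult:
    """Run one (protocol, classifier, speed) cell and pool its confusion matrix."""
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}")
    data = _select_speed(dataset, speed)
    if not data:
        raise ValueError(f"no samples at speed {speed!r}")
    labels = sorted({s.mode for s in data})
    participants = sorted({s.participant_id for s in data})
    modes = np.array([s.mode for s in data])
    parts = np.array([s.participant_id for s in data])

    fold_accs: list[float] = []
    fold_ids: list[str] = []
    pooled_true: list[str] = []
    pooled_pred: list[str] = []

    def _run_fold(train_idx, test_idx, fold_id):
        model = train(spec, [data[i] for i in train_idx], seed)
        pred = model.predict([data[i] for i in test_idx])
        true = [data[i].mode for i in test_idx]
        fold_accs.append(_accuracy(true, pred))
        fold_ids.append(fold_id)
        pooled_true.extend(true)
        pooled_pred.extend(list(pred))

    if protocol == "participant_specific":
        for p in participants:
            idx = np.flatnonzero(parts == p)
            skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
            for k, (tr, te) in enumerate(skf.split(idx, modes[idx])):
                _run_fold(idx[tr], idx[te], f"{p}/fold{k}")
    elif protocol == "multi_participant":
        strat = np.array([f"{m}|{p}" for m, p in zip(modes, parts)])
        # fall back to mode-only stratification when (mode, participant) cells
        # are smaller than the fold count
        if np.min(np.unique(strat, return_counts=True)[1]) < 3:
            strat = modes
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        for k, (tr, te) in enumerate(skf.split(np.arange(len(data)), strat)):
            _run_fold(tr, te, f"fold{k}")
    else:  # participant_independent
        if len(participants) < 2:
            raise ValueError("participant-independent protocol needs >= 2 participants")
        for p in participants:
            te = np.flatnonzero(parts == p)
            tr = np.flatnonzero(parts != p)
            _run_fold(tr, te, f"heldout-{p}")

    conf = confusion(pooled_true, pooled_pred, labels)
    return EvaluationResult(protocol, spec.kind, speed, fold_accs, conf,
                            labels, seed, fold_ids)


def embed_2d(
    dataset: list[EnvelopeCycle],
    seed: int = 0,
    perplexity: float = 30.0,
    flat_points: int = 100,
) -> np.ndarray:
    """t-SNE embedding of the envelope samples, one 2-D point per sample."""
    if len(dataset) < 10:
        raise ValueError("need at least 10 samples to embed")
    X = flatten_features(dataset, flat_points)
    perplexity = min(perplexity, (len(dataset) - 1) / 3.0)
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                init="pca")
    return tsne.fit_transform(X)


def proportions(counts: dict[str, int]) -> dict[str, float]:
    """Percentages of a count table (sums to 100 over the keys)."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return {k: v / total * 100.0 for k, v in counts.items()}


def analyze_self_selected(
    model, self_cycles: list[EnvelopeCycle]
) -> pd.DataFrame:
    """Classify self-selected cycles; per-speed counts and percentages per mode.

    Returns a frame indexed by (speed, mode) with columns ``count`` and
    ``percent``; percentages sum to 100 within each speed.
    """
    if not self_cycles:
        raise ValueError("no self-selected cycles supplied")
    pred = model.predict(self_cycles)
    speeds = [s.speed for s in self_cycles]
    rows = []
    for speed in sorted(set(speeds)):
        counts: dict[str, int] = {}
        for sp, mode in zip(speeds, pred):
            if sp == speed:
                counts[mode] = counts.get(mode, 0) + 1
        pct = proportions(counts)
        for mode in sorted(counts):
            rows.append({"speed": speed, "mode": mode,
                         "count": counts[mode], "percent": pct[mode]})
    return pd.DataFrame(rows).set_index(["speed", "mode"])


def summarize_gait(
    trials: list[Trial],
    boundaries: list[CycleBoundaries] | None = None,
) -> pd.DataFrame:
    """Per-speed stance/swing duration and duty-factor statistics (mean, sd).

    Durations come from the detected left-palm cycle boundaries; the duty
    factor is computed per cycle and aggregated per speed.
    """
    if boundaries is None:
        boundaries = [detect_cycles(t.pressure, t.sample_rate) for t in trials]
    per_speed: dict[str, dict[str, list[float]]] = {}
    for trial, bounds in zip(trials, boundaries):
        stance, swing = phase_durations(bounds, trial.sample_rate)
        d = per_speed.setdefault(trial.speed, {"stance": [], "swing": [], "duty": []})
        d["stance"].extend(stance)
        d["swing"].extend(swing)
        d["duty"].extend(duty_factor(stance, swing))
    rows = []
    for speed in sorted(per_speed):
        d = per_speed[speed]
        rows.append({
            "speed": speed,
            "n_cycles": len(d["duty"]),
            "stance_mean_s": float(np.mean(d["stance"])),
            "stance_sd_s": float(np.std(d["stance"], ddof=1)) if len(d["stance"]) > 1 else 0.0,
            "swing_mean_s": float(np.mean(d["swing"])),
            "swing_sd_s": float(np.std(d["swing"], ddof=1)) if len(d["swing"]) > 1 else 0.0,
            "duty_mean_pct": float(np.mean(d["duty"])),
            "duty_sd_pct": float(np.std(d["duty"], ddof=1)) if len(d["duty"]) > 1 else 0.0,
        })
    return pd.DataFrame(rows).set_index("speed")
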