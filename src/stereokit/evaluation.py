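"""Metrics and experiment protocols.

Besides the confusion matrix and per-class precision/recall/F1, this module
houses the two replication protocols run on synthetic data: the denoising
ablation (train identical networks on corrupted-raw vs denoised inputs and
compare held-out accuracy) and the head-to-head against the manual-feature
baselines.  Stochastic experiments report one value per seed; "accuracy" is
always micro accuracy over the held-out split.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .classifier import ActionRecognitionModel, ModelConfig
from .denoise import denoise_sequence, remove_head_joints, scale_coordinates
from .sequence_prep import normalize_length, train_test_split
from .synthetic import Clip, NoiseModel, generate_dataset
from .types import N_CLASSES

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics


def confusion(true_labels, pred_labels, n_classes: int = N_CLASSES) -> np.ndarray:
    """Confusion matrix; rows are true classes, columns predicted classes."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(pred_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError(f"label length mismatch: {t.shape} vs {p.shape}")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


def normalized_confusion(cm: np.ndarray) -> np.ndarray:
    """Row-stochastic view (per-class rates); empty rows stay zero."""
    cm = np.asarray(cm, dtype=float)
    sums = cm.sum(axis=1, keepdims=True)
    return np.divide(cm, sums, out=np.zeros_like(cm), where=sums > 0)


def prf(cm: np.ndarray) -> dict:
    """Per-class precision, recall and F1 from one-vs-rest counts.

    P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); a class with no
    predictions or no support gets 0 by convention (with a warning).
    """
    cm = np.asarray(cm)
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    if (tp + fn == 0).any():
        warnings.warn("some classes have no test samples; their metrics are 0")
    with np.errstate(invalid="ignore"):
        P = np.divide(tp, tp + fp, out=np.zeros_like(tp), where=(tp + fp) > 0)
        R = np.divide(tp, tp + fn, out=np.zeros_like(tp), where=(tp + fn) > 0)
        F1 = np.divide(2 * P * R, P + R, out=np.zeros_like(tp), where=(P + R) > 0)
    return {"precision": P, "recall": R, "f1": F1, "support": cm.sum(axis=1)}


def micro_accuracy(cm: np.ndarray) -> float:
    cm = np.asarray(cm)
    return float(np.diag(cm).sum() / cm.sum()) if cm.sum() else 0.0


# ---------------------------------------------------------------------------
# dataset assembly from generated clips


def raw_sequence_array(clip: Clip) -> np.ndarray:
    """Clip's detector output as a dense (n, 13, 2) array, *without* denoising.

    Only unit scaling and head removal are applied (the tensors must have
    the classifier's shape); missing joints stay at 0, invalid frames and
    empty frames are kept as-is.  This is the "original skeleton data" arm
    of the ablation.
    """
    out = []
    for fr in clip.raw_frames:
        if not fr.skeletons:
            out.append(np.zeros((13, 2)))
            continue
        body13 = remove_head_joints(scale_coordinates(fr.skeletons[0], fr.image_size))
        coords = np.where(body13[:, 2:3] > 0, body13[:, :2], 0.0)
        out.append(coords)
    return np.stack(out)


def clips_to_samples(
    clips: list[Clip],
    T: int,
    seed: int = 0,
    denoised: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-length (N, T, 13, 2) samples + labels from generated clips."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for clip in clips:
        if denoised:
            cleaned = denoise_sequence(clip.raw_frames)
            if not cleaned:
                logger.warning("clip %s: all frames invalid, skipped", clip.clip_id)
                continue
            arr = np.stack([s.joints for s in cleaned])
        else:
            arr = raw_sequence_array(clip)
        X.append(normalize_length(arr, T, rng=rng).data)
        y.append(clip.label_index)
    return np.stack(X), np.asarray(y)


def split_clips(
    clips: list[Clip], fraction: float = 0.7, seed: int = 0
) -> tuple[list[int], list[int]]:
    """Sequence-level stratified split; returns (train, test) clip indices."""
    entries = [
        {"index": i, "action_label": c.label, "n_frames": len(c.raw_frames)}
        for i, c in enumerate(clips)
    ]
    train, test = train_test_split(entries, fraction=fraction, seed=seed)
    return [e["index"] for e in train], [e["index"] for e in test]


# ---------------------------------------------------------------------------
# experiment protocols


def run_classification(
    clips: list[Clip],
    cfg: ModelConfig,
    denoised: bool = True,
    split_seed: int = 0,
) -> dict:
    """Train the recurrent model on a 70/30 sequence-level split.

    Returns held-out accuracy, the confusion matrix and per-class metrics.
    """
    X, y = clips_to_samples(clips, cfg.time_steps, seed=cfg.seed, denoised=denoised)
    train_idx, test_idx = split_clips(clips, seed=split_seed)
    model = ActionRecognitionModel(cfg)
    history = model.fit(X[train_idx], y[train_idx])
    pred = model.predict_proba(X[test_idx]).argmax(axis=1)
    cm = confusion(y[test_idx], pred)
    return {
        "accuracy": micro_accuracy(cm),
        "confusion": cm,
        "metrics": prf(cm),
        "history": history,
        "model": model,
        "train_idx": train_idx,
        "test_idx": test_idx,
    }


def ablation_denoising(
    cfg: ModelConfig,
    corruption: NoiseModel,
    n_per_class: int = 150,
    seeds: tuple[int, ...] = (0, 1, 2),
) -> dict:
    """Denoised-input vs corrupted-raw-input accuracy, per seed.

    For each seed a fresh synthetic dataset is generated with the given
    corruption; two identical networks are trained, one on the denoised
    skeletons and one on the raw ones, and their held-out accuracies and
    gap are reported alongside the full configuration.
    """
    records = []
    for seed in seeds:
        clips = generate_dataset(n_per_class=n_per_class, noise=corruption, seed=seed)
        cfg_s = ModelConfig(**{**cfg.__dict__, "seed": seed})
        acc_den = run_classification(clips, cfg_s, denoised=True, split_seed=seed)
        acc_raw = run_classification(clips, cfg_s, denoised=False, split_seed=seed)
        records.append({
            "seed": seed,
            "denoised_accuracy": acc_den["accuracy"],
            "raw_accuracy": acc_raw["accuracy"],
            "gap": acc_den["accuracy"] - acc_raw["accuracy"],
        })
    gaps = [r["gap"] for r in records]
    return {
        "records": records,
        "mean_denoised": float(np.mean([r["denoised_accuracy"] for r in records])),
        "mean_raw": float(np.mean([r["raw_accuracy"] for r in records])),
        "mean_gap": float(np.mean(gaps)),
        "config": {**cfg.__dict__, "n_per_class": n_per_class, "seeds": list(seeds),
                   "corruption": {
                       "joint_dropout_rate": corruption.joint_dropout_rate,
                       "frame_loss_rate": corruption.frame_loss_rate,
                       "jitter_sd": corruption.jitter_sd,
                   }},
    }


def compare_baselines(
    clips: list[Clip],
    cfg: ModelConfig,
    families: tuple[str, ...] = ("decision_tree", "linear_svm", "random_forest", "mlp"),
    split_seed: int = 0,
) -> dict:
    """LSTM vs manual-feature baselines on the same denoised split."""
    from .baselines import extract_features, fit_baseline

    result = run_classification(clips, cfg, denoised=True, split_seed=split_seed)
    X, y = clips_to_samples(clips, cfg.time_steps, seed=cfg.seed, denoised=True)
    train_idx, test_idx = result["train_idx"], result["test_idx"]
    accs: dict[str, float] = {"lstm": result["accuracy"]}
    for method, fams in ((1, ("decision_tree",)),
                         (2, tuple(f for f in families if f != "decision_tree"))):
        feats = extract_features(X, method=method)
        for family in fams:
            clf = fit_baseline(feats[train_idx], y[train_idx], family, seed=split_seed)
            accs[f"method{method}_{family}"] = float(
                (clf.predict(feats[test_idx]) == y[test_idx]).mean()
            )
    return accs
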