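"""Manual-feature baselines against which the recurrent model is compared.

Two feature sets are implemented:

* **Method 1** — periodicity statistics: for each joint and each of three
  velocity measures (per-frame change in x, in y, and in overall position),
  the mean and standard deviation of the velocity plus the maximum, mean
  and standard deviation of the magnitudes of the autocorrelogram's local
  maxima.  Originally defined over six upper-body joints; here extended to
  all 13 body joints and augmented with the normalized joint positions.
* **Method 2** — normalized joint positions X (Neck-relative, scaled by the
  mean Neck-to-mid-hip length H), the body velocity (per-frame Neck
  displacement) and the velocities of all normalized joints.

Classifier families are scikit-learn estimators: decision tree, linear
SVM, random forest (100 trees, depth 40) and a 3x100 multilayer
perceptron.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .types import ActionSample, BODY13_NAMES, L_HIP, NECK, R_HIP

#: The six upper-body joints of the original periodicity-feature method.
UPPER_BODY_6 = tuple(
    BODY13_NAMES.index(n)
    for n in ("RShoulder", "RElbow", "RWrist", "LShoulder", "LElbow", "LWrist")
)

BASELINE_FAMILIES = ("decision_tree", "linear_svm", "random_forest", "mlp")


def _as_array(sample: ActionSample | np.ndarray) -> np.ndarray:
    return sample.data if isinstance(sample, ActionSample) else np.asarray(sample)


def velocity_measures(sample: ActionSample | np.ndarray):
    """Per-joint velocity series (dx, dy, dP), each of shape (T-1, 13).

    dx_t = x_t - x_{t-1}; dP is the per-step Euclidean displacement.
    """
    arr = _as_array(sample)
    if arr.shape[0] < 2:
        raise ValueError("velocity needs at least 2 frames")
    d = np.diff(arr, axis=0)
    dx, dy = d[..., 0], d[..., 1]
    return dx, dy, np.hypot(dx, dy)


def autocorrelogram_maxima_stats(series: np.ndarray) -> tuple[float, float, float]:
    """(max, mean, sd) of the magnitudes of the autocorrelation's local peaks.

    The biased, variance-normalized sample autocorrelation rho(l) is
    evaluated at lags 1..L-2; a peak is a strict local maximum
    rho(l-1) < rho(l) > rho(l+1) (with rho(0) = 1 as the left neighbour of
    lag 1).  No peaks, or a constant series, yield (0, 0, 0).
    """
    x = np.asarray(series, dtype=float)
    L = x.size
    if L < 4:
        raise ValueError("series too short for an autocorrelogram (need >= 4)")
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        warnings.warn("constant series has no autocorrelation structure")
        return (0.0, 0.0, 0.0)
    max_lag = L - 2
    rho = np.empty(max_lag + 1)
    rho[0] = 1.0
    for lag in range(1, max_lag + 1):
        rho[lag] = float(x[:-lag] @ x[lag:]) / denom
    interior = np.arange(1, max_lag)
    peaks = rho[interior][
        (rho[interior] > rho[interior - 1]) & (rho[interior] > rho[interior + 1])
    ]
    if peaks.size == 0:
        return (0.0, 0.0, 0.0)
    mags = np.abs(peaks)
    return (float(mags.max()), float(mags.mean()), float(mags.std()))


def skeleton_height(arr: np.ndarray) -> float:
    """Mean Neck-to-mid-hip length H over the clip's frames."""
    midhip = (arr[:, R_HIP] + arr[:, L_HIP]) / 2.0
    return float(np.linalg.norm(arr[:, NECK] - midhip, axis=1).mean())


def normalized_positions(sample: ActionSample | np.ndarray) -> np.ndarray:
    """Neck-relative joint positions scaled by the body height H, (T, 13, 2)."""
    arr = _as_array(sample)
    H = skeleton_height(arr)
    if H == 0.0:
        raise ValueError("degenerate skeleton: Neck-to-hip length is zero")
    return (arr - arr[:, NECK:NECK + 1]) / H


def method1_features(
    sample: ActionSample | np.ndarray,
    joint_subset: tuple[int, ...] | None = None,
    include_positions: bool = True,
) -> np.ndarray:
    """Periodicity feature vector.

    Per joint in ``joint_subset`` (default all 13) and per velocity measure:
    mean, sd, and the three autocorrelogram-peak statistics — 15 values per
    joint.  With ``include_positions`` the normalized per-frame joint
    positions (26 T values) are appended; the upper-body subset without
    positions reproduces the original six-joint feature scope.
    """
    joints = tuple(range(13)) if joint_subset is None else tuple(joint_subset)
    measures = velocity_measures(sample)
    feats: list[float] = []
    for j in joints:
        for m in measures:
            feats.append(float(m[:, j].mean()))
            feats.append(float(m[:, j].std()))
        for m in measures:
            feats.extend(autocorrelogram_maxima_stats(m[:, j]))
    if include_positions:
        feats.extend(normalized_positions(sample).ravel())
    return np.asarray(feats)


def method2_features(sample: ActionSample | np.ndarray) -> np.ndarray:
    """Normalized positions + body velocity + normalized joint velocities.

    X is translation- and scale-invariant; the body velocity (per-frame Neck
    displacement magnitude in scaled units) is the only block that sees
    global motion.  Length: 26 T + (T-1) + 26 (T-1).
    """
    arr = _as_array(sample)
    if arr.shape[0] < 2:
        raise ValueError("method 2 needs at least 2 frames")
    X = normalized_positions(arr)
    v_body = np.linalg.norm(np.diff(arr[:, NECK], axis=0), axis=1)
    v_joints = np.diff(X, axis=0)
    return np.concatenate([X.ravel(), v_body, v_joints.ravel()])


def method1_feature_length(n_joints: int = 13, T: int = 32,
                           include_positions: bool = True) -> int:
    return n_joints * (6 + 9) + (26 * T if include_positions else 0)


def method2_feature_length(T: int) -> int:
    return 26 * T + (T - 1) + 26 * (T - 1)


def extract_features(samples, method: int = 2, **kwargs) -> np.ndarray:
    fn = {1: method1_features, 2: method2_features}[method]
    return np.stack([fn(s, **kwargs) for s in samples])


def fit_baseline(features: np.ndarray, labels, family: str, seed: int = 0):
    """Fit one of the comparison classifier families on extracted features."""
    if family == "decision_tree":
        clf = DecisionTreeClassifier(random_state=seed)
    elif family == "linear_svm":
        clf = LinearSVC(random_state=seed)
    elif family == "random_forest":
        clf = RandomForestClassifier(n_estimators=100, max_depth=40, random_state=seed)
    elif family == "mlp":
        clf = MLPClassifier(hidden_layer_sizes=(100, 100, 100), random_state=seed,
                            max_iter=500)
    else:
        raise ValueError(f"unknown family {family!r}; choose from {BASELINE_FAMILIES}")
    clf.fit(np.asarray(features), np.asarray(labels))
    return clf
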