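"""Spectrogram images, class balancing, cross-validated behaviour
classification, and odds-ratio evaluation.

Each 0.4 s window becomes one spectrogram per band (Hamming window, length
128 or 256 samples, 98% overlap), log-scaled, min–max normalised and resized
to 224×224.  Classes are balanced by duplicating rarer behaviours, a
stratified 10-fold cross-validation (repeated five times) scores the
classifier, and accuracy is compared against the chance baseline 1/k via the
odds ratio [p/(1−p)] / [p₀/(1−p₀)].

The default classifier pools each image to a coarse grid and fits a
multinomial logistic regression; ``model_spec`` accepts any scikit-learn
estimator factory, so a heavier feature extractor can be plugged in.  The
evaluation arithmetic, not the network weights, is what this module pins
down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.signal import get_window
from skimage.measure import block_reduce
from skimage.transform import resize
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .core_io import BAND_RANGES, BEHAVIOUR_LABELS

IMAGE_SIZE = 224
DEFAULT_OVERLAP = 0.98
ALLOWED_WL = (128, 256)

#: Behavioural-group mapping: minimal-signal behaviours, carapace percussion,
#: and high-repetition-rate claw drumming.
GROUP_OF_LABEL: dict[str, str] = {
    "conflict": "non_percussive",
    "locomotion": "non_percussive",
    "MB": "non_percussive",
    "waving": "non_percussive",
    "seqW": "non_percussive",
    "simWBD": "body_dropping",
    "seqBD": "body_dropping",
    "AD": "drumming",
    "UGD": "drumming",
}

GROUPS = ("non_percussive", "body_dropping", "drumming")


def group_of(behaviour_label: str) -> str:
    """Map one of the nine behaviours to its behavioural group."""
    try:
        return GROUP_OF_LABEL[behaviour_label]
    except KeyError:
        raise ValueError(f"unknown behaviour label {behaviour_label!r}") from None


def hop_for(wl: int, overlap: float = DEFAULT_OVERLAP) -> int:
    """Frame hop in samples for a given window length and overlap fraction:
    max(1, round((1−overlap)·wl)) → 3 at wl=128, 5 at wl=256."""
    return max(1, int(round((1.0 - overlap) * wl)))


def spectrogram(
    segment: np.ndarray,
    fs: float,
    wl: int,
    overlap: float = DEFAULT_OVERLAP,
    window: str = "hamming",
):
    """Short-time Fourier magnitude matrix of a segment.

    Returns ``(freqs, mags)`` with ``mags`` of shape (n_bins, n_frames),
    n_frames = floor((N − wl)/hop) + 1.  Frames are not zero-padded: a
    segment shorter than ``wl`` is an error.
    """
    segment = np.asarray(segment, dtype=float)
    n = segment.size
    if n < wl:
        raise ValueError(f"segment of {n} samples shorter than window length {wl}")
    hop = hop_for(wl, overlap)
    taper = get_window(window, wl, fftbins=True)
    frames = np.lib.stride_tricks.sliding_window_view(segment, wl)[::hop]
    mags = np.abs(np.fft.rfft(frames * taper, axis=1)).T
    freqs = np.fft.rfftfreq(wl, d=1.0 / fs)
    return freqs, mags


@dataclass
class SpectrogramImage:
    """A 224×224 normalised spectrogram image ready for classification."""

    matrix: np.ndarray
    band: str
    wl: int
    hop: int
    label: str = ""
    degenerate: bool = False  # all-zero input; normalisation was skipped

    def __post_init__(self) -> None:
        if self.matrix.shape != (IMAGE_SIZE, IMAGE_SIZE):
            raise ValueError(f"image must be {IMAGE_SIZE}x{IMAGE_SIZE}")


def preprocess_image(
    mags: np.ndarray,
    freqs: np.ndarray,
    band: str,
    wl: int,
    label: str = "",
) -> SpectrogramImage:
    """Crop a magnitude matrix to the band's response range, take
    log-magnitude, min–max normalise to [0, 1], and bilinearly resize to
    224×224.

    An all-zero matrix cannot be normalised; it yields an all-zero image
    flagged ``degenerate``.
    """
    mags = np.asarray(mags, dtype=float)
    if mags.size == 0:
        raise ValueError("empty spectrogram matrix")
    lo, hi = BAND_RANGES[band]
    rows = (freqs >= lo) & (freqs <= hi)
    if not rows.any():
        raise ValueError(f"no spectrogram bins inside the {band} band")
    cropped = mags[rows]
    degenerate = not np.any(cropped > 0)
    if degenerate:
        img = np.zeros((IMAGE_SIZE, IMAGE_SIZE))
    else:
        logm = np.log(cropped + 1e-30)
        lo_v, hi_v = logm.min(), logm.max()
        norm = np.zeros_like(logm) if hi_v == lo_v else (logm - lo_v) / (hi_v - lo_v)
        degenerate = hi_v == lo_v
        img = resize(
            norm, (IMAGE_SIZE, IMAGE_SIZE), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    return SpectrogramImage(
        matrix=img, band=band, wl=wl, hop=hop_for(wl), label=label,
        degenerate=degenerate,
    )


def window_to_images(
    window, wl: int, bands: Sequence[str] = ("low", "high"), label: str = "",
    overlap: float = DEFAULT_OVERLAP,
) -> dict[str, SpectrogramImage]:
    """Spectrogram images of a SignalWindow's close channels, one per band."""
    out = {}
    for band in bands:
        seg = window.segments[f"close_{band}"]
        freqs, mags = spectrogram(seg, window.fs, wl, overlap=overlap)
        out[band] = preprocess_image(mags, freqs, band, wl, label=label)
    return out


# ---------------------------------------------------------------------------
# Balancing, cross-validation, odds ratios


def balance_by_duplication(items: Sequence, labels: Sequence[str]):
    """Duplicate rarer classes (cycling through their items) up to the
    majority-class count; all original items are retained.

    Returns ``(balanced_items, balanced_labels)``.
    """
    labels = list(labels)
    if len(items) != len(labels):
        raise ValueError("items and labels must align")
    by_class: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    if any(len(v) == 0 for v in by_class.values()) or not by_class:
        raise ValueError("every class must be non-empty")
    target = max(len(v) for v in by_class.values())
    out_items, out_labels = list(items), list(labels)
    for lab, idxs in by_class.items():
        k = len(idxs)
        for j in range(target - k):
            out_items.append(items[idxs[j % k]])
            out_labels.append(lab)
    return out_items, out_labels


def chance_accuracy(n_classes: int) -> float:
    """Chance classification accuracy 1/k (as a proportion)."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    return 1.0 / n_classes


def odds_ratio(accuracy: float, n_classes: int) -> float:
    """Odds of correct classification at ``accuracy`` relative to the odds
    at the chance baseline 1/n_classes."""
    if not 0.0 < accuracy < 1.0:
        raise ValueError(f"accuracy must lie strictly in (0, 1), got {accuracy}")
    p0 = chance_accuracy(n_classes)
    return (accuracy / (1.0 - accuracy)) / (p0 / (1.0 - p0))


def pooled_features(image: SpectrogramImage, pool: int = 28) -> np.ndarray:
    """Fixed feature vector of a spectrogram image: coarse mean- and
    max-pooled grids plus per-frame (time-axis) max and mean profiles.

    The max pools and column profiles keep short broadband impulses — a
    handful of bright vertical stripes — visible after pooling, which mean
    pooling alone smears out.
    """
    m = image.matrix
    return np.concatenate(
        [
            block_reduce(m, (pool, pool), np.mean).ravel(),
            block_reduce(m, (pool, pool), np.max).ravel(),
            m.max(axis=0),
            m.mean(axis=0),
        ]
    )


def _default_model() -> object:
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(max_iter=2000, C=1.0),
    )


@dataclass
class CVResult:
    """Cross-validated classification outcome."""

    fold_accuracies: np.ndarray  # shape (repeats, k)
    mean_accuracy: float
    odds_ratio: float
    confusion: np.ndarray  # k_classes × k_classes counts, summed over folds/repeats
    n_classes: int
    classes: tuple = ()


def crossval_classify(
    samples: Sequence[dict],
    labels: Sequence[str],
    k: int = 10,
    repeats: int = 5,
    model_spec: str | Callable[[], object] = "pooled-logreg",
    seed: int = 0,
    balance: str = "train_only",
) -> CVResult:
    """Stratified k-fold cross-validation over spectrogram images.

    ``samples`` is a sequence of per-sample dicts mapping band →
    :class:`SpectrogramImage`; with both bands present the per-band feature
    vectors are concatenated ("combined" classification).  Duplication
    balancing is applied inside each training fold by default, so no
    duplicate of a test item can leak into training; ``balance='before_split'``
    reproduces balancing of the whole dataset prior to splitting, and
    ``balance='none'`` disables it.
    """
    if model_spec == "pooled-logreg":
        make_model = _default_model
    elif callable(model_spec):
        make_model = model_spec
    else:
        raise ValueError(f"unknown model_spec {model_spec!r}")
    if balance not in ("train_only", "before_split", "none"):
        raise ValueError(f"unknown balance mode {balance!r}")

    labels_arr = np.asarray(labels)
    classes, y_all = np.unique(labels_arr, return_inverse=True)
    counts = np.bincount(y_all)
    if counts.min() < k:
        raise ValueError(
            f"k={k} exceeds the smallest class count {counts.min()}"
        )
    bands = sorted(samples[0].keys())
    X_all = np.array(
        [np.concatenate([pooled_features(s[b]) for b in bands]) for s in samples]
    )

    if balance == "before_split":
        idx = np.arange(len(y_all))
        idx_bal, lab_bal = balance_by_duplication(list(idx), list(labels_arr))
        X_all = X_all[np.asarray(idx_bal)]
        y_all = np.searchsorted(classes, np.asarray(lab_bal))

    n_classes = len(classes)
    fold_acc = np.zeros((repeats, k))
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
        for f, (tr, te) in enumerate(skf.split(X_all, y_all)):
            X_tr, y_tr = X_all[tr], y_all[tr]
            if balance == "train_only":
                idx_bal, lab_bal = balance_by_duplication(
                    list(range(len(y_tr))), list(y_tr)
                )
                X_tr = X_tr[np.asarray(idx_bal)]
                y_tr = np.asarray(lab_bal)
            model = make_model()
            model.fit(X_tr, y_tr)
            pred = model.predict(X_all[te])
            fold_acc[r, f] = float(np.mean(pred == y_all[te]))
            for t, p in zip(y_all[te], pred):
                confusion[t, p] += 1
    mean_acc = float(fold_acc.mean())
    return CVResult(
        fold_accuracies=fold_acc,
        mean_accuracy=mean_acc,
        odds_ratio=odds_ratio(mean_acc, n_classes) if 0 < mean_acc < 1 else float("inf"),
        confusion=confusion,
        n_classes=n_classes,
        classes=tuple(classes),
    )
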