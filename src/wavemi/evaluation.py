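"""Repeated k-fold cross-validation of the full decoding pipeline.

The default protocol is 10 repetitions of stratified 10-fold CV: each
repetition reshuffles the trials with its own derived seed and partitions
them into 10 disjoint test folds, yielding 100 train/test splits.  For
every split a fresh CNN is initialized with a split-specific seed and
trained on the training-fold images only.  Image construction is
trial-local (the min-max normalization uses no cross-trial statistics),
so images can be precomputed once without information leaking between
folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold, StratifiedShuffleSplit

from wavemi.cnn import CNNConfig, encode_labels, predict, train
from wavemi.cwt import MotherWavelet
from wavemi.images import build_trial_image
from wavemi.synthetic import EpochSet


@dataclass
class CVResult:
    """Per-split accuracies (percent) and their summary."""

    accuracies: np.ndarray
    n_splits: int
    seed: int
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if len(self.accuracies) != self.n_splits:
            raise ValueError("accuracy count does not match n_splits")
        if np.any((self.accuracies < 0) | (self.accuracies > 100)):
            raise ValueError("accuracies must be percentages in [0, 100]")

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def std(self) -> float:
        """Population standard deviation over the split accuracies."""
        return float(self.accuracies.std())


def repeated_kfold(n: int, k: int = 10, reps: int = 10, seed: int = 0,
                   labels: np.ndarray | None = None
                   ) -> list[tuple[np.ndarray, np.ndarray]]:
    """k disjoint folds per repetition, freshly shuffled each time.

    Returns ``k * reps`` (train_idx, test_idx) pairs.  With ``labels``
    given the folds are stratified, which guarantees both classes in
    every training fold.
    """
    if n < k or k < 2:
        raise ValueError(f"need n >= k >= 2, got n={n}, k={k}")
    rep_seeds = np.random.SeedSequence(seed).generate_state(reps)
    splits = []
    for rep_seed in rep_seeds:
        state = int(rep_seed % (2**32 - 1))
        if labels is None:
            folds = KFold(k, shuffle=True, random_state=state).split(np.arange(n))
        else:
            folds = StratifiedKFold(k, shuffle=True, random_state=state).split(
                np.arange(n), labels)
        splits.extend(folds)
    return splits


def shuffle_splits(n: int, n_splits: int = 100, test_fraction: float = 0.1,
                   seed: int = 0, labels: np.ndarray | None = None
                   ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Alternative protocol: independent random stratified 90/10 splits."""
    sss = StratifiedShuffleSplit(
        n_splits=n_splits, test_size=test_fraction, random_state=seed % (2**32 - 1))
    y = labels if labels is not None else np.zeros(n, dtype=int)
    return list(sss.split(np.arange(n), y))


def build_images(dataset: EpochSet, wavelet: MotherWavelet,
                 variant: str = "dual", **kwargs) -> np.ndarray:
    """Stack per-trial images into an (n, Nv, Nt) array."""
    return np.stack(
        [build_trial_image(ep, wavelet, variant, **kwargs).values
         for ep in dataset]
    )


def evaluate_cv(
    dataset: EpochSet | None = None,
    wavelet: MotherWavelet = MotherWavelet("morlet"),
    variant: str = "dual",
    cnn_config: CNNConfig = CNNConfig(),
    k: int = 10,
    reps: int = 10,
    seed: int = 0,
    mode: str = "kfold",
    images: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> CVResult:
    """Cross-validated decoding accuracy of the full pipeline.

    Per split: train a freshly initialized CNN on the training-fold
    images, predict the held-out fold, record percent accuracy.
    Precomputed ``images``/``labels`` may be passed to reuse the (purely
    trial-local) image construction across configurations.
    """
    if images is None:
        if dataset is None:
            raise ValueError("need either a dataset or precomputed images")
        images = build_images(dataset, wavelet, variant)
    if labels is None:
        labels = dataset.labels
    y = encode_labels(labels)
    n = len(images)

    if mode == "kfold":
        splits = repeated_kfold(n, k, reps, seed, labels=y)
    elif mode == "shuffle":
        splits = shuffle_splits(n, k * reps, 1.0 / k, seed, labels=y)
    else:
        raise ValueError(f"mode must be 'kfold' or 'shuffle', got {mode!r}")

    split_seeds = np.random.SeedSequence(seed + 1).generate_state(len(splits))
    accuracies = []
    for (train_idx, test_idx), split_seed in zip(splits, split_seeds):
        cfg = replace(cnn_config, seed=int(split_seed % (2**31 - 1)))
        model, _ = train(images[train_idx], y[train_idx], cfg)
        pred, _ = predict(images[test_idx], model)
        accuracies.append(100.0 * (encode_labels(pred) == y[test_idx]).mean())

    return CVResult(
        accuracies=np.array(accuracies),
        n_splits=len(splits),
        seed=seed,
        config={
            "wavelet": wavelet.kind, "variant": variant, "k": k, "reps": reps,
            "mode": mode, "epochs": cnn_config.epochs,
            "batch_size": cnn_config.batch_size,
            "learning_rate": cnn_config.learning_rate,
        },
    )


def summarize(results: dict[tuple[str, str], CVResult]) -> pd.DataFrame:
    """Mean +/- std accuracy table over (wavelet, variant) configurations.

    Rows are ordered deterministically by wavelet then variant.
    """
    if not results:
        raise ValueError("need at least one result")
    rows = [
        {"wavelet": wavelet, "variant": variant,
         "mean_accuracy": res.mean, "std_accuracy": res.std,
         "n_splits": res.n_splits}
        for (wavelet, variant), res in sorted(results.items())
    ]
    return pd.DataFrame(rows)
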