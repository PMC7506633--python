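"""Training/evaluation orchestration.

The workflow mirrors the intended use on histology archives: a stratified
split at source-image level (so no patch of a held-out image can reach the
training set), patch extraction with 50% overlap, 8-fold dihedral
augmentation of the training patches, per-channel mean normalization,
mini-batch training with cross-entropy and Adam, and image-level evaluation
by averaging patch softmax vectors.

Manifests are plain DataFrames with columns ``image_id`` and ``class`` plus
either an ``image`` object column (in-memory arrays) or a ``path`` column.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from .architecture import build_architecture
from .backend import Adam, NumpyModel, instantiate_model
from .exceptions import ConfigError, DivergenceError, InputError
from .patches import patch_pipeline


@dataclass
class TrainConfig:
    """Run configuration.

    Defaults reproduce the reference setup: 200 epochs, batch size 3, a
    70/30 train/test split, 512x512 network input with four wavelet levels,
    dropout 0.5 and orthonormal wavelet normalization.  Optimizer and
    learning rate are not pinned by the reference description; Adam at 1e-4
    is the package default.
    """

    epochs: int = 200
    batch_size: int = 3
    train_fraction: float = 0.7
    seed: int = 0
    learning_rate: float = 1e-4
    optimizer_name: str = "adam"
    num_classes: int = 4
    input_size: int = 512
    dropout_rate: float = 0.5
    wavelet_mode: str = "orthonormal"
    width_multiplier: float = 1.0
    overlap: float = 0.5
    augment: bool = True

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ConfigError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")
        if self.optimizer_name != "adam":
            raise ConfigError(f"unsupported optimizer {self.optimizer_name!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def split_dataset(manifest: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0):
    """Per-class stratified source-image split, deterministic in the seed.

    Each class contributes ``round(train_fraction * n)`` images to training;
    the split happens before patching so augmented patches never straddle
    the partition.
    """
    if not 0 < train_fraction < 1:
        raise ConfigError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls, group in manifest.groupby("class", sort=True):
        n = len(group)
        if n < 2:
            raise ConfigError(f"class {cls!r} has {n} item(s); need at least 2 to split")
        n_train = int(round(train_fraction * n))
        n_train = min(max(n_train, 1), n - 1)  # both sides non-empty
        perm = rng.permutation(n)
        idx = group.index.to_numpy()
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    train = manifest.loc[sorted(train_idx)].reset_index(drop=True)
    test = manifest.loc[sorted(test_idx)].reset_index(drop=True)
    return train, test


def _load_image(row) -> np.ndarray:
    if "image" in row.index and row["image"] is not None:
        return np.asarray(row["image"], dtype=float)
    if "path" in row.index and isinstance(row["path"], (str, Path)):
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(row["path"]), dtype=float)
        if arr.max() > 1.0:
            arr = arr / 255.0
        return arr
    raise InputError("manifest row carries neither an 'image' array nor a 'path'")


def build_patch_arrays(manifest: pd.DataFrame, config: TrainConfig, augment: bool):
    """Patch every manifest image into model-ready arrays.

    Returns ``(X, image_ids)`` with X of shape (n_patches, S, S, C), patches
    normalized to zero-mean channels, plus the source image id of each patch.
    """
    xs, ids = [], []
    side = config.input_size
    for _, row in manifest.iterrows():
        img = _load_image(row)
        pset = patch_pipeline(
            img, side=side, overlap=config.overlap, augment=augment,
            normalize=True, label=row["class"], image_id=row["image_id"],
        )
        for p in pset:
            xs.append(p.pixels.astype(np.float32))
            ids.append(row["image_id"])
    if not xs:
        raise ConfigError("manifest produced no patches")
    return np.stack(xs), np.asarray(ids, dtype=object)


def _labels_to_indices(manifest, class_names):
    lookup = {c: i for i, c in enumerate(class_names)}
    return manifest.set_index("image_id")["class"].map(lookup)


def train(
    config: TrainConfig,
    train_manifest: pd.DataFrame,
    test_manifest: pd.DataFrame | None = None,
    class_names: list | None = None,
    verbose: bool = False,
):
    """Train the network on a manifest; returns ``(model, history)``.

    ``history`` has one row per epoch with the running training loss,
    the running optimization accuracy (``train_accuracy_running``, measured
    with dropout and batch statistics active), the end-of-epoch training
    accuracy in inference mode (``train_accuracy``, the quantity an accuracy
    curve plots) and, if a test manifest is given, patch-level test accuracy.
    The parameter state with the best test accuracy is restored at the end.
    """
    if len(train_manifest) == 0:
        raise ConfigError("empty training manifest")
    class_names = class_names or sorted(train_manifest["class"].unique())
    if len(class_names) != config.num_classes:
        raise ConfigError(
            f"config.num_classes={config.num_classes} but manifest has "
            f"{len(class_names)} classes: {class_names}"
        )
    ss = np.random.SeedSequence(config.seed)
    model_seed, shuffle_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    graph = build_architecture(
        num_classes=config.num_classes,
        input_size=(config.input_size, config.input_size, 3),
        dropout_rate=config.dropout_rate,
        width_multiplier=config.width_multiplier,
    )
    model = instantiate_model(graph, seed=model_seed, wavelet_mode=config.wavelet_mode)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)

    x_train, train_ids = build_patch_arrays(train_manifest, config, augment=config.augment)
    y_lookup = _labels_to_indices(train_manifest, class_names)
    y_train = y_lookup.loc[train_ids].to_numpy()

    x_test = y_test = None
    if test_manifest is not None and len(test_manifest):
        x_test, test_ids = build_patch_arrays(test_manifest, config, augment=False)
        y_test = _labels_to_indices(test_manifest, class_names).loc[test_ids].to_numpy()

    rng = np.random.default_rng(shuffle_seed)
    rows = []
    best = (-np.inf, None)
    for epoch in range(config.epochs):
        perm = rng.permutation(len(x_train))
        loss_sum = correct = seen = 0
        for start in range(0, len(perm), config.batch_size):
            sel = perm[start : start + config.batch_size]
            loss, n_ok = model.train_step(x_train[sel], y_train[sel], optimizer)
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            loss_sum += loss * len(sel)
            correct += n_ok
            seen += len(sel)
        train_probs = model.predict_proba(x_train)
        row = {
            "epoch": epoch,
            "loss": loss_sum / seen,
            "train_accuracy_running": correct / seen,
            "train_accuracy": float(np.mean(train_probs.argmax(axis=1) == y_train)),
        }
        if x_test is not None:
            probs = model.predict_proba(x_test)
            test_acc = float(np.mean(probs.argmax(axis=1) == y_test))
            row["test_accuracy"] = test_acc
            if test_acc > best[0]:
                best = (test_acc, model.get_state())
        rows.append(row)
        if verbose:
            print(
                "epoch {epoch}: loss={loss:.4f} train_acc={train_accuracy:.3f}".format(**row)
                + (f" test_acc={row['test_accuracy']:.3f}" if "test_accuracy" in row else "")
            )
    if best[1] is not None:
        model.set_state(best[1])
    history = pd.DataFrame(rows)
    return model, history


def evaluate(
    model: NumpyModel,
    test_manifest: pd.DataFrame,
    config: TrainConfig,
    class_names: list | None = None,
) -> dict:
    """Patch- and image-level evaluation report.

    Image-level scores are the mean of the softmax vectors over all patches
    of an image; the report carries both granularities plus the one-vs-rest
    metrics of :func:`wavecnn.metrics.multiclass_report`.
    """
    if len(test_manifest) == 0:
        raise ConfigError("empty test manifest")
    class_names = class_names or sorted(test_manifest["class"].unique())
    x, ids = build_patch_arrays(test_manifest, config, augment=False)
    probs = model.predict_proba(x)
    labels = _labels_to_indices(test_manifest, class_names)

    patch_labels = np.asarray([class_names[i] for i in labels.loc[ids]], dtype=object)
    patch_report = metrics_mod.multiclass_report(patch_labels, probs, class_names)

    frame = pd.DataFrame(probs, columns=class_names).assign(image_id=ids)
    image_probs = frame.groupby("image_id", sort=True).mean()
    image_scores = image_probs.to_numpy()
    image_scores = image_scores / image_scores.sum(axis=1, keepdims=True)
    image_labels = (
        test_manifest.set_index("image_id")["class"].loc[image_probs.index].to_numpy(object)
    )
    image_report = metrics_mod.multiclass_report(image_labels, image_scores, class_names)

    missing = [c for c in class_names if c not in set(image_labels)]
    return {
        "class_names": class_names,
        "patch_level": patch_report,
        "image_level": image_report,
        "patch_accuracy": patch_report["overall_accuracy"],
        "image_accuracy": image_report["overall_accuracy"],
        "classes_missing_from_test": missing,
    }


def run_experiment(config: TrainConfig, manifest: pd.DataFrame, verbose: bool = False) -> dict:
    """split -> train -> evaluate with a runtime leakage assertion."""
    train_manifest, test_manifest = split_dataset(manifest, config.train_fraction, config.seed)
    overlap_ids = set(train_manifest["image_id"]) & set(test_manifest["image_id"])
    if overlap_ids:
        raise ConfigError(f"train/test leakage: shared image ids {sorted(overlap_ids)[:5]}")
    class_names = sorted(manifest["class"].unique())
    model, history = train(config, train_manifest, test_manifest, class_names, verbose=verbose)
    report = evaluate(model, test_manifest, config, class_names)
    return {
        "model": model,
        "history": history,
        "report": report,
        "train_manifest": train_manifest,
        "test_manifest": test_manifest,
        "config": copy.deepcopy(config),
    }
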