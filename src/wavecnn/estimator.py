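"""scikit-learn estimator front ends.

:class:`WaveletCNNClassifier` wraps the full spectral-spatial network behind
the fit/predict API so it composes with sklearn pipelines and model
selection; :class:`HaarWaveletFeatures` exposes the multilevel subband
energies as a plain feature transformer (useful as a fast baseline or for
inspecting class separability).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.exceptions import NotFittedError

from . import harness
from .architecture import audit_parameters, build_architecture
from .exceptions import DimensionError, InputError
from .haar import HaarFilterBank, dwt_pyramid, subband_energy


def _check_images(X) -> list[np.ndarray]:
    if isinstance(X, np.ndarray) and X.ndim == 4:
        return [X[i] for i in range(len(X))]
    imgs = [np.asarray(x, dtype=float) for x in X]
    if not imgs:
        raise InputError("no input images")
    for img in imgs:
        if img.ndim != 3:
            raise DimensionError(f"expected HxWxC images, got shape {img.shape}")
    return imgs


class HaarWaveletFeatures(TransformerMixin, BaseEstimator):
    """Per-subband energy features from a multilevel Haar decomposition.

    Each image maps to ``levels * 4 * C`` nonnegative energies (sum of
    squared coefficients per subband plane), optionally log1p-compressed.
    """

    def __init__(self, levels: int = 4, mode: str = "orthonormal", log_scale: bool = True):
        self.levels = levels
        self.mode = mode
        self.log_scale = log_scale

    def fit(self, X, y=None):
        imgs = _check_images(X)
        self.n_features_in_ = self.levels * 4 * imgs[0].shape[-1]
        return self

    def transform(self, X) -> np.ndarray:
        bank = HaarFilterBank(self.mode)
        feats = []
        for img in _check_images(X):
            pyramid = dwt_pyramid(img, self.levels, bank)
            feats.append(np.concatenate([subband_energy(s) for s in pyramid]))
        out = np.stack(feats)
        return np.log1p(out) if self.log_scale else out


class WaveletCNNClassifier(ClassifierMixin, BaseEstimator):
    """Spectral-spatial wavelet CNN with the sklearn fit/predict contract.

    ``fit`` expects square RGB images whose side is divisible by 16 (four
    wavelet levels plus four stride-2 convolutions); each image is optionally
    expanded into its eight dihedral variants before training.  ``predict``
    averages softmax outputs over an image's patches.

    Attributes set by ``fit``: ``classes_``, ``model_``, ``graph_``,
    ``history_``, ``n_parameters_`` (trainable, non-trainable).
    """

    def __init__(
        self,
        epochs: int = 200,
        batch_size: int = 3,
        learning_rate: float = 1e-4,
        width_multiplier: float = 1.0,
        dropout_rate: float = 0.5,
        wavelet_mode: str = "orthonormal",
        augment: bool = True,
        overlap: float = 0.5,
        random_state: int = 0,
    ):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.width_multiplier = width_multiplier
        self.dropout_rate = dropout_rate
        self.wavelet_mode = wavelet_mode
        self.augment = augment
        self.overlap = overlap
        self.random_state = random_state

    def _config(self, side: int, n_classes: int) -> harness.TrainConfig:
        return harness.TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            width_multiplier=self.width_multiplier,
            dropout_rate=self.dropout_rate,
            wavelet_mode=self.wavelet_mode,
            augment=self.augment,
            overlap=self.overlap,
            seed=self.random_state,
            num_classes=n_classes,
            input_size=side,
        )

    @staticmethod
    def _manifest(imgs, y=None) -> pd.DataFrame:
        rows = [
            {"image_id": f"img_{i:05d}", "class": None if y is None else y[i], "image": img}
            for i, img in enumerate(imgs)
        ]
        return pd.DataFrame(rows)

    def fit(self, X, y):
        imgs = _check_images(X)
        y = np.asarray(y)
        if len(y) != len(imgs):
            raise InputError(f"X has {len(imgs)} images but y has {len(y)} labels")
        side = imgs[0].shape[0]
        if imgs[0].shape[1] != side:
            raise DimensionError("training images must be square")
        self.classes_ = np.unique(y)
        config = self._config(side, len(self.classes_))
        manifest = self._manifest(imgs, [str(v) for v in y])
        class_names = [str(v) for v in self.classes_]
        self.model_, self.history_ = harness.train(
            config, manifest, class_names=class_names
        )
        self.graph_ = self.model_.graph
        audit = audit_parameters(self.graph_)
        self.n_parameters_ = audit.totals
        self._config_ = config
        return self

    def _require_fitted(self):
        if not hasattr(self, "model_"):
            raise NotFittedError("this WaveletCNNClassifier instance is not fitted yet")

    def predict_proba(self, X) -> np.ndarray:
        self._require_fitted()
        imgs = _check_images(X)
        manifest = self._manifest(imgs, ["?"] * len(imgs))
        x, ids = harness.build_patch_arrays(manifest, self._config_, augment=False)
        probs = self.model_.predict_proba(x)
        frame = pd.DataFrame(probs).assign(image_id=ids)
        mean = frame.groupby("image_id", sort=True).mean()
        mean = mean.loc[manifest["image_id"]]
        out = mean.to_numpy()
        return out / out.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]


def parameter_summary(num_classes: int = 4, input_size: int = 512,
                      width_multiplier: float = 1.0) -> tuple[int, int]:
    """(trainable, non_trainable) totals of the default architecture."""
    graph = build_architecture(
        num_classes=num_classes,
        input_size=(input_size, input_size, 3),
        width_multiplier=width_multiplier,
    )
    return audit_parameters(graph).totals
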