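"""ANN classifier mapping EEG features to the aging mechanism that produced them.

A small multilayer perceptron (4 inputs → two 20-unit ReLU hidden layers →
5-way softmax) classifies an EEG feature vector (aperiodic offset,
exponent, periodic peak center frequency, 1/f AUC) into one of the five
experimental conditions (middle_age, older, inhib_loss, nmda_loss,
spine_loss). Training uses the Adam optimizer with Nesterov momentum
(Nadam), categorical cross-entropy, zero-centered normal weight init,
and early stopping on validation loss (patience 10, max 100 epochs).
An ensemble of models is trained on independent random 60/10/30
train/validation/test splits to estimate accuracy distributions.

Feature handling: inputs are z-scored by training-split statistics; a
missing peak center frequency (spectra without a detected periodic peak)
is imputed with the training-split median. Both transforms are stored on
the model for inference.

Feature attribution uses Shapley values of the predicted-class
probability with respect to a background set — exact enumeration over the
2⁴ feature coalitions (feasible with 4 features, and the oracle for the
approximation) or permutation sampling.

The implementation is plain NumPy, which keeps training bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .aging_parameters import CONDITION_LABELS

__all__ = [
    "DecoderModel",
    "EnsembleResult",
    "train_decoder",
    "classify",
    "attribute_features",
    "exact_shapley",
    "sampling_shapley",
]

FEATURE_NAMES = ("offset", "exponent", "peak_cf", "aperiodic_auc")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class DecoderModel:
    """One trained MLP with its preprocessing statistics."""

    weights: list  # [W1, b1, W2, b2, W3, b3]
    feat_mean: np.ndarray
    feat_std: np.ndarray
    cf_impute: float
    labels: tuple
    seed: int
    epochs_run: int
    test_idx: np.ndarray

    def preprocess(self, X: np.ndarray) -> np.ndarray:
        X = np.array(X, dtype=float, copy=True)
        cf_col = FEATURE_NAMES.index("peak_cf")
        nan = np.isnan(X[:, cf_col])
        X[nan, cf_col] = self.cf_impute
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite values beyond peak CF")
        return (X - self.feat_mean) / self.feat_std

    def forward(self, Z: np.ndarray) -> np.ndarray:
        W1, b1, W2, b2, W3, b3 = self.weights
        h1 = np.maximum(Z @ W1 + b1, 0.0)
        h2 = np.maximum(h1 @ W2 + b2, 0.0)
        return _softmax(h2 @ W3 + b3)


@dataclass
class EnsembleResult:
    """Ensemble of decoders with their test accuracies."""

    models: list
    test_accuracy: np.ndarray  # %, one per model
    per_condition_accuracy: dict  # label -> array of %, one per model
    labels: tuple


def _init_weights(rng: np.random.Generator, sizes=(4, 20, 20, 5), scale=0.1):
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        weights.append(np.zeros(fan_out))
    return weights


def _xent(probs: np.ndarray, onehot: np.ndarray) -> float:
    return float(-np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=1)))


def _train_one(
    Z: np.ndarray,
    Y: np.ndarray,
    Zval: np.ndarray,
    Yval: np.ndarray,
    rng: np.random.Generator,
    lr: float,
    max_epochs: int,
    patience: int,
    batch_size: int,
):
    """Nadam + categorical cross-entropy with early stopping."""
    weights = _init_weights(rng)
    m = [np.zeros_like(w) for w in weights]
    v = [np.zeros_like(w) for w in weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    best_loss = math.inf
    best_weights = [w.copy() for w in weights]
    best_epoch = 0
    n = Z.shape[0]

    for epoch in range(max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            zb, yb = Z[idx], Y[idx]
            W1, b1, W2, b2, W3, b3 = weights
            a1 = zb @ W1 + b1
            h1 = np.maximum(a1, 0.0)
            a2 = h1 @ W2 + b2
            h2 = np.maximum(a2, 0.0)
            probs = _softmax(h2 @ W3 + b3)
            nb = zb.shape[0]
            d3 = (probs - yb) / nb
            gW3 = h2.T @ d3
            gb3 = d3.sum(axis=0)
            d2 = (d3 @ W3.T) * (a2 > 0)
            gW2 = h1.T @ d2
            gb2 = d2.sum(axis=0)
            d1 = (d2 @ W2.T) * (a1 > 0)
            gW1 = zb.T @ d1
            gb1 = d1.sum(axis=0)
            grads = [gW1, gb1, gW2, gb2, gW3, gb3]
            t += 1
            for k, g in enumerate(grads):
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                m_hat = m[k] / (1 - beta1 ** (t + 1))
                v_hat = v[k] / (1 - beta2**t)
                # Nesterov-accelerated Adam update
                m_bar = beta1 * m_hat + (1 - beta1) * g / (1 - beta1**t)
                weights[k] = weights[k] - lr * m_bar / (np.sqrt(v_hat) + eps)
        # full-batch validation loss for early stopping
        W1, b1, W2, b2, W3, b3 = weights
        h1 = np.maximum(Zval @ W1 + b1, 0.0)
        h2 = np.maximum(h1 @ W2 + b2, 0.0)
        val_loss = _xent(_softmax(h2 @ W3 + b3), Yval)
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_weights = [w.copy() for w in weights]
            best_epoch = epoch
        elif epoch - best_epoch >= patience:
            break
    return best_weights, epoch + 1


def train_decoder(
    features: np.ndarray,
    labels,
    n_models: int = 50,
    split: tuple = (0.6, 0.1, 0.3),
    lr: float = 0.001,
    max_epochs: int = 100,
    patience: int = 10,
    batch_size: int = 32,
    seed: int = 0,
    class_labels: tuple = CONDITION_LABELS,
) -> EnsembleResult:
    """Train an ensemble of mechanism decoders on labeled feature vectors.

    ``features`` is (n, 4) — offset, exponent, peak CF (NaN if absent),
    1/f AUC. ``labels`` are condition names. Each of the ``n_models``
    models gets an independent random 60/10/30 train/validation/test
    split; preprocessing statistics come from its training split only.
    Deterministic in ``seed``.
    """
    X = np.asarray(features, dtype=float)
    y_names = list(labels)
    missing = [lb for lb in class_labels if lb not in y_names]
    if missing:
        raise ValueError(f"missing condition label(s): {missing}")
    y = np.array([class_labels.index(lb) for lb in y_names])
    n, n_classes = X.shape[0], len(class_labels)
    for k in range(n_classes):
        if np.sum(y == k) < 5:
            raise ValueError(
                f"need at least 5 samples per condition, {class_labels[k]} has {np.sum(y == k)}"
            )
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    rng = np.random.default_rng(seed)
    cf_col = FEATURE_NAMES.index("peak_cf")

    models = []
    accs = np.empty(n_models)
    per_cond = {lb: np.full(n_models, np.nan) for lb in class_labels}
    for i in range(n_models):
        perm = rng.permutation(n)
        tr = perm[:n_train]
        va = perm[n_train : n_train + n_val]
        te = perm[n_train + n_val :]
        Xtr = X[tr].copy()
        cf_med = float(np.nanmedian(Xtr[:, cf_col]))
        if math.isnan(cf_med):
            cf_med = 0.0
        for part in (Xtr,):
            part[np.isnan(part[:, cf_col]), cf_col] = cf_med
        mean = Xtr.mean(axis=0)
        std = Xtr.std(axis=0)
        std[std == 0] = 1.0
        model = DecoderModel(
            weights=[],
            feat_mean=mean,
            feat_std=std,
            cf_impute=cf_med,
            labels=tuple(class_labels),
            seed=seed,
            epochs_run=0,
            test_idx=te,
        )
        Ztr = model.preprocess(X[tr])
        Zva = model.preprocess(X[va])
        Zte = model.preprocess(X[te])
        onehot = np.eye(n_classes)
        weights, epochs = _train_one(
            Ztr,
            onehot[y[tr]],
            Zva,
            onehot[y[va]],
            rng,
            lr,
            max_epochs,
            patience,
            batch_size,
        )
        model.weights = weights
        model.epochs_run = epochs
        pred = np.argmax(model.forward(Zte), axis=1)
        accs[i] = 100.0 * np.mean(pred == y[te])
        for k, lb in enumerate(class_labels):
            sel = y[te] == k
            if sel.any():
                per_cond[lb][i] = 100.0 * np.mean(pred[sel] == k)
        models.append(model)
    return EnsembleResult(
        models=models,
        test_accuracy=accs,
        per_condition_accuracy=per_cond,
        labels=tuple(class_labels),
    )


def classify(model: DecoderModel, feature: np.ndarray) -> np.ndarray:
    """Softmax class probabilities for one feature vector (or a batch)."""
    feature = np.atleast_2d(np.asarray(feature, dtype=float))
    probs = model.forward(model.preprocess(feature))
    return probs[0] if probs.shape[0] == 1 else probs


def _coalition_value(model, z, background, subset, cls):
    """Expected predicted-class probability with features outside
    ``subset`` replaced by background values."""
    Zm = background.copy()
    Zm[:, list(subset)] = z[list(subset)]
    return float(model.forward(Zm)[:, cls].mean())


def exact_shapley(model: DecoderModel, z: np.ndarray, background: np.ndarray, cls: int) -> np.ndarray:
    """Exact Shapley values over the 2⁴ coalitions of the four features.

    ``z`` and ``background`` are preprocessed (standardized) feature
    vectors; the value function is the mean predicted probability of class
    ``cls`` over the background set with the coalition's features set to
    ``z``.
    """
    d = z.size
    phi = np.zeros(d)
    fact = [math.factorial(k) for k in range(d + 1)]
    values = {}
    for r in range(d + 1):
        for s in itertools.combinations(range(d), r):
            values[s] = _coalition_value(model, z, background, s, cls)
    for j in range(d):
        for s, v in values.items():
            if j in s:
                continue
            s_with = tuple(sorted(s + (j,)))
            w = fact[len(s)] * fact[d - len(s) - 1] / fact[d]
            phi[j] += w * (values[s_with] - v)
    return phi


def sampling_shapley(
    model: DecoderModel,
    z: np.ndarray,
    background: np.ndarray,
    cls: int,
    n_perm: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Permutation-sampling Shapley approximation (same value function)."""
    rng = np.random.default_rng(seed)
    d = z.size
    phi = np.zeros(d)
    for _ in range(n_perm):
        order = rng.permutation(d)
        prev = _coalition_value(model, z, background, (), cls)
        subset: list[int] = []
        for j in order:
            subset.append(int(j))
            cur = _coalition_value(model, z, background, tuple(subset), cls)
            phi[j] += cur - prev
            prev = cur
    return phi / n_perm


def attribute_features(
    ensemble: EnsembleResult,
    features: np.ndarray,
    n_background: int = 50,
    n_eval: int = 20,
    n_models: int | None = 5,
    method: str = "sampling",
    n_perm: int = 100,
    seed: int = 0,
) -> dict:
    """Mean absolute Shapley importance per EEG feature.

    For each of up to ``n_models`` ensemble members, Shapley values of the
    predicted-class probability are computed for ``n_eval`` evaluation
    points from the model's test split against a fixed background of
    ``n_background`` points. Returns feature name → mean |Shapley value|.
    """
    X = np.asarray(features, dtype=float)
    rng = np.random.default_rng(seed)
    models = ensemble.models[: n_models or len(ensemble.models)]
    scores = np.zeros(len(FEATURE_NAMES))
    count = 0
    for model in models:
        Z = model.preprocess(X)
        bg_idx = rng.choice(Z.shape[0], size=min(n_background, Z.shape[0]), replace=False)
        background = Z[bg_idx]
        test_pool = model.test_idx if model.test_idx.size else np.arange(Z.shape[0])
        ev_idx = rng.choice(test_pool, size=min(n_eval, test_pool.size), replace=False)
        for i in ev_idx:
            z = Z[i]
            cls = int(np.argmax(model.forward(z[None, :])[0]))
            if method == "exact":
                phi = exact_shapley(model, z, background, cls)
            else:
                phi = sampling_shapley(
                    model, z, background, cls, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
                )
            scores += np.abs(phi)
            count += 1
    scores /= max(count, 1)
    return dict(zip(FEATURE_NAMES, scores))
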