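"""Normalized mixed-type k-nearest-neighbor classification.

Numeric features are min-max scaled onto [0, 1] from the training matrix
(so features on different scales have the same impact on the distance);
categorical and boolean features contribute 0 when equal and 1 when
different. The distance is Euclidean over the masked feature set:

    d(u, v)^2 = sum_num (u_i - v_i)^2 + sum_cat [u_i != v_i]

k is odd (binary majority voting can then never tie); distance ties at the
k-th neighbor are broken by stable training order so reruns are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import MISSING_NUMERIC, FeatureVector

#: Code assigned to categorical values never seen in training.
_UNSEEN = -1.0


@dataclass
class Scaler:
    """Per-numeric-feature min/max observed on the training matrix."""

    mins: np.ndarray
    maxs: np.ndarray
    numeric_mask: np.ndarray    # bool per column

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Map numeric columns to [0, 1] (clipping out-of-range test values);
        constant columns map to 0; the missing-value sentinel maps to 1."""
        X = X.astype(float).copy()
        for j in np.flatnonzero(self.numeric_mask):
            col = X[:, j]
            missing = col == MISSING_NUMERIC
            span = self.maxs[j] - self.mins[j]
            if span > 0:
                col = np.clip((col - self.mins[j]) / span, 0.0, 1.0)
            else:
                col = np.zeros_like(col)
            col[missing] = 1.0
            X[:, j] = col
        return X


def fit_scaler(X: np.ndarray, numeric_mask: np.ndarray) -> Scaler:
    """Fit per-column min/max on training data, ignoring missing sentinels."""
    if X.size == 0:
        raise ValueError("cannot fit a scaler on an empty matrix")
    mins = np.zeros(X.shape[1])
    maxs = np.zeros(X.shape[1])
    for j in np.flatnonzero(numeric_mask):
        col = X[:, j].astype(float)
        col = col[col != MISSING_NUMERIC]
        if col.size:
            mins[j], maxs[j] = col.min(), col.max()
    return Scaler(mins=mins, maxs=maxs, numeric_mask=numeric_mask)


def distance(v1: FeatureVector, v2: FeatureVector, mask=None) -> float:
    """Euclidean mixed-type distance between two *scaled* feature vectors.

    ``mask`` is an iterable of feature names to use (default: all shared
    names of ``v1``); a mask naming an unknown feature raises KeyError.
    """
    names = list(mask) if mask is not None else list(v1.values)
    total = 0.0
    for name in names:
        if name not in v1.values or name not in v2.values:
            raise KeyError(f"mask references unknown feature {name!r}")
        a, b = v1.values[name], v2.values[name]
        if v1.kinds.get(name) == "numeric":
            total += (float(a) - float(b)) ** 2
        else:
            total += 0.0 if a == b else 1.0
    return float(np.sqrt(total))


def choose_k(n: int, mode: str = "sqrt_rule", *, X=None, y=None,
             grid=tuple(range(5, 32, 2)), folds: int = 3,
             seed: int = 0) -> int:
    """Select an odd k.

    sqrt_rule: the odd integer nearest sqrt(n), ties toward the larger,
    clamped to [1, n]. cv_rmse: inner cross-validation over an odd-k grid
    on the encoded training data (X, y), picking the k with the lowest
    root-mean-square 0/1 error (ties toward the smaller k).
    """
    if n <= 0:
        raise ValueError("empty training set")
    if mode == "sqrt_rule":
        root = float(np.sqrt(n))
        lower = int(np.floor((root - 1) / 2)) * 2 + 1
        lower = max(lower, 1)
        upper = lower + 2
        k = upper if (upper - root) <= (root - lower) else lower
        max_odd = n if n % 2 == 1 else n - 1
        return int(min(max(k, 1), max_odd))
    if mode == "cv_rmse":
        if X is None or y is None:
            raise ValueError("cv_rmse mode requires X and y")
        return _choose_k_cv(np.asarray(X), np.asarray(y), grid, folds, seed)
    raise ValueError(f"unknown k-selection mode {mode!r}")


def _choose_k_cv(X, y, grid, folds, seed) -> int:
    rng = np.random.default_rng(seed)
    n = len(y)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds
    best_k, best_rmse = None, np.inf
    max_odd = n if n % 2 == 1 else n - 1
    for k in sorted(set(min(k, max_odd) for k in grid)):
        errors = 0
        for f in range(folds):
            train, test = fold_of != f, fold_of == f
            if not test.any() or k > train.sum():
                continue
            preds = _bulk_predict(X[train], y[train], X[test], k,
                                  np.ones(X.shape[1], dtype=bool))
            errors += int((preds != y[test]).sum())
        rmse = float(np.sqrt(errors / n))
        if rmse < best_rmse:
            best_k, best_rmse = k, rmse
    return int(best_k)


def _pairwise_sq(Xtr, Xte, numeric_mask):
    num = np.flatnonzero(numeric_mask)
    cat = np.flatnonzero(~numeric_mask)
    d2 = np.zeros((Xte.shape[0], Xtr.shape[0]))
    if num.size:
        diff = Xte[:, None, num] - Xtr[None, :, num]
        d2 += np.einsum("ijk,ijk->ij", diff, diff)
    if cat.size:
        d2 += (Xte[:, None, cat] != Xtr[None, :, cat]).sum(axis=2)
    return d2


def _bulk_predict(Xtr, ytr, Xte, k, numeric_mask):
    d2 = _pairwise_sq(Xtr, Xte, numeric_mask)
    # stable argsort: equidistant neighbors resolve by training order
    idx = np.argsort(d2, axis=1, kind="stable")[:, :k]
    votes = ytr[idx].sum(axis=1)
    return votes * 2 > k


@dataclass
class KnnModel:
    """A fitted k-NN classifier over an encoded feature matrix.

    ``feature_names`` fixes the column order; categorical columns carry
    integer codes from ``vocab`` (unseen test categories encode to a code
    distinct from every training code).
    """

    feature_names: list[str]
    kinds: dict[str, str]
    k: int
    scaler: Scaler
    vocab: dict[str, dict[object, float]]
    X: np.ndarray
    y: np.ndarray
    numeric_mask: np.ndarray = field(repr=False, default=None)

    # -- construction --------------------------------------------------------

    @classmethod
    def fit(cls, vectors: list[FeatureVector], labels, *,
            mask=None, k: int | None = None, k_mode: str = "sqrt_rule",
            seed: int = 0) -> "KnnModel":
        """Fit on feature vectors; ``mask`` is the feature-name subset to use
        (default: every feature of the first vector)."""
        if not vectors:
            raise ValueError("empty training set")
        names = [n for n in vectors[0].values if mask is None or n in mask]
        if mask is not None:
            unknown = set(mask) - set(vectors[0].values)
            if unknown:
                raise KeyError(f"mask references unknown features {unknown}")
        kinds = {n: vectors[0].kinds[n] for n in names}
        numeric_mask = np.array([kinds[n] == "numeric" for n in names])
        vocab: dict[str, dict[object, float]] = {
            n: {} for n in names if kinds[n] != "numeric"}
        X = cls._encode(vectors, names, kinds, vocab, grow=True)
        y = np.asarray([bool(l) for l in labels])
        if len(y) != len(X):
            raise ValueError("labels/vectors length mismatch")
        scaler = fit_scaler(X, numeric_mask)
        Xs = scaler.transform(X)
        n = len(y)
        if k is None:
            k = choose_k(n, k_mode, X=Xs, y=y, seed=seed)
        if k % 2 == 0 or k < 1:
            raise ValueError(f"k must be odd and positive, got {k}")
        if k > n:
            raise ValueError(f"k={k} exceeds training size {n}")
        return cls(feature_names=names, kinds=kinds, k=k, scaler=scaler,
                   vocab=vocab, X=Xs, y=y, numeric_mask=numeric_mask)

    @staticmethod
    def _encode(vectors, names, kinds, vocab, grow: bool) -> np.ndarray:
        X = np.empty((len(vectors), len(names)))
        for i, vec in enumerate(vectors):
            for j, name in enumerate(names):
                value = vec.values[name]
                if kinds[name] == "numeric":
                    X[i, j] = float(value)
                else:
                    codes = vocab[name]
                    if value not in codes:
                        if grow:
                            codes[value] = float(len(codes))
                        else:
                            X[i, j] = _UNSEEN
                            continue
                    X[i, j] = codes[value]
        return X

    # -- prediction ----------------------------------------------------------

    def predict(self, vectors: list[FeatureVector]) -> np.ndarray:
        Xq = self._encode(vectors, self.feature_names, self.kinds,
                          self.vocab, grow=False)
        Xq = self.scaler.transform(Xq)
        return _bulk_predict(self.X, self.y, Xq, self.k, self.numeric_mask)


def classify(model: KnnModel, vector: FeatureVector) -> bool:
    """Majority label among the k nearest training vectors."""
    return bool(model.predict([vector])[0])
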