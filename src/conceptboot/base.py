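"""Shared estimator plumbing for the 17-bin response predictors."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .curricula import N_RESPONSES, Trial


def validate_features(X, y=None):
    """Coerce X to an (n, 3) integer array of (stripes, spots, segments)."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(
            f"X must have shape (n_samples, 3) = (stripes, spots, segments); got {X.shape}"
        )
    if np.any(X < 0):
        raise ValueError("feature counts must be non-negative")
    X = X.astype(int)
    if y is None:
        return X, None
    y = np.asarray(y).astype(int).ravel()
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    return X, y


def trials_from_arrays(X, y) -> list[Trial]:
    return [
        Trial(int(r[0]), int(r[1]), int(r[2]), result=int(v)) for r, v in zip(X, y)
    ]


class ResponsePredictorMixin:
    """Common surface for models emitting distributions over 0-16 segments."""

    n_responses_ = N_RESPONSES

    def predict(self, X):
        """Modal response value per task."""
        return np.argmax(self.predict_proba(X), axis=1)

    @staticmethod
    def _normalize(tally: np.ndarray) -> np.ndarray:
        tally = np.asarray(tally, dtype=float)
        sums = tally.sum(axis=-1, keepdims=True)
        out = np.where(sums > 0, tally / np.where(sums == 0, 1.0, sums), 1.0 / N_RESPONSES)
        return out
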