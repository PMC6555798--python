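"""Lagged design matrices shared by the forward (STRF) and backward
(stimulus reconstruction) linear models."""

from __future__ import annotations

import numpy as np

__all__ = ["lagged_design_causal", "lagged_design_anticausal"]


def lagged_design_causal(values: np.ndarray, n_lags: int) -> np.ndarray:
    """(T x d) series -> (T x n_lags*d); column block l holds the series
    delayed by l samples (rows before l are zero-padded). Row t therefore
    collects values[t], values[t-1], ..., values[t-n_lags+1]."""
    T, d = values.shape
    X = np.zeros((T, n_lags * d))
    for l in range(n_lags):
        X[l:, l * d : (l + 1) * d] = values[: T - l]
    return X


def lagged_design_anticausal(values: np.ndarray, n_lags: int) -> np.ndarray:
    """(T x d) series -> (T x n_lags*d); column block l holds the series
    advanced by l samples (rows within l of the end are zero-padded). Row t
    collects values[t], values[t+1], ..., values[t+n_lags-1]."""
    T, d = values.shape
    X = np.zeros((T, n_lags * d))
    for l in range(n_lags):
        X[: T - l, l * d : (l + 1) * d] = values[l:]
    return X
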