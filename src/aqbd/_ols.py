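"""Minimal ordinary least squares core shared by the model classes.

Kept deliberately small and explicit: the fits in this package are tiny
(tens of runs, at most 21 terms) and the workflow needs quantities —
PRESS via the leave-one-out identity, unscaled parameter covariance —
in exact, documented form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class OLSFit:
    params: np.ndarray
    cov_unscaled: np.ndarray  # (X'X)^-1
    fitted: np.ndarray
    resid: np.ndarray
    hat_diag: np.ndarray
    df_resid: int
    sse: float
    sst: float  # corrected total sum of squares

    @property
    def s2(self) -> float:
        """Residual variance; NaN when there are no residual df."""
        return self.sse / self.df_resid if self.df_resid > 0 else np.nan

    @property
    def rsquared(self) -> float:
        return 1.0 - self.sse / self.sst if self.sst > 0 else np.nan

    @property
    def press(self) -> float:
        """Prediction sum of squares via the leave-one-out identity
        e_(i) = e_i / (1 - h_ii).  Raises if a run is self-predicting."""
        h = self.hat_diag
        if np.any(h >= 1.0 - 1e-12):
            raise ValueError(
                "leverage h_ii >= 1: a run would be exactly self-predicting; "
                "PRESS/Q2 undefined"
            )
        return float(np.sum((self.resid / (1.0 - h)) ** 2))

    @property
    def q2(self) -> float:
        """Goodness of prediction, 1 - PRESS / SS_total(corrected)."""
        return 1.0 - self.press / self.sst if self.sst > 0 else np.nan

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_unscaled) * self.s2)

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        if self.df_resid <= 0:
            return np.full_like(self.params, np.nan)
        return 2.0 * stats.t.sf(np.abs(self.tvalues), self.df_resid)


def ols(X: np.ndarray, y: np.ndarray) -> OLSFit:
    """Full-rank least squares with hat diagonals and covariance."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise np.linalg.LinAlgError(
            f"model matrix is rank deficient (rank {rank} < {p} columns)"
        )
    params, *_ = np.linalg.lstsq(X, y, rcond=None)
    xtx_inv = np.linalg.inv(X.T @ X)
    fitted = X @ params
    resid = y - fitted
    hat = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    return OLSFit(params, xtx_inv, fitted, resid, hat, n - p, sse, sst)
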