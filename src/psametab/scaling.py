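"""Column-wise centering and Pareto scaling.

Pareto scaling divides each mean-centered variable by the square root of its
standard deviation — intermediate between no scaling (which lets the most
intense NMR buckets dominate a latent-variable model) and unit-variance
scaling (which inflates baseline noise).  The sample (n-1) standard
deviation is used, matching common chemometrics software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScalingModel", "pareto_scale"]


@dataclass
class ScalingModel:
    """Fitted column statistics; supports transform / inverse-transform.

    ``scale`` is sqrt(SD) for Pareto, SD for unit-variance, 1 for centering
    only.  Zero-variance columns are flagged and mapped to all-zero columns
    (their inverse transform restores the constant value).
    """

    means: np.ndarray
    sds: np.ndarray
    scale: np.ndarray
    zero_variance: np.ndarray  # boolean mask
    columns: list[str] | None = None
    method: str = "pareto"

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        denom = np.where(self.zero_variance, 1.0, self.scale)
        return (X - self.means) / denom

    def inverse_transform(self, Xs: np.ndarray) -> np.ndarray:
        Xs = np.asarray(Xs, dtype=float)
        denom = np.where(self.zero_variance, 1.0, self.scale)
        return Xs * denom + self.means


def _fit(X: np.ndarray, method: str, columns) -> ScalingModel:
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = sds <= 0.0
    if method == "pareto":
        scale = np.sqrt(np.where(zero, 1.0, sds))
    elif method == "unit":
        scale = np.where(zero, 1.0, sds)
    elif method == "none":
        scale = np.ones_like(sds)
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    return ScalingModel(means=means, sds=sds, scale=scale,
                        zero_variance=zero, columns=columns, method=method)


def pareto_scale(X, columns=None, method: str = "pareto"):
    """Center and Pareto-scale a data matrix.

    Parameters
    ----------
    X : (n_samples, n_variables) array-like
        Raw data matrix, at least two rows.
    columns : optional list of column names recorded in the model.
    method : "pareto" (default), "unit" or "none" (centering only).

    Returns
    -------
    (scaled matrix, ScalingModel)
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("scaling requires a 2-D matrix with at least 2 rows")
    model = _fit(X, method, list(columns) if columns is not None else None)
    return model.transform(X), model
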