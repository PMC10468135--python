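"""Varimax-rotated principal component analysis.

PCA here is always computed on the correlation matrix (columns standardized
to zero mean and unit variance), with the retained axes optionally rotated by
the varimax criterion so that each axis loads strongly on few variables
("simple structure") while the rotation stays orthogonal and the total
retained variance is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["RotatedPCA", "RotatedPCAResults", "fit_rotated_pca", "varimax"]


def _varimax_criterion(loadings: np.ndarray) -> float:
    # raw varimax: sum over axes of the variance of squared loadings
    sq = loadings**2
    p = loadings.shape[0]
    return float(np.sum(sq**2) / p - np.sum((sq.sum(axis=0) / p) ** 2))


def varimax(
    loadings: np.ndarray,
    normalize: bool = True,
    tol: float = 1e-6,
    max_sweeps: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate a loading matrix by the varimax criterion.

    Iterative pairwise (Jacobi-style) rotation: every sweep visits each pair
    of axes and applies the closed-form optimal planar rotation; sweeps stop
    when the criterion gain falls below ``tol``.

    Parameters
    ----------
    loadings : (n_variables, n_axes) array
    normalize : bool
        Kaiser row normalization — rows are scaled to unit communality
        before rotation and scaled back afterwards.

    Returns
    -------
    rotated : (n_variables, n_axes) array
    rotation : (n_axes, n_axes) orthogonal matrix with
        ``loadings @ rotation = rotated``.
    """
    A = np.asarray(loadings, dtype=float)
    p, k = A.shape
    R = np.eye(k)
    if k < 2:
        return A.copy(), R
    h = np.sqrt((A**2).sum(axis=1))
    if normalize:
        if np.any(h == 0):
            raise ValueError("variable with zero communality cannot be Kaiser-normalized")
        L = A / h[:, None]
    else:
        L = A.copy()
    for _ in range(max_sweeps):
        before = _varimax_criterion(L)
        for i, j in combinations(range(k), 2):
            x, y = L[:, i], L[:, j]
            u = x**2 - y**2
            v = 2.0 * x * y
            num = 2.0 * (p * (u @ v) - u.sum() * v.sum())
            den = p * (u @ u) - p * (v @ v) - u.sum() ** 2 + v.sum() ** 2
            phi = 0.25 * np.arctan2(num, den)
            if abs(phi) < 1e-12:
                continue
            c, s = np.cos(phi), np.sin(phi)
            rot = np.array([[c, -s], [s, c]])
            L[:, [i, j]] = L[:, [i, j]] @ rot
            R[:, [i, j]] = R[:, [i, j]] @ rot
        if _varimax_criterion(L) - before < tol:
            break
    if normalize:
        L = L * h[:, None]
    return L, R


@dataclass
class RotatedPCAResults:
    """Fitted standardized PCA with (optional) varimax rotation.

    Attributes
    ----------
    loadings : DataFrame (variable x axis)
        Post-rotation loadings on the correlation scale (eigenvector columns
        scaled by the square root of their eigenvalue, then rotated).
    rotation : DataFrame (axis x axis)
        Orthogonal matrix taking unrotated to rotated loadings.
    scores : DataFrame (observation x axis)
        ``standardized data @ loadings`` (see ``score_convention``).
    variance_fraction : Series
        Per-axis share of total variance after rotation (sum of squared
        loadings over the number of variables).
    """

    center: pd.Series
    scale: pd.Series
    loadings: pd.DataFrame
    rotation: pd.DataFrame
    scores: pd.DataFrame
    variance_fraction: pd.Series
    eigenvalues: np.ndarray
    rotated: bool
    score_convention: str = "standardized_data @ loadings"

    @property
    def n_axes(self) -> int:
        return self.loadings.shape[1]

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        """Project new observations (same variables) onto the fitted axes."""
        frame = pd.DataFrame(data)[self.center.index]
        z = (frame - self.center) / self.scale
        return pd.DataFrame(
            z.to_numpy() @ self.loadings.to_numpy(),
            index=frame.index,
            columns=self.loadings.columns,
        )

    def summary(self) -> str:
        lines = [
            "Varimax-rotated PCA" if self.rotated else "PCA (unrotated)",
            f"  variables: {self.loadings.shape[0]}, axes retained: {self.n_axes}",
            "  variance fraction per axis: "
            + ", ".join(f"{c}={v:.3f}" for c, v in self.variance_fraction.items()),
            f"  total retained: {self.variance_fraction.sum():.3f}",
            "",
            self.loadings.round(3).to_string(),
        ]
        return "\n".join(lines)


class RotatedPCA:
    """Standardized PCA with varimax rotation of the retained axes.

    Parameters
    ----------
    data : DataFrame or array (observations x variables)
    n_axes : int
        Number of principal axes to retain (and rotate).
    rotate : bool
        Apply varimax to the retained axes.
    kaiser_normalize : bool
        Kaiser row normalization inside varimax.
    """

    def __init__(
        self,
        data,
        n_axes: int,
        rotate: bool = True,
        kaiser_normalize: bool = True,
        tol: float = 1e-6,
        max_sweeps: int = 1000,
    ):
        frame = pd.DataFrame(data)
        if frame.isna().any().any():
            raise ValueError("missing values are not allowed; impute or drop first")
        if n_axes < 1:
            raise ValueError("n_axes must be >= 1")
        if n_axes > min(frame.shape):
            raise ValueError(
                f"n_axes={n_axes} exceeds min(n_obs, n_vars)={min(frame.shape)}"
            )
        sd = frame.std(ddof=1)
        constant = sd[sd == 0].index.tolist()
        if constant:
            raise ValueError(f"constant column(s): {constant}")
        self.data = frame
        self.n_axes = n_axes
        self.rotate = rotate
        self.kaiser_normalize = kaiser_normalize
        self.tol = tol
        self.max_sweeps = max_sweeps

    def fit(self) -> RotatedPCAResults:
        frame = self.data
        center = frame.mean()
        scale = frame.std(ddof=1)
        z = ((frame - center) / scale).to_numpy()
        corr = np.corrcoef(z, rowvar=False)
        corr = np.atleast_2d(corr)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        evals = np.clip(evals, 0.0, None)
        k = self.n_axes
        A = evecs[:, :k] * np.sqrt(evals[:k])
        if self.rotate and k > 1:
            L, R = varimax(
                A,
                normalize=self.kaiser_normalize,
                tol=self.tol,
                max_sweeps=self.max_sweeps,
            )
        else:
            L, R = A.copy(), np.eye(k)
        # sign convention: the largest-|loading| variable on each axis is positive
        for j in range(k):
            i = int(np.argmax(np.abs(L[:, j])))
            if L[i, j] < 0:
                L[:, j] *= -1.0
                R[:, j] *= -1.0
        axes = [f"PC{j + 1}" for j in range(k)]
        nvar = corr.shape[0]
        var_frac = pd.Series((L**2).sum(axis=0) / nvar, index=axes, name="variance_fraction")
        loadings = pd.DataFrame(L, index=frame.columns, columns=axes)
        scores = pd.DataFrame(z @ L, index=frame.index, columns=axes)
        return RotatedPCAResults(
            center=center,
            scale=scale,
            loadings=loadings,
            rotation=pd.DataFrame(R, index=axes, columns=axes),
            scores=scores,
            variance_fraction=var_frac,
            eigenvalues=evals,
            rotated=bool(self.rotate and k > 1),
        )


def fit_rotated_pca(table, n_axes: int, rotate: bool = True, **kwargs) -> RotatedPCAResults:
    """Fit a (varimax-rotated) standardized PCA. See :class:`RotatedPCA`."""
    return RotatedPCA(table, n_axes=n_axes, rotate=rotate, **kwargs).fit()
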