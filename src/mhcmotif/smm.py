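"""Stabilized-matrix-method training of position-specific scoring matrices.

A peptide of length L is one-hot encoded into a 20*L binary row (one
block of 20 indicator columns per position, residues in ``ALPHABET``
order).  Stacking the rows for all peptides gives the design matrix H,
and measured affinities are regressed on it on a log10(IC50 nM) scale:

    minimize  ||H w + b 1 - y||^2  +  lambda ||w||^2

with an unpenalized intercept b.  The ridge penalty stabilizes the fit
against experimental noise; lambda is chosen by k-fold cross-validation
over a grid.  The coefficient vector reshapes into the 20 x L scoring
matrix whose per-column spread drives the motif-calling stage.

The solver centers H and y (which makes the intercept drop out of the
penalized problem exactly), eigendecomposes the centered Gram matrix
once, and sweeps the lambda grid through the eigenbasis — so the k-fold
grid search costs one factorization per fold rather than one solve per
(fold, lambda) pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold

from .core import AA_INDEX, ALPHABET, BindingDataset, ScoringMatrix

#: Assay dynamic range used to clamp IC50 before the log transform, in nM.
IC50_FLOOR = 0.1
IC50_CEILING = 50000.0

DEFAULT_LAMBDAS = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)


def transform_affinity(ic50, floor: float = IC50_FLOOR, ceiling: float = IC50_CEILING):
    """Map IC50 in nM to the regression target log10(clamp(ic50)).

    Accepts a scalar or array; raises on non-positive or non-finite input.
    """
    arr = np.asarray(ic50, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("ic50 values must be positive and finite")
    out = np.log10(np.clip(arr, floor, ceiling))
    return float(out) if np.isscalar(ic50) or arr.ndim == 0 else out


def encode_peptides(peptides, length: int | None = None) -> np.ndarray:
    """One-hot encode equal-length peptides into an (n, 20*L) design matrix.

    Column order is position-major: columns [20p, 20p+20) hold the
    indicator block for position p (0-based), residues in ALPHABET order.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("no peptides to encode")
    L = length if length is not None else len(peptides[0])
    H = np.zeros((len(peptides), 20 * L))
    for i, pep in enumerate(peptides):
        if len(pep) != L:
            raise ValueError(f"peptide {pep!r} has length {len(pep)}, expected {L}")
        for p, aa in enumerate(pep):
            try:
                H[i, 20 * p + AA_INDEX[aa]] = 1.0
            except KeyError:
                raise ValueError(f"non-canonical residue {aa!r} in {pep!r}") from None
    return H


@dataclass
class EncodedDesign:
    """One-hot design matrix H plus transformed affinities y."""

    H: np.ndarray
    y: np.ndarray
    peptides: list[str] | None = None

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.H.ndim != 2 or self.H.shape[1] % 20:
            raise ValueError("H must be (n, 20*L)")
        if self.H.shape[0] != self.y.shape[0]:
            raise ValueError("H and y row counts differ")

    @property
    def length(self) -> int:
        return self.H.shape[1] // 20


def encode(dataset: BindingDataset) -> EncodedDesign:
    """Encode a BindingDataset into (H, y) with y = log10(clamped IC50)."""
    peptides = dataset.peptides
    return EncodedDesign(
        H=encode_peptides(peptides, dataset.length),
        y=transform_affinity(dataset.ic50s),
        peptides=peptides,
    )


def _ridge_sweep(H, y, lambdas):
    """Solve the unpenalized-intercept ridge problem for every lambda.

    Centers H and y, eigendecomposes the centered Gram matrix once, and
    recovers (w, b) per lambda.  Returns a list of (w, b) pairs.
    """
    col_mean = H.mean(axis=0)
    y_mean = y.mean()
    Hc = H - col_mean
    yc = y - y_mean
    gram = Hc.T @ Hc
    hty = Hc.T @ yc
    evals, evecs = np.linalg.eigh(gram)
    proj = evecs.T @ hty
    out = []
    for lam in lambdas:
        w = evecs @ (proj / (evals + lam))
        b = y_mean - col_mean @ w
        out.append((w, float(b)))
    return out


class SMMRegressor(RegressorMixin, BaseEstimator):
    """Ridge-regularized scoring-matrix regressor for peptide affinities.

    Parameters
    ----------
    lambdas : sequence of float
        Candidate ridge strengths (all strictly positive); the one with
        the smallest mean cross-validated squared error is kept.
    folds : int
        Number of cross-validation folds (>= 2).
    seed : int
        Seed for the shuffled fold assignment; fixing it makes the
        selected lambda and the fitted matrix reproducible.
    allele : str
        Identifier carried into the fitted :class:`ScoringMatrix`.

    Attributes
    ----------
    coef_ : ndarray of shape (20*L,)
        Flat coefficient vector (position-major blocks).
    intercept_ : float
    lambda_ : float
        Selected ridge strength.
    cv_error_ : float
        Mean squared CV error at the selected lambda.
    cv_errors_ : dict mapping lambda -> mean CV MSE.
    matrix_ : ScoringMatrix
        Coefficients reshaped to 20 x L with metadata.

    Examples
    --------
    >>> reg = SMMRegressor(seed=1).fit(peptides, log10_ic50)   # doctest: +SKIP
    >>> reg.predict(["SIINFEKLV"])                             # doctest: +SKIP
    """

    def __init__(
        self,
        lambdas=DEFAULT_LAMBDAS,
        folds: int = 5,
        seed: int = 1,
        allele: str = "unknown",
    ):
        self.lambdas = lambdas
        self.folds = folds
        self.seed = seed
        self.allele = allele

    def _encode_X(self, X) -> np.ndarray:
        arr = np.asarray(X)
        if arr.dtype.kind in "US" or arr.dtype == object:
            return encode_peptides([str(p) for p in arr.ravel()])
        H = np.asarray(X, dtype=float)
        if H.ndim != 2:
            raise ValueError("X must be peptide strings or a 2-D design matrix")
        return H

    def fit(self, X, y):
        """Fit on peptides (or a one-hot design) and log10(IC50) targets."""
        H = self._encode_X(X)
        y = np.asarray(y, dtype=float).ravel()
        if H.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of samples")
        lambdas = [float(l) for l in np.atleast_1d(self.lambdas)]
        if not lambdas:
            raise ValueError("lambda grid is empty")
        if any(l <= 0 for l in lambdas):
            raise ValueError(
                "all lambdas must be > 0: the unregularized system can be "
                "singular for one-hot designs"
            )
        if not 2 <= self.folds <= H.shape[0]:
            raise ValueError(f"need n >= folds >= 2, got n={H.shape[0]}, folds={self.folds}")
        n_distinct = len({row.tobytes() for row in np.ascontiguousarray(H)})
        if n_distinct < self.folds:
            raise ValueError(
                f"only {n_distinct} distinct peptides for {self.folds}-fold CV"
            )

        kf = KFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
        sse = np.zeros(len(lambdas))
        for train_idx, val_idx in kf.split(H):
            fits = _ridge_sweep(H[train_idx], y[train_idx], lambdas)
            for j, (w, b) in enumerate(fits):
                resid = H[val_idx] @ w + b - y[val_idx]
                sse[j] += resid @ resid
        cv_mse = sse / H.shape[0]
        best = int(np.argmin(cv_mse))

        (w, b), = _ridge_sweep(H, y, [lambdas[best]])
        self.coef_ = w
        self.intercept_ = b
        self.lambda_ = lambdas[best]
        self.cv_error_ = float(cv_mse[best])
        self.cv_errors_ = dict(zip(lambdas, cv_mse.tolist()))
        self.n_features_in_ = H.shape[1]
        L = H.shape[1] // 20
        # blocks are position-major, so reshape to (L, 20) then transpose
        self.matrix_ = ScoringMatrix(
            allele=self.allele,
            values=w.reshape(L, 20).T,
            intercept=b,
            lambda_used=self.lambda_,
            cv_error=self.cv_error_,
        )
        return self

    def predict(self, X) -> np.ndarray:
        H = self._encode_X(X)
        return H @ self.coef_ + self.intercept_


def train(
    data: BindingDataset | EncodedDesign,
    lambdas=DEFAULT_LAMBDAS,
    folds: int = 5,
    seed: int = 1,
    allele: str | None = None,
) -> ScoringMatrix:
    """Train a scoring matrix; thin wrapper over :class:`SMMRegressor`."""
    if isinstance(data, BindingDataset):
        design = encode(data)
        allele = allele or data.allele
    else:
        design = data
        allele = allele or "unknown"
    reg = SMMRegressor(lambdas=lambdas, folds=folds, seed=seed, allele=allele)
    reg.fit(design.H, design.y)
    return reg.matrix_


def predict(matrix: ScoringMatrix, peptide: str) -> float:
    """Predicted log10(IC50) of one peptide under a scoring matrix."""
    if len(peptide) != matrix.length:
        raise ValueError(
            f"peptide length {len(peptide)} != matrix length {matrix.length}"
        )
    total = matrix.intercept
    for p, aa in enumerate(peptide):
        try:
            total += matrix.values[AA_INDEX[aa], p]
        except KeyError:
            raise ValueError(f"non-canonical residue {aa!r}") from None
    return float(total)
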