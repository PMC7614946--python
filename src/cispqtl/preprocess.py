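"""Protein-trait preprocessing: rank-inverse-normal transform, covariate
residualization, and genotype principal components.

The analysis-ready phenotype is the residual of the rank-inverse normal
transformed abundance after regressing out age, sex, measurement plate,
and the leading genotype principal components; those residuals feed every
downstream model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TraitVector:
    """A per-sample trait with its transformation provenance."""

    values: np.ndarray
    transform_state: str = "raw"  # raw | rint | residual
    covariates_removed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def rank_inverse_normal(values: np.ndarray, offset: float = 0.5) -> np.ndarray:
    """Map values to standard-normal quantiles of their (mean-tie) ranks.

    Value i becomes Φ⁻¹((rank_i − c) / (n − 2c + 1)) with c = ``offset``;
    the default c = 0.5 gives the symmetric (rank − 0.5)/n rule, c = 3/8
    gives the Blom variant. Ties receive mean ranks, so exchangeable
    inputs map to equal outputs and the transform is strictly monotone in
    input ranks otherwise.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if np.isnan(x).any():
        raise ValueError("missing values not allowed")
    if np.ptp(x) == 0:
        raise ValueError("constant input: all ranks tied, transform undefined")
    ranks = stats.rankdata(x, method="average")
    n = x.size
    return stats.norm.ppf((ranks - offset) / (n - 2 * offset + 1))


def _expand_design(C: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + numeric columns + first-level-reference indicator coding."""
    cols: list[np.ndarray] = [np.ones(len(C))]
    names = ["intercept"]
    for name in C.columns:
        col = C[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(col))
            for level in levels[1:]:  # first level is the reference
                cols.append((col == level).to_numpy(dtype=float))
                names.append(f"{name}[{level}]")
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
    return np.column_stack(cols), names


def _collinear_columns(D: np.ndarray, names: list[str], tol: float = 1e-8) -> list[str]:
    scale = np.linalg.norm(D, axis=0)
    scale[scale == 0] = 1.0
    _, R, piv = _qr_pivoted(D / scale)
    diag = np.abs(np.diag(R))
    bad = diag < tol * max(diag.max(), 1.0)
    return [names[piv[i]] for i in np.flatnonzero(bad)]


def _qr_pivoted(A: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(A, mode="economic", pivoting=True)
    return Q, R, piv


def residualize(
    y: TraitVector | np.ndarray, C: pd.DataFrame | None
) -> TraitVector:
    """Project a trait onto the orthogonal complement of the covariates.

    ``C`` may be ``None`` or empty, in which case only the intercept is
    removed (mean-centering). Categorical columns (e.g. plate) are
    expanded to first-level-reference indicators. Rank-deficient designs
    are rejected with the offending columns named.
    """
    tv = y if isinstance(y, TraitVector) else TraitVector(np.asarray(y, dtype=float))
    yv = tv.values
    if C is None or C.shape[1] == 0:
        D, names = np.ones((yv.size, 1)), ["intercept"]
    else:
        if len(C) != yv.size:
            raise ValueError("covariate table length does not match trait length")
        C = C.drop(columns=[c for c in ("sample_id",) if c in C.columns])
        D, names = _expand_design(C)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        bad = _collinear_columns(D, names)
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(D, yv, rcond=None)
    resid = yv - D @ coef
    removed = [n for n in names if n != "intercept"]
    return TraitVector(resid, transform_state="residual",
                       covariates_removed=tv.covariates_removed + removed)


def genotype_pcs(G, k: int) -> np.ndarray:
    """Top-k principal-component scores of the column-standardized dosages.

    Monomorphic variants are dropped with a warning before
    standardization. Scores are the left singular directions scaled by
    their singular values; each component's sign is fixed so its
    largest-magnitude variant loading is positive.
    """
    X = G.dosages if hasattr(G, "dosages") else np.asarray(G, dtype=float)
    n, m = X.shape
    sd = X.std(axis=0)
    if (sd == 0).any():
        warnings.warn(
            f"dropping {int((sd == 0).sum())} monomorphic variants before PCA",
            stacklevel=2,
        )
        X = X[:, sd > 0]
        sd = sd[sd > 0]
    if k > min(n, X.shape[1]):
        raise ValueError(f"k={k} exceeds min(n, m)={min(n, X.shape[1])}")
    if k == 0:
        return np.empty((n, 0))
    Xs = (X - X.mean(axis=0)) / sd
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            scores[:, j] *= -1
    return scores


def prepare_trait(
    raw: np.ndarray, covariates: pd.DataFrame | None, rint_offset: float = 0.5
) -> TraitVector:
    """RINT then residualize: the standard phenotype preparation."""
    rinted = rank_inverse_normal(raw, offset=rint_offset)
    return residualize(TraitVector(rinted, transform_state="rint"), covariates)
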