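"""Internal linear-model utilities.

Plain least squares on explicitly assembled design matrices.  Designs come in
two flavours: a list of covariate columns (main effects, the default
everywhere) or a patsy right-hand-side formula for richer structure
(interactions, saturated models).  Treatment/ICE indicator columns are always
appended as main-effect columns after the covariate block, so predictions
"under no ICE" are obtained by zeroing those columns.

Rank deficiency is a hard error: the estimators in this package are exact
algebraic compositions of OLS fits, and a pseudo-inverse fallback would
silently change what is being estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from patsy import build_design_matrices, dmatrix

from .errors import SingularDesignError

_RANK_RTOL = 1e-9


@dataclass
class Design:
    """Recipe for building a design matrix from a trial data frame.

    Either ``l_cols`` (intercept + main effects) or ``formula`` (patsy RHS,
    which supplies its own intercept) describes the covariate block;
    ``extra_cols`` are indicator columns (A0, A1, A2) appended afterwards.
    """

    l_cols: tuple[str, ...] = ()
    formula: str | None = None
    extra_cols: tuple[str, ...] = ()
    _design_info: object | None = field(default=None, repr=False, compare=False)

    def matrix(self, df: pd.DataFrame, overrides: dict[str, float] | None = None) -> np.ndarray:
        """Build the design matrix for ``df``.

        ``overrides`` maps column names to fixed values (e.g. ``{"A1": 0}``)
        applied before evaluation, implementing "predict under no ICE".
        """
        if overrides:
            df = df.copy()
            for col, val in overrides.items():
                if col in df.columns or col in self.extra_cols:
                    df[col] = val
        if self.formula is not None:
            if self._design_info is None:
                dm = dmatrix(self.formula, df, return_type="dataframe")
                self._design_info = dm.design_info
                block = np.asarray(dm, dtype=float)
            else:
                (dm,) = build_design_matrices([self._design_info], df)
                block = np.asarray(dm, dtype=float)
        else:
            block = np.column_stack(
                [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in self.l_cols]
            )
        if self.extra_cols:
            extra = np.column_stack([df[c].to_numpy(dtype=float) for c in self.extra_cols])
            block = np.column_stack([block, extra])
        return block

    @property
    def column_names(self) -> list[str]:
        if self.formula is not None and self._design_info is not None:
            base = list(self._design_info.column_names)
        elif self.formula is not None:
            base = [self.formula]
        else:
            base = ["Intercept", *self.l_cols]
        return base + list(self.extra_cols)


@dataclass
class OlsFit:
    """An ordinary least squares fit with everything MI needs later."""

    design: Design
    beta: np.ndarray
    sigma2: float          # residual variance, denominator n - p
    n: int
    df_resid: int
    xtx_inv: np.ndarray

    @property
    def column_names(self) -> list[str]:
        return self.design.column_names

    def predict(self, df: pd.DataFrame, overrides: dict[str, float] | None = None) -> np.ndarray:
        return self.design.matrix(df, overrides) @ self.beta


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    n, p = X.shape
    if n < p:
        raise SingularDesignError(
            f"design has {p} columns but only {n} rows", collinear_terms=names
        )
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * _RANK_RTOL if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < p:
        bad = [names[j] for j in piv[rank:]]
        raise SingularDesignError(
            "singular design matrix; collinear terms: " + ", ".join(bad),
            collinear_terms=bad,
        )


def ols(X: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> tuple[np.ndarray, float, np.ndarray]:
    """Least squares with a rank check.

    Returns ``(beta, sigma2, xtx_inv)`` where ``sigma2`` uses denominator
    ``n - p`` (the REML-style unbiased scale used for MI posterior draws).
    """
    names = names if names is not None else [f"x{j}" for j in range(X.shape[1])]
    _check_rank(X, names)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid / df_resid) if df_resid > 0 else 0.0
    xtx_inv = np.linalg.inv(X.T @ X)
    return beta, sigma2, xtx_inv


def fit_ols(df: pd.DataFrame, y_col: str, design: Design) -> OlsFit:
    X = design.matrix(df)
    y = df[y_col].to_numpy(dtype=float)
    beta, sigma2, xtx_inv = ols(X, y, design.column_names)
    return OlsFit(
        design=design,
        beta=beta,
        sigma2=sigma2,
        n=X.shape[0],
        df_resid=X.shape[0] - X.shape[1],
        xtx_inv=xtx_inv,
    )
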