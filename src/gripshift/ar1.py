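"""Fixed-effects regression with AR(1) within-participant errors (ML).

Trial-by-trial observations from the same participant are serially
correlated: residuals follow a first-order autoregressive process with
lag-1 correlation rho.  The model is

    y_i = X_i beta + e_i,   e_i ~ N(0, sigma^2 R(rho)),  per participant i,

with ``R(rho)`` the AR(1) correlation matrix.  Estimation is maximum
likelihood: for fixed rho, a Prais-Winsten whitening transform turns the
fit into ordinary least squares (the first observation of each
participant is scaled by sqrt(1 - rho^2)); rho itself is profiled over a
grid and refined with a bounded scalar optimizer.  At rho = 0 the fit
coincides with OLS exactly.

Term tests are Wald F statistics against the residual degrees of freedom
(n - p).  This residual-df convention is an approximation — no
Satterthwaite/Kenward-Roger adjustment is attempted — and denominator dfs
therefore differ somewhat from software that uses such adjustments.

Single-observation participants are handled naturally: their only row is
scaled by sqrt(1 - rho^2), i.e. treated as serially independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["AR1Regression", "AR1Results", "design_matrix"]


def design_matrix(df: pd.DataFrame, terms: list[tuple[str, ...]],
                  factors: dict[str, list] | None = None,
                  ) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero design matrix for products of 2-level factors / covariates.

    ``terms`` is a list of tuples of column names; each term's column is
    the elementwise product of its components.  Columns listed in
    ``factors`` (or any non-numeric column) are coded +1/-1 over their two
    sorted levels; numeric columns enter as-is.  An intercept column is
    always prepended.
    """
    factors = factors or {}
    coded: dict[str, np.ndarray] = {}

    def code(col: str) -> np.ndarray:
        if col in coded:
            return coded[col]
        s = df[col]
        if col in factors or not pd.api.types.is_numeric_dtype(s):
            levels = factors.get(col) or sorted(pd.unique(s.astype(str)))
            if len(levels) != 2:
                raise ValueError(f"factor {col!r} must have 2 levels, got {levels}")
            coded[col] = np.where(s.astype(str) == str(levels[0]), 1.0, -1.0)
        else:
            coded[col] = s.to_numpy(float)
        return coded[col]

    cols = [np.ones(len(df))]
    names = ["(intercept)"]
    for term in terms:
        cols.append(np.prod([code(c) for c in term], axis=0))
        names.append("*".join(term))
    return np.column_stack(cols), names


def _whiten(y: np.ndarray, X: np.ndarray, starts: np.ndarray, rho: float
            ) -> tuple[np.ndarray, np.ndarray]:
    """Prais-Winsten transform so that OLS on the result is GLS under AR(1)."""
    yw = y.copy()
    Xw = X.copy()
    lagged = np.zeros(len(y), dtype=bool)
    lagged[1:] = ~starts[1:]
    yw[lagged] = y[lagged] - rho * np.roll(y, 1)[lagged]
    Xw[lagged] = X[lagged] - rho * np.roll(X, 1, axis=0)[lagged]
    s = np.sqrt(1.0 - rho ** 2)
    yw[starts] *= s
    Xw[starts] *= s
    return yw / s, Xw / s   # scaled so that (yw - Xw b)'(yw - Xw b) = r' R^-1 r


class AR1Regression:
    """Linear model with AR(1)-correlated errors within ordered groups.

    Parameters
    ----------
    endog : array
        Response, ordered in time within each group.
    exog : array (n, p)
        Design matrix including the intercept (see :func:`design_matrix`).
    groups : array
        Group (participant) labels; consecutive rows with the same label
        form one AR(1) chain.
    exog_names : list of str, optional
    """

    def __init__(self, endog, exog, groups, exog_names: list[str] | None = None):
        self.endog = np.asarray(endog, float)
        self.exog = np.asarray(exog, float)
        groups = np.asarray(groups)
        n, p = self.exog.shape
        if len(self.endog) != n or len(groups) != n:
            raise ValueError("endog, exog and groups must have equal length")
        if np.linalg.matrix_rank(self.exog) < p:
            raise ValueError("rank-deficient design matrix")
        self.exog_names = list(exog_names) if exog_names else \
            [f"x{j}" for j in range(p)]
        self.starts = np.zeros(n, dtype=bool)
        self.starts[0] = True
        self.starts[1:] = groups[1:] != groups[:-1]
        self._n_groups = int(self.starts.sum())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dv: str,
                       terms: list[tuple[str, ...]], groups: str,
                       order_by: str | None = None,
                       factors: dict[str, list] | None = None) -> "AR1Regression":
        if order_by is not None:
            df = df.sort_values([groups, order_by], kind="stable")
        X, names = design_matrix(df, terms, factors)
        return cls(df[dv].to_numpy(float), X, df[groups].to_numpy(), names)

    # -- likelihood ---------------------------------------------------------

    def _profile(self, rho: float):
        """Concentrated (over beta, sigma^2) -2 log-likelihood at ``rho``."""
        y, X = self.endog, self.exog
        n = len(y)
        yw, Xw = _whiten(y, X, self.starts, rho)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        rss = float(np.sum((yw - Xw @ beta) ** 2))   # = r' R^-1 r
        sigma2 = rss / n
        # log|R| summed over groups: (n_g - 1) log(1 - rho^2) per group
        logdet_R = (n - self._n_groups) * np.log(1.0 - rho ** 2)
        m2ll = n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_R
        return m2ll, beta, sigma2, Xw

    def fit(self, rho_bound: float = 0.98, grid: int = 39) -> "AR1Results":
        """Maximize the profile likelihood over rho (grid + local refinement)."""
        rhos = np.linspace(-rho_bound, rho_bound, grid)
        vals = [self._profile(r)[0] for r in rhos]
        k = int(np.argmin(vals))
        lo = rhos[max(k - 1, 0)]
        hi = rhos[min(k + 1, grid - 1)]
        res = optimize.minimize_scalar(lambda r: self._profile(r)[0],
                                       bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-6})
        rho = float(res.x) if res.fun <= vals[k] else float(rhos[k])
        m2ll, beta, sigma2, Xw = self._profile(rho)
        n, p = self.exog.shape
        # ML scale; covariance of beta on the ML scale
        cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
        return AR1Results(model=self, params=pd.Series(beta, index=self.exog_names),
                          cov_params=cov, rho=rho, scale=sigma2,
                          llf=-0.5 * m2ll, df_resid=n - p, nobs=n)


@dataclass
class AR1Results:
    """ML fit of :class:`AR1Regression`: coefficients, rho, Wald tests."""

    model: AR1Regression
    params: pd.Series
    cov_params: np.ndarray
    rho: float
    scale: float
    llf: float
    df_resid: int
    nobs: int

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)),
                         index=self.params.index)

    def wald_f(self, term: str) -> tuple[float, int, int, float]:
        """Wald F test of a single coefficient: (F, df1, df2, p)."""
        j = list(self.params.index).index(term)
        F = float(self.params.iloc[j] ** 2 / self.cov_params[j, j])
        p = float(stats.f.sf(F, 1, self.df_resid))
        return F, 1, self.df_resid, p

    def wald_table(self) -> pd.DataFrame:
        rows = []
        for name in self.params.index:
            if name == "(intercept)":
                continue
            F, df1, df2, p = self.wald_f(name)
            rows.append({"term": name, "F": F, "df1": df1, "df2": df2, "p": p})
        return pd.DataFrame(rows).set_index("term")

    def summary(self) -> str:
        coef = pd.DataFrame({"coef": self.params, "se": self.bse})
        coef["t"] = coef["coef"] / coef["se"]
        head = (f"AR(1)-error ML regression  (n={self.nobs}, "
                f"groups={self.model._n_groups}, rho={self.rho:.3f}, "
                f"sigma2={self.scale:.4g}, llf={self.llf:.2f})\n")
        return head + coef.to_string(float_format="{:.4f}".format)
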