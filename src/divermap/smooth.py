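"""Gaussian additive smooth models on penalized B-spline bases.

A small penalized-least-squares backend standing in for mgcv-style GAMs:
each term gets a B-spline basis (statsmodels' ``BSplines``, data-quantile
knots) with a second-derivative penalty, and the Gaussian/identity model is
solved in closed form, ``(X'X + P) beta = X'y``.  This stays exact on
zero-residual designs where iterative PIRLS fitters fail, and is fully
deterministic.  Basis size k counts basis functions per term, matching the
usual GAM ``k`` convention; with k=3 there is roughly one wiggly degree of
freedom per term, so penalty choice is nearly inert.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.gam.api import BSplines


class CollinearityError(ValueError):
    """Two model terms are (numerically) identical."""


def _check_collinearity(names, columns) -> None:
    for i in range(len(columns)):
        for j in range(i + 1, len(columns)):
            xi, xj = columns[i], columns[j]
            if np.std(xi) == 0 or np.std(xj) == 0:
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            if abs(r) > 0.9999:
                raise CollinearityError(
                    f"terms {names[i]!r} and {names[j]!r} are collinear (r={r:.6f})")


@dataclass
class AdditiveModel:
    """A fitted Gaussian additive model ``y ~ 1 + s(x1) + s(x2) + ...``.

    Parameters
    ----------
    y : response vector.
    terms : mapping of term name -> 1-D covariate vector.
    k : basis functions per term (scalar or mapping).
    alpha : second-derivative penalty weight (scalar or mapping); 0 gives an
        unpenalized regression spline.
    """

    y: np.ndarray
    terms: dict[str, np.ndarray]
    k: int | dict[str, int] = 3
    alpha: float | dict[str, float] = 0.0
    _fit: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        n = self.y.size
        names = list(self.terms)
        cols = []
        for name in names:
            x = np.asarray(self.terms[name], dtype=float)
            if x.shape != (n,):
                raise ValueError(f"term {name!r} length mismatch")
            if np.unique(x).size < 2:
                raise ValueError(f"term {name!r} is constant")
            cols.append(x)
        _check_collinearity(names, cols)

        kmap = {name: (self.k[name] if isinstance(self.k, dict) else int(self.k))
                for name in names}
        amap = {name: (self.alpha[name] if isinstance(self.alpha, dict) else float(self.alpha))
                for name in names}
        for name, kk in kmap.items():
            if kk < 3:
                raise ValueError("basis size k must be >= 3")
            if n < 10 * kk:
                raise ValueError(f"need n >= 10*k = {10 * kk} observations, have {n}")

        x_mat = np.column_stack(cols)
        df = [kmap[name] for name in names]
        degree = [min(3, kmap[name] - 1) for name in names]
        try:
            smoother = BSplines(x_mat, df=df, degree=degree, include_intercept=False)
        except Exception as exc:  # e.g. too few unique values for the knots
            raise ValueError(f"could not build spline basis: {exc}") from exc

        design = np.column_stack([np.ones(n), smoother.basis])
        p = design.shape[1]
        penalty = np.zeros((p, p))
        offset = 1
        slices: dict[str, slice] = {}
        for name, s in zip(names, smoother.smoothers):
            w = s.dim_basis
            sl = slice(offset, offset + w)
            slices[name] = sl
            penalty[sl, sl] = amap[name] * s.cov_der2
            offset += w

        xtx = design.T @ design + penalty
        xty = design.T @ self.y
        try:
            beta = np.linalg.solve(xtx, xty)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(design.T @ design + penalty, xty, rcond=None)[0]

        fitted = design @ beta
        resid = self.y - fitted
        deviance = float(resid @ resid)
        null_dev = float(((self.y - self.y.mean()) ** 2).sum())
        self._fit = {
            "names": names, "beta": beta, "design": design, "slices": slices,
            "fitted": fitted, "resid": resid, "deviance": deviance,
            "null_deviance": null_dev, "smoother": smoother, "k": kmap,
            "alpha": amap,
        }

    # -- queries ------------------------------------------------------------
    @property
    def deviance(self) -> float:
        return self._fit["deviance"]

    @property
    def null_deviance(self) -> float:
        return self._fit["null_deviance"]

    @property
    def fitted(self) -> np.ndarray:
        return self._fit["fitted"]

    @property
    def residuals(self) -> np.ndarray:
        return self._fit["resid"]

    @property
    def deviance_explained_pct(self) -> float:
        null = self.null_deviance
        if null == 0:
            raise ZeroDivisionError("null deviance is zero")
        return float(np.clip(100.0 * (1.0 - self.deviance / null), 0.0, 100.0))

    def term_contribution(self, name: str) -> np.ndarray:
        """Centered fitted contribution of one smooth term."""
        sl = self._fit["slices"][name]
        contrib = self._fit["design"][:, sl] @ self._fit["beta"][sl]
        return contrib - contrib.mean()

    def partial_residuals(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(x, partial residual) pairs for one term, for Fig-style curves."""
        x = np.asarray(self.terms[name], dtype=float)
        return x, self.residuals + self.term_contribution(name)

    def partial_slope(self, name: str) -> tuple[float, float, float]:
        """OLS slope of the partial residuals on x with a 95% CI.

        A null covariate should give a CI covering zero.
        """
        x, pr = self.partial_residuals(name)
        xc = x - x.mean()
        sxx = float(xc @ xc)
        slope = float(xc @ (pr - pr.mean())) / sxx
        resid = (pr - pr.mean()) - slope * xc
        n = x.size
        se = np.sqrt(float(resid @ resid) / max(n - 2, 1) / sxx)
        from scipy.stats import t as tdist
        half = float(tdist.ppf(0.975, max(n - 2, 1))) * se
        return slope, slope - half, slope + half

    def refit_without(self, name: str) -> "AdditiveModel":
        """Reduced model dropping one term (same y, same k/alpha elsewhere)."""
        terms = {t: v for t, v in self.terms.items() if t != name}
        if not terms:
            raise ValueError("cannot drop the only term")
        k = {t: self._fit["k"][t] for t in terms}
        alpha = {t: self._fit["alpha"][t] for t in terms}
        return AdditiveModel(self.y, terms, k=k, alpha=alpha)
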