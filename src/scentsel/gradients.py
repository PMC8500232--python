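"""Lande–Arnold selection-gradient estimation with model diagnostics.

Directional (linear, beta) and stabilising/disruptive (quadratic, gamma)
selection gradients are partial regression coefficients of population-
relative fitness on z-standardised traits.  Quadratic gradients are
reported as twice the fitted squared-term coefficient (and the SE doubled
accordingly), so that gamma matches the curvature of the individual
selection surface.

The estimator resolves multicollinearity iteratively: while any term's
variance inflation factor exceeds a threshold (first the strong threshold,
then the moderate one), the most strongly correlated pair of offending
main-effect terms is replaced by its product (interaction) term and the
model refit.  Samples whose Cook's distance exceeds an exclusion rule are
dropped once and the model refit; lower flag-rule exceedances are reported
but retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted


@dataclass
class ModelDiagnostics:
    vif: pd.Series
    adj_r2: float
    cooks_distance: pd.Series
    excluded: list
    flagged: list
    substitutions: list  # ordered (term_a, term_b) pairs merged into interactions
    converged: bool = True


def vif_table(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per term: VIF_j = 1 / (1 - R^2_j).

    R^2_j is from regressing term j on all other terms (with intercept).
    Perfectly collinear terms get ``inf``.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two terms")
    out = {}
    arr = X.to_numpy(dtype=float)
    n = arr.shape[0]
    for j, name in enumerate(X.columns):
        others = np.column_stack(
            [np.ones(n), np.delete(arr, j, axis=1)]
        )
        y = arr[:, j]
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def _fit_ols(X: pd.DataFrame, w: pd.Series):
    design = sm.add_constant(X, has_constant="add")
    model = sm.OLS(np.asarray(w, dtype=float), design)
    res = model.fit()
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        aliased = corr.stack().idxmax() if X.shape[1] > 1 else tuple(X.columns)
        raise ValueError(
            f"rank-deficient design; aliased terms include {list(aliased)}"
        )
    return res


class SelectionGradientModel(BaseEstimator):
    """OLS estimation of selection gradients on standardised traits.

    Parameters
    ----------
    quadratic : bool, default False
        Include squared terms (reported gamma = 2 x squared coefficient);
        linear terms for the same traits are retained.
    resolve_vif : bool, default True
        Iteratively replace collinear main-effect pairs by interactions.
    strong_threshold, moderate_threshold : float
        VIF levels triggering substitution (phase 1, then phase 2).
    cook_exclude : float, default 1.0
        Samples with Cook's distance above this are excluded once and the
        model refit.
    cook_flag : float or "4/n"
        Reporting-only flag rule.
    max_rounds : int, default 5
        Substitution budget per phase.

    Attributes (after ``fit``)
    ----------
    gradients_ : DataFrame with term, type, estimate, se, t, p, significant
    diagnostics_ : :class:`ModelDiagnostics`
    result_ : final statsmodels OLS results object
    """

    def __init__(
        self,
        quadratic: bool = False,
        resolve_vif: bool = True,
        strong_threshold: float = 10.0,
        moderate_threshold: float = 5.0,
        cook_exclude: float = 1.0,
        cook_flag="4/n",
        max_rounds: int = 5,
        alpha: float = 0.05,
    ):
        self.quadratic = quadratic
        self.resolve_vif = resolve_vif
        self.strong_threshold = strong_threshold
        self.moderate_threshold = moderate_threshold
        self.cook_exclude = cook_exclude
        self.cook_flag = cook_flag
        self.max_rounds = max_rounds
        self.alpha = alpha

    # -- internals ---------------------------------------------------------

    def _build_design(self, X: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
        terms = X.copy()
        types = {c: "linear" for c in X.columns}
        if self.quadratic:
            for c in X.columns:
                name = f"{c}^2"
                terms[name] = X[c] ** 2 - (X[c] ** 2).mean()
                types[name] = "quadratic"
        return terms, types

    def _substitute(self, terms: pd.DataFrame, types: dict, threshold: float,
                    log: list) -> tuple[pd.DataFrame, dict, bool]:
        """One phase of interaction substitution against a VIF threshold."""
        for _ in range(self.max_rounds):
            if terms.shape[1] < 2:
                return terms, types, True
            vif = vif_table(terms)
            offenders = vif[vif > threshold]
            if offenders.empty:
                return terms, types, True
            mains = [t for t in terms.columns if types[t] == "linear"]
            candidates = [t for t in offenders.index if t in mains]
            if len(candidates) == 0:
                return terms, types, False
            corr = terms[mains].corr().abs()
            np.fill_diagonal(corr.values, 0.0)
            best, partner, best_r = None, None, -1.0
            for t in candidates:
                other = corr[t].drop(index=[t], errors="ignore")
                if other.empty:
                    continue
                p = other.idxmax()
                if other[p] > best_r:
                    best, partner, best_r = t, p, other[p]
            if best is None or partner is None:
                return terms, types, False
            inter = f"{best}:{partner}"
            prod = terms[best] * terms[partner]
            terms = terms.drop(columns=[best, partner])
            terms[inter] = (prod - prod.mean()) / prod.std(ddof=1)
            types.pop(best), types.pop(partner)
            types[inter] = "interaction"
            log.append((best, partner))
        return terms, types, False

    # -- API ---------------------------------------------------------------

    def fit(self, X: pd.DataFrame, w):
        """Fit gradients of relative fitness `w` on z-scored traits `X`."""
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float),
                             columns=[f"z{j}" for j in range(np.asarray(X).shape[1])])
        w = pd.Series(np.asarray(w, dtype=float), index=X.index, name="w")
        n = len(X)
        if X.shape[1] == 0:
            raise ValueError("no traits supplied: nothing to fit gradients on")
        if n <= X.shape[1] + 1:
            raise ValueError("need n > number of terms + 1")

        terms, types = self._build_design(X)
        subs: list = []
        converged = True
        if self.resolve_vif and terms.shape[1] >= 2:
            terms, types, ok1 = self._substitute(terms, types,
                                                 self.strong_threshold, subs)
            terms, types, ok2 = self._substitute(terms, types,
                                                 self.moderate_threshold, subs)
            converged = ok1 and ok2
            if not converged:
                warnings.warn(
                    "collinearity resolution did not reach the VIF target "
                    f"within max_rounds={self.max_rounds}; returning best model"
                )

        res = _fit_ols(terms, w)
        infl = res.get_influence()
        cooks = pd.Series(infl.cooks_distance[0], index=terms.index,
                          name="cooks_distance")
        flag_rule = 4.0 / n if self.cook_flag == "4/n" else float(self.cook_flag)
        flagged = list(cooks.index[cooks > flag_rule])
        excluded = list(cooks.index[cooks > self.cook_exclude])
        if excluded:
            if len(excluded) >= n:
                raise ValueError("outlier exclusion would empty the dataset")
            keep = ~cooks.index.isin(excluded)
            terms_kept = terms.loc[keep]
            res = _fit_ols(terms_kept, w.loc[keep])
            infl = res.get_influence()
            cooks_refit = pd.Series(infl.cooks_distance[0],
                                    index=terms_kept.index)
            cooks = cooks_refit
            terms = terms_kept

        rows = []
        for t in terms.columns:
            est = res.params[t]
            se = res.bse[t]
            tval = res.tvalues[t]
            pval = res.pvalues[t]
            kind = types[t]
            if kind == "quadratic":
                est, se = 2.0 * est, 2.0 * se  # gamma = 2 x squared coefficient
            rows.append(
                {"term": t, "type": kind, "estimate": est, "se": se,
                 "t": tval, "p": pval, "significant": bool(pval < self.alpha)}
            )
        self.gradients_ = pd.DataFrame(rows).set_index("term")
        vif = (vif_table(terms) if terms.shape[1] >= 2
               else pd.Series(1.0, index=terms.columns, name="VIF"))
        self.diagnostics_ = ModelDiagnostics(
            vif=vif,
            adj_r2=float(res.rsquared_adj),
            cooks_distance=cooks,
            excluded=excluded,
            flagged=flagged,
            substitutions=subs,
            converged=converged,
        )
        self.result_ = res
        self.terms_ = terms
        self.n_samples_ = n - len(excluded)
        return self

    def predict(self, X: pd.DataFrame):
        """Predicted relative fitness on the fitted surface."""
        check_is_fitted(self, "result_")
        terms, _ = self._build_design(X)
        # interaction terms cannot be rebuilt without the training moments
        if any(":" in t for t in self.terms_.columns):
            raise ValueError("predict is unavailable after interaction substitution")
        design = sm.add_constant(terms[self.terms_.columns], has_constant="add")
        return np.asarray(self.result_.predict(design))


def fit_linear_gradients(X: pd.DataFrame, w, **kwargs) -> SelectionGradientModel:
    """Multivariate linear regression: directional gradients beta."""
    return SelectionGradientModel(quadratic=False, **kwargs).fit(X, w)


def fit_quadratic_gradients(X: pd.DataFrame, w, **kwargs) -> SelectionGradientModel:
    """Quadratic regression: gamma reported as 2x the squared-term coefficient."""
    return SelectionGradientModel(quadratic=True, **kwargs).fit(X, w)


def resolve_collinearity(X: pd.DataFrame, w, strong_threshold: float = 10.0,
                         moderate_threshold: float = 5.0,
                         max_rounds: int = 5) -> SelectionGradientModel:
    """Fit a linear gradient model with VIF-driven interaction substitution."""
    return SelectionGradientModel(
        quadratic=False, resolve_vif=True,
        strong_threshold=strong_threshold,
        moderate_threshold=moderate_threshold,
        max_rounds=max_rounds,
    ).fit(X, w)


def cooks_outliers(X: pd.DataFrame, w, exclude_rule: float = 1.0,
                   flag_rule="4/n") -> SelectionGradientModel:
    """Fit with Cook's-distance flagging/exclusion only (no VIF step)."""
    return SelectionGradientModel(
        quadratic=False, resolve_vif=False,
        cook_exclude=exclude_rule, cook_flag=flag_rule,
    ).fit(X, w)
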