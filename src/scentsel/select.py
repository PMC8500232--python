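"""Pre-selection of fitness-correlated volatiles.

Two complementary screens reduce a samples << compounds trait matrix to a
tractable candidate set before selection-gradient estimation:

* :class:`ElasticNetSelector` — penalised multivariate linear regression
  (mixed L1/L2) of relative fitness on standardised compound amounts; the
  compounds with nonzero coefficients at the cross-validated penalty are the
  linear candidates.
* :class:`BorutaSelector` — an all-relevant shadow-feature wrapper around a
  random-forest regressor that also captures non-linear relationships: each
  feature's importance is compared against the maximum importance among
  shuffled "shadow" copies, and accumulated hits are judged by two-sided
  binomial tests.

Both are scikit-learn estimators (``fit`` / ``get_support`` / ``transform``)
and compose with sklearn pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted, validate_data


class ElasticNetSelector(SelectorMixin, BaseEstimator):
    """Select features with nonzero elastic-net coefficients.

    Parameters
    ----------
    l1_ratio : float, default 0.5
        Mixing between L1 (1.0) and L2 (0.0) penalties.
    cv : int, default 10
        Number of cross-validation folds for the penalty path.
    lambda_rule : {"1se", "min"}, default "1se"
        Pick the strongest penalty within one standard error of the CV
        minimum ("1se", the conservative default, which keeps false
        selections low in wide matrices) or the CV-minimum penalty ("min").
    alpha : float or None
        Fixed penalty; bypasses cross-validation.  ``alpha=0`` is the
        unpenalised (OLS) limit.
    n_alphas : int, default 100
        Length of the automatically generated penalty path.
    random_state : int or None
        Seeds the CV fold shuffle.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Coefficients at the chosen penalty.
    alpha_ : float
        Chosen penalty.
    cv_curve_ : DataFrame or None
        Mean and SE of the CV mean-squared error along the penalty path.
    """

    def __init__(
        self,
        l1_ratio: float = 0.5,
        cv: int = 10,
        lambda_rule: str = "1se",
        alpha: float | None = None,
        n_alphas: int = 100,
        max_iter: int = 10000,
        random_state: int | None = None,
    ):
        self.l1_ratio = l1_ratio
        self.cv = cv
        self.lambda_rule = lambda_rule
        self.alpha = alpha
        self.n_alphas = n_alphas
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self._names = list(X.columns)
        X, y = validate_data(self, X, y, y_numeric=True)
        if np.std(y) == 0:
            raise ValueError("constant response: nothing to select against")
        if self.alpha is not None:
            self.alpha_ = float(self.alpha)
            self.cv_curve_ = None
            if self.alpha == 0:
                # unpenalised limit: ordinary least squares
                Xc = np.column_stack([np.ones(len(y)), X])
                beta = np.linalg.lstsq(Xc, y, rcond=None)[0]
                self.intercept_ = beta[0]
                self.coef_ = beta[1:]
            else:
                m = ElasticNet(
                    alpha=self.alpha, l1_ratio=self.l1_ratio,
                    max_iter=self.max_iter,
                ).fit(X, y)
                self.coef_, self.intercept_ = m.coef_, m.intercept_
        else:
            folds = KFold(self.cv, shuffle=True, random_state=self.random_state)
            cvm = ElasticNetCV(
                l1_ratio=self.l1_ratio,
                alphas=self.n_alphas,
                cv=folds,
                max_iter=self.max_iter,
                n_jobs=1,
            ).fit(X, y)
            mse = cvm.mse_path_.mean(axis=1)
            se = cvm.mse_path_.std(axis=1, ddof=1) / np.sqrt(cvm.mse_path_.shape[1])
            alphas = cvm.alphas_
            i_min = int(np.argmin(mse))
            if self.lambda_rule == "min":
                alpha = alphas[i_min]
            elif self.lambda_rule == "1se":
                bound = mse[i_min] + se[i_min]
                ok = np.flatnonzero(mse <= bound)
                alpha = alphas.max() if len(ok) == 0 else alphas[ok].max()
            else:
                raise ValueError(f"unknown lambda_rule {self.lambda_rule!r}")
            self.alpha_ = float(alpha)
            self.cv_curve_ = pd.DataFrame(
                {"alpha": alphas, "cv_mse": mse, "cv_se": se}
            )
            m = ElasticNet(
                alpha=self.alpha_, l1_ratio=self.l1_ratio, max_iter=self.max_iter
            ).fit(X, y)
            self.coef_, self.intercept_ = m.coef_, m.intercept_
        self.support_ = self.coef_ != 0
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    @property
    def selected_(self) -> list:
        """Names (or indices) of the selected features."""
        check_is_fitted(self, "support_")
        names = getattr(self, "_names", None)
        idx = np.flatnonzero(self.support_)
        return [names[i] for i in idx] if names is not None else list(idx)


class BorutaSelector(SelectorMixin, BaseEstimator):
    """All-relevant feature selection with shadow features (Boruta).

    Each iteration appends an independently shuffled copy of every feature,
    fits a random-forest regressor, and scores a "hit" for features whose
    importance strictly exceeds the maximum shadow importance.  After each
    iteration, undecided features are tested with a two-sided binomial test
    on their accumulated hit counts at level `alpha_level`: significantly
    more hits than the 0.5 null confirms a feature, significantly fewer
    rejects it.  Features still undecided after `max_iter` iterations are
    reported tentative.

    Attributes
    ----------
    status_ : pandas.Series mapping feature -> {"confirmed", "tentative",
        "rejected"}
    history_ : DataFrame of per-iteration importances (features + shadow max)
    pvalues_ : two-sided binomial p per feature at its decision (or final)
        iteration
    """

    def __init__(
        self,
        n_estimators: int = 100,
        max_iter: int = 100,
        alpha_level: float = 0.01,
        max_depth: int | None = None,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_iter = max_iter
        self.alpha_level = alpha_level
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self._names = list(X.columns)
        X, y = validate_data(self, X, y, y_numeric=True)
        n, p = X.shape
        if n < 10:
            raise ValueError("Boruta needs at least 10 samples")
        rng = np.random.default_rng(self.random_state)

        status = np.array(["tentative"] * p, dtype=object)
        hits = np.zeros(p, dtype=int)
        n_rounds = np.zeros(p, dtype=int)
        pvals = np.ones(p)
        history = []

        for it in range(self.max_iter):
            undecided = status == "tentative"
            if not undecided.any():
                break
            # rejected features leave the design (the test continues on the
            # undecided set; confirmed features stay to support the forest)
            active = np.flatnonzero(status != "rejected")
            xa = X[:, active]
            shadows = xa.copy()
            for j in range(shadows.shape[1]):
                shadows[:, j] = shadows[rng.permutation(n), j]
            ext = np.hstack([xa, shadows])
            rf = RandomForestRegressor(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                random_state=int(rng.integers(2 ** 31 - 1)),
                n_jobs=1,
            ).fit(ext, y)
            imp_ext = rf.feature_importances_
            k_active = len(active)
            shadow_max = imp_ext[k_active:].max()
            imp = np.zeros(p)
            imp[active] = imp_ext[:k_active]
            hit = imp > shadow_max
            hits[undecided] += hit[undecided]
            n_rounds[undecided] += 1
            history.append(np.concatenate([imp, [shadow_max]]))

            for j in np.flatnonzero(undecided):
                k, m = hits[j], n_rounds[j]
                p_hi = binom.sf(k - 1, m, 0.5)   # P(hits >= k)
                p_lo = binom.cdf(k, m, 0.5)      # P(hits <= k)
                p_two = min(1.0, 2.0 * min(p_hi, p_lo))
                pvals[j] = p_two
                if p_two < self.alpha_level:
                    status[j] = "confirmed" if k > m / 2 else "rejected"

        self.status_ = pd.Series(
            status, index=getattr(self, "_names", None) or range(p), name="status"
        )
        self.hits_ = hits
        self.n_iterations_ = int(n_rounds.max()) if p else 0
        self.pvalues_ = pvals
        cols = (getattr(self, "_names", None) or [f"f{j}" for j in range(p)]) + [
            "shadow_max"
        ]
        self.history_ = pd.DataFrame(history, columns=cols)
        self.support_ = status == "confirmed"
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    @property
    def confirmed_(self) -> list:
        check_is_fitted(self, "support_")
        return list(self.status_.index[self.status_ == "confirmed"])

    @property
    def tentative_(self) -> list:
        check_is_fitted(self, "support_")
        return list(self.status_.index[self.status_ == "tentative"])


@dataclass
class CandidateSets:
    """Merged pre-selection outcome feeding the gradient models."""

    linear: list
    nonlinear: list
    overlap: list
    any_selected: bool

    def report(self) -> str:
        lines = [
            f"linear candidates (elastic net): {len(self.linear)}: {self.linear}",
            f"non-linear candidates (Boruta):  {len(self.nonlinear)}: {self.nonlinear}",
            f"overlap: {len(self.overlap)}: {self.overlap}",
        ]
        if not self.any_selected:
            lines.append("no candidates selected; gradient fitting will be skipped")
        return "\n".join(lines)


def merge_candidates(enet: ElasticNetSelector, boruta: BorutaSelector) -> CandidateSets:
    """Combine the linear (elastic net) and non-linear (Boruta) screens.

    The two candidate lists are kept separate — the linear list feeds the
    multivariate linear (beta) model, the non-linear list the quadratic
    (gamma) model — and their overlap is reported.
    """
    linear = list(enet.selected_)
    nonlinear = list(boruta.confirmed_)
    overlap = [c for c in nonlinear if c in set(linear)]
    return CandidateSets(
        linear=linear,
        nonlinear=nonlinear,
        overlap=overlap,
        any_selected=bool(linear or nonlinear),
    )


def elastic_net_select(X, w, cv_folds: int = 10, l1_ratio: float = 0.5,
                       lambda_rule: str = "1se",
                       seed: int | None = None) -> ElasticNetSelector:
    """Functional wrapper over :class:`ElasticNetSelector`."""
    return ElasticNetSelector(
        l1_ratio=l1_ratio, cv=cv_folds, lambda_rule=lambda_rule, random_state=seed
    ).fit(X, w)


def boruta_select(X, w, max_iter: int = 100, alpha_level: float = 0.01,
                  n_estimators: int = 100,
                  seed: int | None = None) -> BorutaSelector:
    """Functional wrapper over :class:`BorutaSelector`."""
    return BorutaSelector(
        max_iter=max_iter, alpha_level=alpha_level,
        n_estimators=n_estimators, random_state=seed
    ).fit(X, w)
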