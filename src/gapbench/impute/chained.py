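"""Model-based imputers built on chained equations.

Fitting runs Gibbs-style chained equations on the training matrix alone:
missing cells are initialized at training means/modes, variables are
visited in order of increasing missingness, and ``chained_iters`` sweeps
refit each incomplete variable on all others and redraw its missing cells.
The per-variable models from the final sweep (plus their donor pools) are
the transferable state; applying to new rows — including a single row —
replays the sweeps with the stored models only and never refits.

Three engines share this machinery:

* random-forest donor imputation: route a row down every tree, pool the
  training observations in the reached terminal nodes, and sample one
  donor's observed value;
* Bayesian normal linear regression with predictive mean matching: draw
  coefficients from the posterior, predict, and return the observed value
  of one of the ``k_donors`` training cases with the nearest predictions;
* bootstrap LASSO: per imputation, an L1-penalized fit on a bootstrap
  sample of the observed training data, drawing prediction + Gaussian
  residual (penalized logistic for two-level factors; a classification
  tree, sampled from leaf class frequencies, for multiclass factors).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .base import BaseImputer


def _seed_from(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


class _ChainedImputer(BaseImputer):
    """Shared chained-equations machinery; subclasses provide the
    per-variable model (`_fit_variable`) and draw (`_draw`)."""

    def __init__(self, m=30, chained_iters=5, max_predictors=None,
                 max_fit_rows=None, seed=0):
        self.m = m
        self.chained_iters = chained_iters
        self.max_predictors = max_predictors
        self.max_fit_rows = max_fit_rows
        self.seed = seed

    def _subsample(self, Xobs, yobs, rng):
        """Optional row subsample for per-variable model fitting (a speed
        knob; donor pools then come from the subsample)."""
        if self.max_fit_rows is None or len(yobs) <= self.max_fit_rows:
            return Xobs, yobs
        idx = rng.choice(len(yobs), size=self.max_fit_rows, replace=False)
        return Xobs[idx], yobs[idx]

    # -- encoding ---------------------------------------------------------
    def _encode(self, X: pd.DataFrame) -> np.ndarray:
        Z = np.empty((len(X), len(self.columns_)))
        for j, c in enumerate(self.columns_):
            if self.kinds_[c] == "categorical":
                codes = X[c].cat.codes.to_numpy(dtype=float)
                codes[codes < 0] = np.nan
                Z[:, j] = codes
            else:
                Z[:, j] = X[c].to_numpy(dtype=float)
        return Z

    def _decode(self, Z: np.ndarray, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for j, c in enumerate(self.columns_):
            if self.kinds_[c] == "categorical":
                codes = np.round(Z[:, j]).astype(int)
                codes = np.clip(codes, 0, len(self.categories_[c]) - 1)
                out[c] = pd.Categorical.from_codes(codes, categories=self.categories_[c])
            else:
                out[c] = Z[:, j]
        return out

    # -- fitting ----------------------------------------------------------
    def _fit(self, X: pd.DataFrame) -> None:
        self.categories_ = {
            c: list(X[c].cat.categories)
            for c in self.columns_
            if self.kinds_[c] == "categorical"
        }
        self.is_cat_ = np.array(
            [self.kinds_[c] == "categorical" for c in self.columns_]
        )
        Z = self._encode(X)
        miss = np.isnan(Z)
        n, d = Z.shape
        counts = miss.sum(axis=0)

        init = np.empty(d)
        for j in range(d):
            obs = Z[~miss[:, j], j]
            if obs.size == 0:
                warnings.warn(
                    f"variable {self.columns_[j]} has zero observed training values; "
                    "falling back to a zero default"
                )
                init[j] = 0.0
            elif self.is_cat_[j]:
                vals, cnts = np.unique(obs, return_counts=True)
                init[j] = vals[np.argmax(cnts)]
            else:
                init[j] = obs.mean()
        self.init_values_ = init

        modelable = (counts > 0) & (n - counts >= 3)
        order = np.argsort(counts, kind="stable")  # ascending missingness
        self.visit_order_ = order[modelable[order]]

        Zw = Z.copy()
        Zw[miss] = np.broadcast_to(init, Z.shape)[miss]

        self.predictors_: dict[int, np.ndarray] = {}
        if self.max_predictors is not None and self.max_predictors < d - 1:
            with np.errstate(invalid="ignore", divide="ignore"):
                C = np.corrcoef(Zw, rowvar=False)
            C = np.nan_to_num(np.abs(C))
            np.fill_diagonal(C, -1.0)
            for j in self.visit_order_:
                self.predictors_[j] = np.sort(
                    np.argpartition(C[j], -self.max_predictors)[-self.max_predictors:]
                )
        else:
            all_idx = np.arange(d)
            for j in self.visit_order_:
                self.predictors_[j] = all_idx[all_idx != j]

        rng = np.random.default_rng(np.random.SeedSequence((self.seed, 0)))
        self.models_: dict[int, object] = {}
        for it in range(self.chained_iters):
            for j in self.visit_order_:
                obs = ~miss[:, j]
                P = self.predictors_[j]
                Xo, yo = self._subsample(Zw[np.ix_(obs, P)], Z[obs, j], rng)
                state = self._fit_variable(j, Xo, yo, rng)
                self.models_[j] = state
                mj = miss[:, j]
                if mj.any():
                    Zw[mj, j] = self._draw(j, state, Zw[np.ix_(mj, P)], rng)
        self._train_missing_ = miss
        self._post_fit(Z, Zw, miss, rng)

    def _post_fit(self, Z, Zw, miss, rng) -> None:
        pass

    # -- applying ---------------------------------------------------------
    def _state_for(self, j: int, imp_index: int):
        return self.models_[j]

    def _transform_once(self, X, rng, imp_index):
        Z = self._encode(X)
        miss = np.isnan(Z)
        Zw = Z.copy()
        Zw[miss] = np.broadcast_to(self.init_values_, Z.shape)[miss]
        todo = [j for j in self.visit_order_ if miss[:, j].any()]
        for it in range(self.chained_iters):
            for j in todo:
                mj = miss[:, j]
                state = self._state_for(j, imp_index)
                Zw[mj, j] = self._draw(
                    j, state, Zw[np.ix_(mj, self.predictors_[j])], rng
                )
        return self._decode(Zw, X)

    def draw_for_variable(
        self,
        variable: str,
        rows: pd.DataFrame,
        rng: np.random.Generator | None = None,
        imp_index: int = 0,
    ) -> np.ndarray:
        """Single-variable draw for given rows (other columns initialized
        at training means/modes where missing).  Supports a single row."""
        rows = self._check_apply_input(rows)
        rng = np.random.default_rng(self.seed) if rng is None else rng
        j = self.columns_.index(variable)
        if j not in self.models_:
            raise KeyError(f"no fitted model for variable {variable!r}")
        Z = self._encode(rows)
        miss = np.isnan(Z)
        Z[miss] = np.broadcast_to(self.init_values_, Z.shape)[miss]
        vals = self._draw(
            j, self._state_for(j, imp_index), Z[:, self.predictors_[j]], rng
        )
        if self.is_cat_[j]:
            cats = self.categories_[variable]
            return np.asarray([cats[int(v)] for v in vals], dtype=object)
        return vals

    # -- subclass surface -------------------------------------------------
    def _fit_variable(self, j, Xobs, yobs, rng):  # pragma: no cover - abstract
        raise NotImplementedError

    def _draw(self, j, state, Xrows, rng):  # pragma: no cover - abstract
        raise NotImplementedError


class RandomForestDonorImputer(_ChainedImputer):
    """Random-forest imputation with terminal-node donor sampling."""

    method = "rf_donor"

    def __init__(self, m=30, n_trees=10, max_depth=None, max_features="sqrt",
                 chained_iters=5, max_predictors=None, max_fit_rows=None, seed=0):
        super().__init__(m=m, chained_iters=chained_iters,
                         max_predictors=max_predictors,
                         max_fit_rows=max_fit_rows, seed=seed)
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.max_features = max_features

    def _fit_variable(self, j, Xobs, yobs, rng):
        cls = RandomForestClassifier if self.is_cat_[j] else RandomForestRegressor
        forest = cls(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            max_features=self.max_features,
            min_samples_leaf=5,
            n_jobs=1,
            random_state=_seed_from(rng),
        )
        forest.fit(Xobs, yobs.astype(int) if self.is_cat_[j] else yobs)
        return {
            "forest": forest,
            "leaves_obs": forest.apply(Xobs),
            "y_obs": yobs.copy(),
        }

    def _draw(self, j, state, Xrows, rng):
        leaves = state["forest"].apply(Xrows)  # (r, n_trees)
        leaves_obs = state["leaves_obs"]  # (n_obs, n_trees)
        y_obs = state["y_obs"]
        r, n_obs = len(Xrows), y_obs.size
        # donor pool per row: union over trees of observations in the same
        # terminal node the row reaches; sampled uniformly over the union
        member = np.zeros((r, n_obs), dtype=bool)
        for t in range(leaves.shape[1]):
            member |= leaves[:, t][:, None] == leaves_obs[:, t][None, :]
        counts = member.sum(axis=1)
        cum = member.cumsum(axis=1)
        u = rng.random(r) * np.maximum(counts, 1)
        pick = (cum > u[:, None]).argmax(axis=1)
        out = y_obs[pick]
        return np.where(counts > 0, out, y_obs.mean())


class BayesianPMMImputer(_ChainedImputer):
    """Bayesian normal linear model with predictive mean matching.

    Posterior: conjugate normal-inverse-gamma on standardized predictors
    with a small ridge for stability.  Matching metric is the absolute
    difference between the target row's prediction (posterior-draw
    coefficients) and the donors' predictions (posterior-mean
    coefficients); one of the ``k_donors`` nearest donors is sampled and
    its observed value returned, so imputations always lie within the
    range of observed training values.  Categorical variables are matched
    on integer level codes, so imputed levels are always valid.
    """

    method = "bayes_pmm"

    def __init__(self, m=30, k_donors=5, chained_iters=5, max_predictors=None,
                 max_fit_rows=None, seed=0):
        super().__init__(m=m, chained_iters=chained_iters,
                         max_predictors=max_predictors,
                         max_fit_rows=max_fit_rows, seed=seed)
        self.k_donors = k_donors

    def _fit_variable(self, j, Xobs, yobs, rng):
        n, p = Xobs.shape
        mx = Xobs.mean(axis=0)
        sx = Xobs.std(axis=0)
        sx[sx == 0] = 1.0
        Xs = np.column_stack([np.ones(n), (Xobs - mx) / sx])
        S = Xs.T @ Xs + 1e-4 * n * np.eye(p + 1)
        Xty = Xs.T @ yobs
        L = np.linalg.cholesky(S)
        beta = cho_solve((L, True), Xty)
        resid = yobs - Xs @ beta
        dof = max(n - p - 1, 1)
        sigma2 = float(resid @ resid) / dof
        return {
            "mx": mx,
            "sx": sx,
            "beta": beta,
            "L": L,
            "sigma2": sigma2,
            "dof": dof,
            "donor_preds": Xs @ beta,
            "y_obs": yobs.copy(),
        }

    def _draw(self, j, state, Xrows, rng):
        beta, L = state["beta"], state["L"]
        sigma2_star = state["sigma2"] * state["dof"] / max(rng.chisquare(state["dof"]), 1e-12)
        z = rng.standard_normal(beta.size)
        beta_star = beta + np.sqrt(sigma2_star) * solve_triangular(L, z, trans="T", lower=True)
        Xs = np.column_stack(
            [np.ones(len(Xrows)), (Xrows - state["mx"]) / state["sx"]]
        )
        yhat = Xs @ beta_star
        donor_preds = state["donor_preds"]
        y_obs = state["y_obs"]
        k = min(self.k_donors, y_obs.size)
        dist = np.abs(yhat[:, None] - donor_preds[None, :])  # (r, n_obs)
        if k < y_obs.size:
            nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
        else:
            nearest = np.broadcast_to(np.arange(y_obs.size), (len(Xrows), y_obs.size))
        picks = nearest[np.arange(len(Xrows)), rng.integers(0, nearest.shape[1], len(Xrows))]
        return y_obs[picks]


class LassoBootstrapImputer(_ChainedImputer):
    """Bootstrap LASSO imputation.

    Each of the m imputations uses its own L1-penalized model fit on a
    bootstrap sample of the observed training data; numeric draws add a
    Gaussian residual at the bootstrap residual scale.  Two-level factors
    use an L1-penalized logistic draw; multiclass factors a classification
    tree sampled from leaf class frequencies.
    """

    method = "lasso_boot"

    def __init__(self, m=30, alpha=0.01, chained_iters=5, max_predictors=None,
                 max_fit_rows=None, seed=0):
        super().__init__(m=m, chained_iters=chained_iters,
                         max_predictors=max_predictors,
                         max_fit_rows=max_fit_rows, seed=seed)
        self.alpha = alpha

    def _fit_one_bootstrap(self, j, Xobs, yobs, rng):
        n = len(yobs)
        idx = rng.integers(0, n, size=n)
        Xb, yb = Xobs[idx], yobs[idx]
        mx = Xobs.mean(axis=0)
        sx = Xobs.std(axis=0)
        sx[sx == 0] = 1.0
        Xbs = (Xb - mx) / sx
        if self.is_cat_[j]:
            levels = np.unique(yobs)
            if np.unique(yb).size < 2:
                return {"kind": "const", "value": float(yb[0]), "mx": mx, "sx": sx}
            if levels.size == 2:
                clf = LogisticRegression(
                    solver="liblinear", l1_ratio=1.0, C=1.0,
                    random_state=_seed_from(rng),
                )
                clf.fit(Xbs, yb.astype(int))
                return {"kind": "logistic", "model": clf, "mx": mx, "sx": sx}
            tree = DecisionTreeClassifier(
                max_depth=5, min_samples_leaf=10, random_state=_seed_from(rng)
            )
            tree.fit(Xbs, yb.astype(int))
            return {"kind": "tree", "model": tree, "mx": mx, "sx": sx}
        my, sy = yobs.mean(), yobs.std()
        if sy == 0:
            return {"kind": "const", "value": float(my), "mx": mx, "sx": sx}
        ybs = (yb - my) / sy
        lasso = Lasso(alpha=self.alpha, max_iter=2000)
        lasso.fit(Xbs, ybs)
        resid = ybs - lasso.predict(Xbs)
        resid_sd = float(np.sqrt(np.mean(resid**2)))
        return {
            "kind": "linear",
            "model": lasso,
            "mx": mx,
            "sx": sx,
            "my": my,
            "sy": sy,
            "resid_sd": resid_sd,
        }

    def _fit_variable(self, j, Xobs, yobs, rng):
        return self._fit_one_bootstrap(j, Xobs, yobs, rng)

    def _post_fit(self, Z, Zw, miss, rng) -> None:
        # one bootstrap-fitted coefficient set per imputation, per variable
        for j in self.visit_order_:
            obs = ~miss[:, j]
            P = self.predictors_[j]
            Xobs, yobs = self._subsample(Zw[np.ix_(obs, P)], Z[obs, j], rng)
            self.models_[j] = [
                self._fit_one_bootstrap(j, Xobs, yobs, rng) for _ in range(self.m)
            ]

    def _state_for(self, j, imp_index):
        state = self.models_[j]
        if isinstance(state, list):
            return state[imp_index % len(state)]
        return state

    def _draw(self, j, state, Xrows, rng):
        if state["kind"] == "const":
            return np.full(len(Xrows), state["value"])
        Xs = (Xrows - state["mx"]) / state["sx"]
        if state["kind"] == "linear":
            pred = state["model"].predict(Xs)
            draws = pred + state["resid_sd"] * rng.standard_normal(len(Xs))
            return state["my"] + state["sy"] * draws
        if state["kind"] == "logistic":
            p1 = state["model"].predict_proba(Xs)[:, 1]
            classes = state["model"].classes_
            return np.where(rng.random(len(Xs)) < p1, classes[1], classes[0]).astype(float)
        proba = state["model"].predict_proba(Xs)
        classes = state["model"].classes_
        cum = np.cumsum(proba, axis=1)
        u = rng.random(len(Xs))[:, None]
        picks = (u > cum).sum(axis=1)
        return classes[np.minimum(picks, len(classes) - 1)].astype(float)
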