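"""Approximate Bayesian computation: reference tables, model choice and
regression-adjusted posteriors.

The workflow mirrors rejection/regression ABC as commonly practised:

1. draw parameters from the prior, simulate a dataset of independent loci,
   reduce it to a summary vector (:mod:`divergesim.sumstats`);
2. discard simulations whose across-locus mean F_ST or pooled Tajima's D
   fall outside the acceptance region applied to the observed data
   (:func:`filter_simulations`);
3. model choice: pool the per-model reference tables, accept the tolerance
   fraction of rows nearest the observation in MAD-scaled Euclidean
   distance, and report both the acceptance proportions (rejection) and a
   distance-weighted multinomial logistic regression evaluated at the
   observation;
4. parameter estimation: on the chosen model's table, accept the tolerance
   fraction, weight by the Epanechnikov kernel
   ``w = 1 - (d / d_max)^2``, regress log-parameters on scaled summaries
   with an ensemble of single-hidden-layer neural networks, and correct
   each accepted draw by the fitted conditional expectation
   (``theta* = m(s_obs) + theta - m(s)``).

Both stages are exposed as sklearn-style estimators
(:class:`ABCModelChoice`, :class:`ABCPosteriorRegressor`); the module-level
functions are thin wrappers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from . import sumstats
from .simulator import (LocusConfig, ModelId, PriorSet, build_timelines_batch,
                        model_param_names, sample_prior_batch,
                        simulate_locus_stats)

#: simulation/locus acceptance region used both for observed loci and
#: reference-table rows: mean F_ST at most this, mean pooled D inside [0, 1]
FILTER_FST_MAX = 0.159
FILTER_D_RANGE = (0.0, 1.0)


def filter_simulations(mean_fst: float, mean_d: float,
                       fst_max: float = FILTER_FST_MAX,
                       d_range: tuple = FILTER_D_RANGE) -> bool:
    """Keep/drop rule for one simulated dataset (True = keep)."""
    if np.isnan(mean_fst) or np.isnan(mean_d):
        return False
    return (mean_fst <= fst_max) and (d_range[0] <= mean_d <= d_range[1])


@dataclass
class ReferenceTable:
    """Rows of (model label, parameter draw, summary vector)."""

    model: str
    params: pd.DataFrame
    stats: np.ndarray
    stat_names: list
    aux: pd.DataFrame
    n_raw: int = 0
    n_filtered: int = 0
    seed: int | None = None

    @property
    def n_rows(self) -> int:
        return self.stats.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.concat(
            [self.params.reset_index(drop=True),
             pd.DataFrame(self.stats, columns=self.stat_names),
             self.aux.reset_index(drop=True)], axis=1)
        df.insert(0, "model", self.model)
        return df

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_reference_table(model, priors: PriorSet, n_sims: int, n_loci: int,
                          locus_config: LocusConfig | None = None, *,
                          n_K: int = 20, n_W: int = 20, seed: int = 0,
                          statistics=sumstats.DEFAULT_SUMMARY_STATS,
                          apply_filter: bool = True,
                          target_retained: int | None = None,
                          batch_size: int = 4000,
                          max_raw: int | None = None) -> ReferenceTable:
    """Prior-predictive simulation of a reference table.

    With ``target_retained`` set, batches are simulated until that many rows
    survive the simulation filter (``n_sims`` is then ignored); otherwise
    exactly ``n_sims`` prior draws are simulated and the surviving rows
    returned.  Raises if more than 99% of simulations are filtered.
    """
    model = ModelId.parse(model)
    cfg = locus_config or LocusConfig()
    if n_sims < 1 and not target_retained:
        raise ValueError("n_sims must be >= 1")
    root = np.random.SeedSequence(seed)
    pnames = model_param_names(model)
    kept_params, kept_stats, kept_aux = [], [], []
    n_raw = 0
    n_kept = 0
    batch_i = 0
    while True:
        if target_retained is not None:
            todo = batch_size
            if n_kept >= target_retained:
                break
            if max_raw is not None and n_raw >= max_raw:
                break
        else:
            todo = min(batch_size, n_sims - n_raw)
            if todo <= 0:
                break
        ss_params, ss_engine = np.random.SeedSequence(
            entropy=seed, spawn_key=(batch_i,)).spawn(2)
        batch_i += 1
        rng = np.random.default_rng(ss_params)
        draws = sample_prior_batch(priors, model, todo, rng)
        tls = build_timelines_batch(draws, model, cfg)
        rows = simulate_locus_stats(tls, n_K, n_W, cfg, n_loci, ss_engine)
        summ = sumstats.summarize_rows(rows, statistics)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_fst = np.nanmean(
                rows[:, :, sumstats.LOCUS_STAT_FIELDS.index("fst")], axis=1)
            mean_d = np.nanmean(
                rows[:, :, sumstats.LOCUS_STAT_FIELDS.index("d_pool")], axis=1)
        ok = ~np.isnan(summ).any(axis=1)
        if apply_filter:
            ok &= (mean_fst <= FILTER_FST_MAX) & \
                  (mean_d >= FILTER_D_RANGE[0]) & (mean_d <= FILTER_D_RANGE[1])
        n_raw += todo
        n_kept += int(ok.sum())
        kept_params.append(pd.DataFrame({k: draws[k][ok] for k in pnames}))
        kept_stats.append(summ[ok])
        kept_aux.append(pd.DataFrame({"mean_fst": mean_fst[ok],
                                      "mean_d_pool": mean_d[ok]}))
        if n_raw >= 2000 and n_kept < 0.01 * n_raw:
            raise RuntimeError(
                f"more than 99% of simulations filtered for {model.name}; "
                "priors and simulation filter are incompatible")
    params = pd.concat(kept_params, ignore_index=True)
    stats = np.vstack(kept_stats) if kept_stats else np.empty((0, 0))
    aux = pd.concat(kept_aux, ignore_index=True)
    if target_retained is not None and len(params) > target_retained:
        params = params.iloc[:target_retained].reset_index(drop=True)
        stats = stats[:target_retained]
        aux = aux.iloc[:target_retained].reset_index(drop=True)
    return ReferenceTable(model=model.name, params=params, stats=stats,
                          stat_names=sumstats.summary_names(statistics),
                          aux=aux, n_raw=n_raw,
                          n_filtered=n_raw - len(params), seed=seed)


# ---------------------------------------------------------------------------
# scaling and distance

def mad_scale(stats: np.ndarray, observed: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Scale columns by their median absolute deviation across the table.

    Returns (scaled table, scaled observation, scale factors, kept column
    mask); zero-MAD columns are dropped with a warning.
    """
    stats = np.asarray(stats, dtype=float)
    observed = np.asarray(observed, dtype=float).ravel()
    mad = sps.median_abs_deviation(stats, axis=0, scale=1.0)
    keep = mad > 0
    if not keep.any():
        raise ValueError("all summary-statistic columns are constant")
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant summary "
                      "columns (zero MAD)")
    return (stats[:, keep] / mad[keep], observed[keep] / mad[keep],
            mad[keep], keep)


def _accept(scaled: np.ndarray, scaled_obs: np.ndarray, tolerance: float,
            min_accepted: int = 1
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest tolerance-fraction rows; ties broken by row index (stable)."""
    d = np.sqrt(((scaled - scaled_obs) ** 2).sum(axis=1))
    n_acc = max(min_accepted, int(math.ceil(tolerance * len(d))))
    n_acc = min(n_acc, len(d))
    order = np.argsort(d, kind="stable")[:n_acc]
    return order, d[order], d


def epanechnikov_weights(dist: np.ndarray) -> np.ndarray:
    """w = 1 - (d/d_max)^2 on accepted distances (all ones if d_max == 0)."""
    dmax = dist.max()
    if dmax == 0:
        return np.ones_like(dist)
    w = 1.0 - (dist / dmax) ** 2
    # the boundary row would get weight exactly 0; keep it infinitesimal
    return np.maximum(w, 1e-12)


# ---------------------------------------------------------------------------
# model choice

@dataclass
class ModelPosterior:
    """Posterior model probabilities under equal prior model weights."""

    rejection: dict
    mnlogistic: dict
    tolerance: float
    n_accepted: int
    method: str = "mnlogistic"

    @property
    def probabilities(self) -> dict:
        return getattr(self, self.method)

    @property
    def best_model(self) -> str:
        probs = self.probabilities
        return max(probs, key=probs.get)


class ABCModelChoice(BaseEstimator, ClassifierMixin):
    """ABC model choice by rejection and multinomial logistic regression.

    Fit on pooled reference-table summaries ``X`` with model labels ``y``;
    ``predict_proba`` returns the multinomial-logistic posterior evaluated
    at each observation, fitted on the accepted rows with Epanechnikov
    distance weights (the R ``abc::postpr`` construction).
    """

    def __init__(self, tolerance: float = 0.005, weighted: bool = True,
                 C: float = 1e4, max_iter: int = 5000, min_accepted: int = 50):
        self.tolerance = tolerance
        self.weighted = weighted
        self.C = C
        self.max_iter = max_iter
        self.min_accepted = min_accepted

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("model choice needs at least two models")
        if len(X) < self.min_accepted:
            raise ValueError(
                f"need at least {self.min_accepted} reference rows")
        self.X_ = X
        self.y_ = y
        mad = sps.median_abs_deviation(X, axis=0, scale=1.0)
        self.keep_ = mad > 0
        self.scale_ = np.where(self.keep_, mad, 1.0)
        self.X_scaled_ = X[:, self.keep_] / self.scale_[self.keep_]
        return self

    def posterior(self, observed) -> ModelPosterior:
        check_is_fitted(self, "X_scaled_")
        obs = np.asarray(observed, dtype=float).ravel()
        obs_scaled = obs[self.keep_] / self.scale_[self.keep_]
        idx, dist, _ = _accept(self.X_scaled_, obs_scaled, self.tolerance,
                               self.min_accepted)
        labels = self.y_[idx]
        rej = {str(c): float(np.mean(labels == c)) for c in self.classes_}
        present = np.unique(labels)
        missing = [c for c in self.classes_ if c not in present]
        if missing:
            warnings.warn("models absent from the accepted set get zero "
                          f"multinomial-logistic probability: {missing}")
        if len(present) < 2:
            mnl = {str(c): float(c in present) for c in self.classes_}
        else:
            w = epanechnikov_weights(dist) if self.weighted else None
            clf = LogisticRegression(C=self.C, max_iter=self.max_iter)
            clf.fit(self.X_scaled_[idx], labels, sample_weight=w)
            p = clf.predict_proba(obs_scaled[None, :])[0]
            mnl = {str(c): 0.0 for c in self.classes_}
            for c, pc in zip(clf.classes_, p):
                mnl[str(c)] = float(pc)
        return ModelPosterior(rejection=rej, mnlogistic=mnl,
                              tolerance=self.tolerance, n_accepted=len(idx))

    def predict_proba(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((len(X), len(self.classes_)))
        for i, row in enumerate(X):
            probs = self.posterior(row).mnlogistic
            out[i] = [probs[str(c)] for c in self.classes_]
        return out

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def combine_tables(tables: dict) -> tuple[np.ndarray, np.ndarray, list]:
    """Stack per-model reference tables into (X, labels, stat_names)."""
    names = None
    xs, ys = [], []
    for model, tab in tables.items():
        if names is None:
            names = tab.stat_names
        elif names != tab.stat_names:
            raise ValueError("reference tables disagree on statistic order")
        xs.append(tab.stats)
        ys.append(np.repeat(str(model), tab.n_rows))
    return np.vstack(xs), np.concatenate(ys), names


def abc_model_choice(observed, tables: dict, tolerance: float = 0.005
                     ) -> ModelPosterior:
    """Model choice over pooled per-model reference tables."""
    X, y, _ = combine_tables(tables)
    obs = observed.values if isinstance(observed, sumstats.SummaryVector) \
        else observed
    est = ABCModelChoice(tolerance=tolerance).fit(X, y)
    return est.posterior(obs)


def two_stage_model_choice(observed, tables: dict, tolerance: float = 0.005
                           ) -> dict:
    """Hierarchical protocol: choose within each size-regime group first,
    then compare each group's best model head to head."""
    groups = {"A": {}, "B": {}}
    for name, tab in tables.items():
        groups[ModelId.parse(name).group][name] = tab
    stage1 = {g: abc_model_choice(observed, tabs, tolerance)
              for g, tabs in groups.items() if len(tabs) >= 2}
    finalists = {g: p.best_model for g, p in stage1.items()}
    final_tables = {m: tables[m] for m in finalists.values()}
    final = abc_model_choice(observed, final_tables, tolerance)
    return {"within_group": stage1, "finalists": finalists, "final": final}


def bayes_factor(posterior: ModelPosterior, model_i: str, model_j: str,
                 method: str = "mnlogistic") -> float:
    """BF_ij = p_i / p_j under equal prior model probabilities."""
    probs = getattr(posterior, method)
    p_i, p_j = probs[str(model_i)], probs[str(model_j)]
    if p_j == 0:
        return math.inf
    return p_i / p_j


def cross_validate_model_choice(tables: dict, n_pseudo: int,
                                tolerance: float, seed: int = 0,
                                method: str = "mnlogistic") -> pd.DataFrame:
    """Leave-one-out confusion matrix of true vs selected model.

    For each model, ``n_pseudo`` rows of its reference table serve as
    pseudo-observations; each is removed from the pooled table before the
    choice is made.
    """
    if n_pseudo < 1:
        raise ValueError("n_pseudo must be >= 1")
    X, y, _ = combine_tables(tables)
    rng = np.random.default_rng(seed)
    models = list(tables.keys())  # offsets must follow the stacking order
    conf = pd.DataFrame(0, index=sorted(models), columns=sorted(models))
    offsets = {}
    pos = 0
    for m in models:
        offsets[m] = pos
        pos += tables[m].n_rows
    for m in models:
        take = rng.choice(tables[m].n_rows, size=min(n_pseudo,
                                                     tables[m].n_rows),
                          replace=False)
        for t in take:
            i = offsets[m] + t
            mask = np.ones(len(X), dtype=bool)
            mask[i] = False
            est = ABCModelChoice(tolerance=tolerance).fit(X[mask], y[mask])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                post = est.posterior(X[i])
            sel = max(getattr(post, method), key=getattr(post, method).get)
            conf.loc[m, sel] += 1
    return conf


# ---------------------------------------------------------------------------
# weighted single-hidden-layer network ensemble

def _nnet_unpack(theta, d, h, p):
    i = 0
    W1 = theta[i:i + (d + 1) * h].reshape(d + 1, h)
    i += (d + 1) * h
    W2 = theta[i:i + (h + 1) * p].reshape(h + 1, p)
    return W1, W2


def _nnet_loss_grad(theta, X1, Y, w, d, h, p, decay):
    W1, W2 = _nnet_unpack(theta, d, h, p)
    A = np.tanh(X1 @ W1)                       # n x h
    A1 = np.hstack([A, np.ones((len(A), 1))])  # n x (h+1)
    R = A1 @ W2 - Y                            # residuals n x p
    wsum = w.sum()
    loss = float((w[:, None] * R ** 2).sum() / wsum
                 + decay * ((W1 ** 2).sum() + (W2 ** 2).sum()))
    GR = 2.0 * w[:, None] * R / wsum           # dLoss/dOut
    gW2 = A1.T @ GR + 2.0 * decay * W2
    GA = GR @ W2[:-1].T * (1.0 - A ** 2)
    gW1 = X1.T @ GA + 2.0 * decay * W1
    return loss, np.concatenate([gW1.ravel(), gW2.ravel()])


class _Nnet:
    """Weighted single-hidden-layer feed-forward regressor (tanh hidden,
    linear output, weight-decay penalty), fitted with L-BFGS."""

    def __init__(self, hidden: int, decay: float, rng: np.random.Generator,
                 max_iter: int = 500):
        self.hidden = hidden
        self.decay = decay
        self.rng = rng
        self.max_iter = max_iter

    def fit(self, X, Y, w):
        n, d = X.shape
        p = Y.shape[1]
        h = self.hidden
        X1 = np.hstack([X, np.ones((n, 1))])
        theta0 = self.rng.uniform(-0.7, 0.7, size=(d + 1) * h + (h + 1) * p)
        res = optimize.minimize(
            _nnet_loss_grad, theta0, jac=True,
            args=(X1, Y, w, d, h, p, self.decay),
            method="L-BFGS-B", options={"maxiter": self.max_iter})
        self.theta_ = res.x
        self.converged_ = bool(res.success) or res.status == 1
        self.dims_ = (d, h, p)
        return self

    def predict(self, X):
        d, h, p = self.dims_
        W1, W2 = _nnet_unpack(self.theta_, d, h, p)
        X1 = np.hstack([np.atleast_2d(X), np.ones((len(np.atleast_2d(X)), 1))])
        A1 = np.hstack([np.tanh(X1 @ W1), np.ones((len(X1), 1))])
        return A1 @ W2


# ---------------------------------------------------------------------------
# posterior regression adjustment

def weighted_quantile(x: np.ndarray, q, w: np.ndarray) -> np.ndarray:
    """Weighted quantiles by interpolation of the weighted empirical CDF."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(np.atleast_1d(q), cw, x)


@dataclass
class AdjustedPosterior:
    """Regression-adjusted ABC posterior sample for one model."""

    param_names: list
    accepted: pd.DataFrame
    weights: np.ndarray
    adjusted: pd.DataFrame
    tolerance: float
    transform: str
    point_estimates: pd.DataFrame = field(default=None)

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)

    def quantile(self, q, param: str) -> float:
        return float(weighted_quantile(self.adjusted[param].to_numpy(), q,
                                       self.weights)[0])

    def summary_table(self) -> pd.DataFrame:
        return self.point_estimates


def _weighted_mode(x: np.ndarray, w: np.ndarray) -> float:
    """Mode of a weighted kernel density (Silverman bandwidth)."""
    if np.allclose(x, x[0]):
        return float(x[0])
    try:
        kde = sps.gaussian_kde(x, bw_method="silverman", weights=w)
    except np.linalg.LinAlgError:
        return float(weighted_quantile(x, 0.5, w)[0])
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


class ABCPosteriorRegressor(BaseEstimator, RegressorMixin):
    """Neural-network regression-adjusted ABC posterior.

    Fit on one model's reference table (summaries ``X``, parameter draws
    ``y``); :meth:`adjust` accepts the tolerance fraction nearest an
    observation, weights by the Epanechnikov kernel and corrects the
    accepted draws with an ensemble of weighted single-hidden-layer
    networks regressing (log-)parameters on scaled summaries.  The
    adjustment is homoscedastic: ``theta* = m(s_obs) + (theta - m(s))``.
    """

    def __init__(self, tolerance: float = 0.002, n_networks: int = 50,
                 hidden_units: int = 5, decay_grid: tuple = (1e-4, 1e-3, 1e-2),
                 transform: str = "log", max_iter: int = 500,
                 random_state: int = 0):
        self.tolerance = tolerance
        self.n_networks = n_networks
        self.hidden_units = hidden_units
        self.decay_grid = decay_grid
        self.transform = transform
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = pd.DataFrame(y)
        if self.transform == "log" and (y.to_numpy() <= 0).any():
            raise ValueError("log transform requires strictly positive "
                             "parameters")
        if self.transform not in ("log", "none"):
            raise ValueError("transform must be 'log' or 'none'")
        self.param_names_ = list(y.columns)
        self.y_ = y.to_numpy(dtype=float)
        mad = sps.median_abs_deviation(X, axis=0, scale=1.0)
        self.keep_ = mad > 0
        self.scale_ = np.where(self.keep_, mad, 1.0)
        self.X_scaled_ = X[:, self.keep_] / self.scale_[self.keep_]
        return self

    def adjust(self, observed) -> AdjustedPosterior:
        check_is_fitted(self, "X_scaled_")
        obs = np.asarray(observed, dtype=float).ravel()
        obs_scaled = obs[self.keep_] / self.scale_[self.keep_]
        idx, dist, _ = _accept(self.X_scaled_, obs_scaled, self.tolerance)
        w = epanechnikov_weights(dist)
        acc_X = self.X_scaled_[idx]
        acc_y = self.y_[idx]
        Y = np.log(acc_y) if self.transform == "log" else acc_y.copy()

        if len(idx) < 2 or np.all(dist == 0) or np.ptp(acc_X, axis=0).max() == 0:
            adj = Y
        else:
            # standardize inputs and targets for network fitting
            xm, xs = acc_X.mean(axis=0), acc_X.std(axis=0)
            xs[xs == 0] = 1.0
            ym, ys = Y.mean(axis=0), Y.std(axis=0)
            ys[ys == 0] = 1.0
            Xs = (acc_X - xm) / xs
            Ys = (Y - ym) / ys
            obs_s = (obs_scaled - xm) / xs
            root = np.random.default_rng(self.random_state)
            preds_obs = []
            preds_acc = []
            n_failed = 0
            for _ in range(self.n_networks):
                decay = root.choice(self.decay_grid)
                net = _Nnet(self.hidden_units, decay, root, self.max_iter)
                net.fit(Xs, Ys, w)
                if not net.converged_:
                    n_failed += 1
                preds_obs.append(net.predict(obs_s[None, :])[0])
                preds_acc.append(net.predict(Xs))
            if n_failed > self.n_networks / 2:
                raise RuntimeError(
                    f"{n_failed}/{self.n_networks} networks failed to "
                    "converge")
            m_obs = np.mean(preds_obs, axis=0) * ys + ym
            m_acc = np.mean(preds_acc, axis=0) * ys + ym
            adj = m_obs[None, :] + (Y - m_acc)

        adj_nat = np.exp(adj) if self.transform == "log" else adj
        accepted = pd.DataFrame(acc_y, columns=self.param_names_)
        adjusted = pd.DataFrame(adj_nat, columns=self.param_names_)
        post = AdjustedPosterior(param_names=self.param_names_,
                                 accepted=accepted, weights=w,
                                 adjusted=adjusted, tolerance=self.tolerance,
                                 transform=self.transform)
        rows = {}
        for name in self.param_names_:
            x = adjusted[name].to_numpy()
            logx = np.log(x) if self.transform == "log" else x
            mode = _weighted_mode(logx, w)
            q = weighted_quantile(x, [0.025, 0.5, 0.975], w)
            rows[name] = {
                "median": q[1],
                "mean": float(np.average(x, weights=w)),
                "mode": float(np.exp(mode)) if self.transform == "log"
                        else float(mode),
                "q2.5": q[0],
                "q97.5": q[2],
            }
        post.point_estimates = pd.DataFrame(rows)
        return post

    def predict(self, X):
        """Weighted posterior-median point estimates for each observation."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((len(X), len(self.param_names_)))
        for i, row in enumerate(X):
            post = self.adjust(row)
            out[i] = [post.point_estimates[n]["median"]
                      for n in self.param_names_]
        return out


def nn_regression_adjust(observed, table: ReferenceTable,
                         tolerance: float = 0.002, n_networks: int = 50,
                         transform: str = "log",
                         random_state: int = 0) -> AdjustedPosterior:
    """Neural-net regression adjustment on one model's reference table."""
    obs = observed.values if isinstance(observed, sumstats.SummaryVector) \
        else observed
    est = ABCPosteriorRegressor(tolerance=tolerance, n_networks=n_networks,
                                transform=transform,
                                random_state=random_state)
    est.fit(table.stats, table.params)
    return est.adjust(obs)
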