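"""Approximate Bayesian computation engine.

A *reference table* holds, per row, a model label, a prior draw of the
demographic parameters, and the five-statistic summary vector of one
simulated genotype panel (40 individuals x 10 loci by default).
Rejection ABC retains the ``ceil(tolerance x n_rows)`` rows closest to
the observed summary vector in Euclidean distance after scaling every
statistic by its median absolute deviation over the table.  Model
choice refines the accepted-label proportions with a weighted
multinomial logistic regression of the label on the scaled statistics
(Epanechnikov kernel weights in distance); parameter posteriors use the
Beaumont local-linear adjustment of the accepted draws on transformed
scales.  Cross-validation, prior-predictive goodness of fit and
posterior predictive simulation close the loop.

The two workhorses are scikit-learn style estimators:

* :class:`ABCModelClassifier` -- ``fit(X, y)`` on (statistics, model
  label), ``predict_proba`` giving model posterior probabilities;
* :class:`ABCLocalLinearRegressor` -- ``fit(X, theta)`` on (statistics,
  parameters), ``posterior(obs)`` giving raw and adjusted draws.

The module-level functions (``model_posterior``, ``param_posterior``,
``cv_model_choice``, ...) are thin wrappers over these, operating on a
:class:`ReferenceTable`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from . import _kernels, coalsim
from .coalsim import (BOTTLENECK, MODEL_KINDS, NON_BOTTLENECK, PARAM_NAMES,
                      DemographicParams, PriorSet)
from .sumstats import STAT_NAMES, SummaryVector

DEFAULT_TOLERANCE = 5e-4

#: parameters that are free under each model
MODEL_PARAMS = {
    BOTTLENECK: ("ne", "ne_hist", "ne_bot", "t_bot_start", "t_bot_end",
                 "mu", "gsm_par"),
    NON_BOTTLENECK: ("ne", "ne_hist", "t_hist", "mu", "gsm_par"),
}


# ---------------------------------------------------------------------------
# Reference table


@dataclass
class ReferenceTable:
    """Simulated (model, parameters, summary statistics) rows.

    ``df`` columns: ``model`` plus the eight parameter columns (NaN for
    parameters absent from a model) plus the five statistic columns.
    """

    df: pd.DataFrame
    n_ind: int
    n_loci: int
    priors: PriorSet
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        stats = self.df[list(STAT_NAMES)].to_numpy()
        if not np.all(np.isfinite(stats)):
            raise ValueError("non-finite summary statistics in table")

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def stats(self) -> np.ndarray:
        return self.df[list(STAT_NAMES)].to_numpy()

    def labels(self) -> np.ndarray:
        return self.df["model"].to_numpy()

    def model_counts(self) -> dict:
        return self.df["model"].value_counts().to_dict()

    def save(self, csv_path) -> None:
        self.df.to_csv(csv_path, index=False)
        meta = {
            "n_ind": self.n_ind, "n_loci": self.n_loci, "seed": self.seed,
            "priors": asdict(self.priors), "counts": self.model_counts(),
            **self.meta,
        }
        with open(str(csv_path) + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, csv_path) -> "ReferenceTable":
        df = pd.read_csv(csv_path)
        with open(str(csv_path) + ".meta.json") as fh:
            meta = json.load(fh)
        priors = PriorSet(**{
            k: coalsim.Prior(**v) for k, v in meta.pop("priors").items()
        })
        return cls(df, meta.pop("n_ind"), meta.pop("n_loci"), priors,
                   meta.pop("seed", None), meta)


def _draw_params_vectorized(model_kind, priors, n, rng):
    cols = {
        "ne": priors.ne.sample(rng, n),
        "ne_hist": priors.ne_hist.sample(rng, n),
        "mu": priors.mu.sample(rng, n),
        "gsm_par": priors.gsm_par.sample(rng, n),
        "ne_bot": np.full(n, np.nan),
        "t_bot_start": np.full(n, np.nan),
        "t_bot_end": np.full(n, np.nan),
        "t_hist": np.full(n, np.nan),
    }
    if model_kind == BOTTLENECK:
        cols["ne_bot"] = priors.ne_bot.sample(rng, n)
        ts = priors.t_bot_start.sample(rng, n)
        te = priors.t_bot_end.sample(rng, n)
        bad = te >= ts
        while bad.any():  # rejection keeps the marginals, drops inversions
            m = int(bad.sum())
            ts[bad] = priors.t_bot_start.sample(rng, m)
            te[bad] = priors.t_bot_end.sample(rng, m)
            bad = te >= ts
        cols["t_bot_start"], cols["t_bot_end"] = ts, te
    else:
        cols["t_hist"] = priors.t_hist.sample(rng, n)
    return pd.DataFrame({k: cols[k] for k in PARAM_NAMES})


def _epoch_arrays(model_kind, params: pd.DataFrame):
    """Per-row (bounds, sizes) matrices for the simulation kernel; the
    non-bottleneck model is padded to three epochs by duplicating the
    historical one."""
    n = len(params)
    if model_kind == BOTTLENECK:
        bounds = np.column_stack(
            [params["t_bot_end"], params["t_bot_start"]]
        ).astype(float)
        sizes = np.column_stack(
            [params["ne"], params["ne_bot"], params["ne_hist"]]
        ).astype(float)
    else:
        th = params["t_hist"].to_numpy(float)
        bounds = np.column_stack([th, th])
        sizes = np.column_stack(
            [params["ne"], params["ne_hist"], params["ne_hist"]]
        ).astype(float)
    return np.ascontiguousarray(bounds), np.ascontiguousarray(sizes)


def build_reference_table(
    priors: PriorSet | None = None,
    n_per_model: int = 100_000,
    n_ind: int = 40,
    n_loci: int = 10,
    rng: np.random.Generator | None = None,
    unbiased: bool = True,
    chunk_size: int = 20_000,
    models=MODEL_KINDS,
) -> ReferenceTable:
    """Simulate ``n_per_model`` prior draws per demographic model and
    summarise each simulated panel into the five-statistic vector.

    Work proceeds in chunks with per-chunk seeds derived from ``rng``,
    so a fixed seed gives a bit-identical table regardless of chunking.
    """
    if n_per_model < 1:
        raise ValueError("n_per_model must be >= 1")
    priors = priors or PriorSet()
    rng = np.random.default_rng(rng)
    frames = []
    for model_kind in models:
        params = _draw_params_vectorized(model_kind, priors, n_per_model, rng)
        bounds, sizes = _epoch_arrays(model_kind, params)
        mus = params["mu"].to_numpy(float)
        g = params["gsm_par"].to_numpy(float)
        p_single = np.zeros(n_per_model)
        pi_geom = 1.0 - g
        stat_rows = np.empty((n_per_model, 5))
        for lo in range(0, n_per_model, chunk_size):
            hi = min(lo + chunk_size, n_per_model)
            seed = int(rng.integers(1, 2**31 - 1))
            stat_rows[lo:hi] = _kernels.build_table_rows(
                2 * n_ind, n_loci, bounds[lo:hi], sizes[lo:hi], mus[lo:hi],
                p_single[lo:hi], pi_geom[lo:hi], unbiased, seed,
            )
        frame = params.copy()
        frame.insert(0, "model", model_kind)
        for i, s in enumerate(STAT_NAMES):
            frame[s] = stat_rows[:, i]
        frames.append(frame)
    df = pd.concat(frames, ignore_index=True)
    return ReferenceTable(df, n_ind, n_loci, priors,
                          meta={"unbiased": unbiased})


# ---------------------------------------------------------------------------
# Distance machinery


def mad_scale(X: np.ndarray) -> np.ndarray:
    """Per-column median absolute deviation (normal-consistent)."""
    return _sps.median_abs_deviation(X, axis=0, scale="normal")


def _as_stat_vector(obs) -> np.ndarray:
    if isinstance(obs, SummaryVector):
        return obs.values
    v = np.asarray(obs, dtype=float).ravel()
    if v.shape != (5,):
        raise ValueError("observed summary vector must have 5 entries")
    return v


def _n_accept(tolerance: float, n_rows: int) -> int:
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    return min(int(np.ceil(tolerance * n_rows)), n_rows)


@dataclass
class AcceptResult:
    """Rejection-ABC acceptance: positional row indices (closest first,
    ties broken by row index), their distances, and any statistics
    dropped for having zero spread."""

    indices: np.ndarray
    distances: np.ndarray
    n_rows: int
    tolerance: float
    dropped_stats: tuple = ()

    @property
    def n_accepted(self) -> int:
        return len(self.indices)


def _scaled(X, mad):
    keep = mad > 0
    return X[:, keep] / mad[keep], keep


def abc_reject(obs, table: ReferenceTable, tolerance: float = DEFAULT_TOLERANCE,
               _stats=None) -> AcceptResult:
    """Plain rejection step on a reference table (or raw stat matrix)."""
    X = table.stats() if _stats is None else _stats
    obs_v = _as_stat_vector(obs)
    mad = mad_scale(X)
    dropped = tuple(np.array(STAT_NAMES)[mad == 0])
    if dropped:
        warnings.warn(f"statistics with zero MAD dropped from distance: "
                      f"{dropped}")
    Xs, keep = _scaled(X, mad)
    d = np.sqrt(((Xs - obs_v[keep] / mad[keep]) ** 2).sum(axis=1))
    n_acc = _n_accept(tolerance, X.shape[0])
    order = np.argsort(d, kind="stable")[:n_acc]
    return AcceptResult(order, d[order], X.shape[0], tolerance, dropped)


def _epanechnikov(d: np.ndarray) -> np.ndarray:
    dmax = d.max()
    if dmax == 0:
        return np.ones_like(d)
    w = 1.0 - (d / dmax) ** 2
    if w.sum() <= 0:
        return np.ones_like(d)
    return w


# ---------------------------------------------------------------------------
# Model choice


@dataclass
class ABCModelChoice:
    """Posterior model probabilities for one observed summary vector."""

    probs: dict
    method: str
    tolerance: float
    n_accepted: dict
    rejection_probs: dict

    @property
    def p_bot(self) -> float:
        return float(self.probs.get(BOTTLENECK, 0.0))

    @property
    def preferred_model(self) -> str:
        return max(self.probs, key=self.probs.get)


class ABCModelClassifier(ClassifierMixin, BaseEstimator):
    """Rejection / multinomial-regression ABC model choice.

    Parameters
    ----------
    tolerance : float
        Proportion of reference rows retained around each query point.
    method : {"mnlogistic", "rejection"}
        "rejection" returns accepted-label proportions; "mnlogistic"
        refines them with a multinomial logistic regression of the
        label on the MAD-scaled statistics over the accepted rows,
        weighted by an Epanechnikov kernel in distance, evaluated at
        the query point (falls back to rejection when the regression is
        degenerate).
    C : float
        Inverse regularisation of the logistic fit (large = close to
        the unpenalised polychotomous regression).

    Attributes
    ----------
    classes_ : ndarray of model labels.
    scale_ : per-statistic MAD over the training table.
    keep_ : boolean mask of statistics with non-zero spread.
    """

    def __init__(self, tolerance: float = DEFAULT_TOLERANCE,
                 method: str = "mnlogistic", C: float = 1e6,
                 max_iter: int = 500):
        self.tolerance = tolerance
        self.method = method
        self.C = C
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if self.method not in ("mnlogistic", "rejection"):
            raise ValueError(f"unknown method {self.method!r}")
        self.classes_ = np.unique(y)
        self.scale_ = mad_scale(X)
        self.keep_ = self.scale_ > 0
        if not self.keep_.any():
            raise ValueError("all statistics have zero spread")
        self.Xs_ = X[:, self.keep_] / self.scale_[self.keep_]
        self.y_ = y
        return self

    def _proba_one(self, x: np.ndarray, exclude: int | None = None):
        """Posterior probabilities for one raw statistic vector;
        ``exclude`` removes one training row (leave-one-out CV)."""
        xs = x[self.keep_] / self.scale_[self.keep_]
        d = np.sqrt(((self.Xs_ - xs) ** 2).sum(axis=1))
        if exclude is not None:
            d[exclude] = np.inf
        n_rows = len(d) - (exclude is not None)
        n_acc = _n_accept(self.tolerance, n_rows)
        idx = np.argsort(d, kind="stable")[:n_acc]
        lab = self.y_[idx]
        rej = np.array([(lab == c).mean() for c in self.classes_])
        n_acc_per = {c: int((lab == c).sum()) for c in self.classes_}
        if self.method == "rejection" or np.unique(lab).size < 2:
            return rej, "rejection", n_acc_per, rej
        w = _epanechnikov(d[idx])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                lr = LogisticRegression(C=self.C, max_iter=self.max_iter)
                lr.fit(self.Xs_[idx], lab, sample_weight=w)
            p = lr.predict_proba(xs[None, :])[0]
            full = np.zeros(len(self.classes_))
            for c, pc in zip(lr.classes_, p):
                full[list(self.classes_).index(c)] = pc
            probs = np.clip(full, 0.0, 1.0)
            probs = probs / probs.sum()
            return probs, "mnlogistic", n_acc_per, rej
        except Exception:
            return rej, "rejection", n_acc_per, rej

    def predict_proba(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([self._proba_one(x)[0] for x in X])

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


def model_posterior(
    obs, table: ReferenceTable, tolerance: float = DEFAULT_TOLERANCE,
    method: str = "mnlogistic",
) -> ABCModelChoice:
    """Posterior model probabilities for an observed summary vector."""
    clf = ABCModelClassifier(tolerance=tolerance, method=method)
    clf.fit(table.stats(), table.labels())
    probs, used, n_acc, rej = clf._proba_one(_as_stat_vector(obs))
    return ABCModelChoice(
        dict(zip(clf.classes_, map(float, probs))), used, tolerance, n_acc,
        dict(zip(clf.classes_, map(float, rej))),
    )


# ---------------------------------------------------------------------------
# Parameter estimation


def _transform(x, spec):
    kind, a, b = spec
    if kind == "none":
        return x
    if kind == "log":
        return np.log(np.maximum(x, 1e-300))
    if kind == "logit":
        eps = 1e-9 * (b - a)
        z = np.clip((x - a) / (b - a), eps, 1 - eps)
        return np.log(z / (1 - z))
    raise ValueError(kind)


def _back_transform(t, spec):
    kind, a, b = spec
    if kind == "none":
        return t
    if kind == "log":
        return np.maximum(np.exp(t), a)
    if kind == "logit":
        z = 1.0 / (1.0 + np.exp(-t))
        return a + (b - a) * z
    raise ValueError(kind)


def default_transforms(priors: PriorSet) -> dict:
    """Per-parameter transform specs: log for the unbounded lognormal
    sizes, logit onto the prior support for uniformly bounded
    parameters (keeps every adjusted draw inside its prior support)."""
    tr = {}
    for name in PARAM_NAMES:
        prior: coalsim.Prior = getattr(priors, name)
        if prior.kind == "lognormal":
            tr[name] = ("log", 1.0, np.inf)
        else:
            tr[name] = ("logit", prior.a, prior.b)
    return tr


@dataclass
class PosteriorSample:
    """Raw and regression-adjusted parameter draws with kernel weights."""

    raw: pd.DataFrame
    adjusted: pd.DataFrame
    weights: np.ndarray
    model: str
    distances: np.ndarray
    ridge_fallback: bool = False

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("negative kernel weight")
        s = w.sum()
        self.weights = w / s if s > 0 else np.full_like(w, 1.0 / len(w))


def _weighted_quantile(x, w, q):
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    cw /= cw[-1]
    return float(np.interp(q, cw, x[order]))


class ABCLocalLinearRegressor(RegressorMixin, BaseEstimator):
    """Beaumont local-linear ABC parameter estimation.

    ``fit(X, theta)`` stores the (statistics, parameters) table;
    ``posterior(obs)`` performs rejection at ``tolerance``, transforms
    each parameter (log / logit per ``transforms``), regresses it on the
    MAD-scaled statistics over the accepted rows by Epanechnikov-
    weighted least squares, and returns raw plus adjusted draws
    (adjusted draw = fit at obs + residual, back-transformed).
    ``predict(obs)`` returns the weighted posterior medians.
    """

    def __init__(self, tolerance: float = DEFAULT_TOLERANCE,
                 transforms: dict | None = None, min_accepted: int = 50,
                 ridge: float = 1e-6):
        self.tolerance = tolerance
        self.transforms = transforms
        self.min_accepted = min_accepted
        self.ridge = ridge

    def fit(self, X, theta):
        X = np.asarray(X, dtype=float)
        theta = pd.DataFrame(theta)
        if len(X) != len(theta):
            raise ValueError("X and theta must have equal length")
        self.scale_ = mad_scale(X)
        self.keep_ = self.scale_ > 0
        self.Xs_ = X[:, self.keep_] / self.scale_[self.keep_]
        self.theta_ = theta.reset_index(drop=True)
        self.param_names_ = list(theta.columns)
        self.transforms_ = dict(self.transforms or {})
        for p in self.param_names_:
            self.transforms_.setdefault(p, ("none", -np.inf, np.inf))
        return self

    def posterior(self, obs, model: str = "") -> PosteriorSample:
        x = _as_stat_vector(obs)
        xs = x[self.keep_] / self.scale_[self.keep_]
        d = np.sqrt(((self.Xs_ - xs) ** 2).sum(axis=1))
        n_acc = _n_accept(self.tolerance, len(d))
        if n_acc < self.min_accepted:
            raise ValueError(
                f"only {n_acc} rows accepted; need >= {self.min_accepted} "
                "(raise tolerance or enlarge the table)"
            )
        idx = np.argsort(d, kind="stable")[:n_acc]
        w = _epanechnikov(d[idx])
        raw = self.theta_.iloc[idx].reset_index(drop=True)
        A = np.column_stack([np.ones(n_acc), self.Xs_[idx] - xs])
        sw = np.sqrt(w)
        ridge_used = False
        adjusted = {}
        for p in self.param_names_:
            spec = self.transforms_[p]
            t = _transform(raw[p].to_numpy(float), spec)
            Aw = A * sw[:, None]
            tw = t * sw
            beta, _, rank, _ = np.linalg.lstsq(Aw, tw, rcond=None)
            if rank < A.shape[1]:
                ridge_used = True
                G = Aw.T @ Aw + self.ridge * np.eye(A.shape[1])
                beta = np.linalg.solve(G, Aw.T @ tw)
            fitted = A @ beta
            adj_t = beta[0] + (t - fitted)  # fit at obs + residual
            adjusted[p] = _back_transform(adj_t, spec)
        return PosteriorSample(
            raw, pd.DataFrame(adjusted), w, model, d[idx],
            ridge_fallback=ridge_used,
        )

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((len(X), len(self.param_names_)))
        for i, x in enumerate(X):
            ps = self.posterior(x)
            out[i] = [
                _weighted_quantile(ps.adjusted[p].to_numpy(), ps.weights, 0.5)
                for p in self.param_names_
            ]
        return out


def param_posterior(
    obs, table: ReferenceTable, model: str,
    tolerance: float = DEFAULT_TOLERANCE, min_accepted: int = 50,
) -> PosteriorSample:
    """Local-linear posterior for the parameters of one model, using
    only that model's reference rows."""
    if model not in MODEL_KINDS:
        raise ValueError(f"unknown model {model!r}")
    sub = table.df[table.df["model"] == model]
    params = list(MODEL_PARAMS[model])
    reg = ABCLocalLinearRegressor(
        tolerance=tolerance,
        transforms=default_transforms(table.priors),
        min_accepted=min_accepted,
    )
    reg.fit(sub[list(STAT_NAMES)].to_numpy(), sub[params])
    return reg.posterior(obs, model=model)


def point_estimates(p: PosteriorSample) -> pd.DataFrame:
    """Per-parameter mode (argmax of a Silverman-bandwidth Gaussian
    KDE over the adjusted, weighted draws), weighted median and central
    95% credible interval."""
    if len(p.adjusted) < 100:
        raise ValueError("need >= 100 posterior draws for point estimates")
    rows = {}
    for name in p.adjusted.columns:
        x = p.adjusted[name].to_numpy(float)
        lo = _weighted_quantile(x, p.weights, 0.025)
        hi = _weighted_quantile(x, p.weights, 0.975)
        med = _weighted_quantile(x, p.weights, 0.5)
        if np.ptp(x) == 0:
            mode = float(x[0])
        else:
            kde = _sps.gaussian_kde(x, bw_method="silverman",
                                    weights=p.weights)
            grid = np.linspace(x.min(), x.max(), 512)
            mode = float(grid[np.argmax(kde(grid))])
        rows[name] = {"mode": mode, "median": med, "ci_low": lo,
                      "ci_high": hi}
    return pd.DataFrame(rows).T[["mode", "median", "ci_low", "ci_high"]]


# ---------------------------------------------------------------------------
# Cross-validation, goodness of fit, posterior prediction


@dataclass
class CVResult:
    """Leave-one-out cross-validation summary.

    For model choice, ``model_probs`` holds the mean posterior
    probability assigned to each model (columns) given the true
    generating model (rows), and ``classification_rate`` the fraction
    of pseudo-observations whose highest-probability model is the true
    one (the "correctly classified" rate of a confusion matrix).  For
    parameter estimation, ``prediction_error`` holds the cv4abc-style
    normalised error per parameter (0 = perfect, ~1 = prior-level
    information).
    """

    n_reps: int
    tolerance: float
    model_probs: pd.DataFrame | None = None
    classification_rate: pd.Series | None = None
    prediction_error: pd.Series | None = None


def cv_model_choice(
    table: ReferenceTable, n_reps: int = 100,
    tolerance: float = DEFAULT_TOLERANCE,
    rng: np.random.Generator | None = None, method: str = "mnlogistic",
) -> CVResult:
    """Leave-one-out model-choice cross-validation: random reference
    rows serve as pseudo-observations and are classified against all
    remaining rows; posterior probabilities are averaged per true
    model."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(rng)
    clf = ABCModelClassifier(tolerance=tolerance, method=method)
    X = table.stats()
    y = table.labels()
    clf.fit(X, y)
    means = {}
    rates = {}
    true_idx = {m: j for j, m in enumerate(clf.classes_)}
    for model in clf.classes_:
        rows = np.flatnonzero(y == model)
        chosen = rng.choice(rows, size=min(n_reps, rows.size), replace=False)
        acc = np.zeros(len(clf.classes_))
        n_correct = 0
        for i in chosen:
            probs, _, _, _ = clf._proba_one(X[i], exclude=int(i))
            acc += probs
            n_correct += int(np.argmax(probs) == true_idx[model])
        means[model] = acc / len(chosen)
        rates[model] = n_correct / len(chosen)
    probs_df = pd.DataFrame(means, index=clf.classes_).T
    probs_df.index.name = "true_model"
    return CVResult(n_reps, tolerance, model_probs=probs_df,
                    classification_rate=pd.Series(rates))


def cv_param_error(
    table: ReferenceTable, model: str, n_reps: int = 1000,
    tolerance: float = DEFAULT_TOLERANCE,
    rng: np.random.Generator | None = None,
) -> CVResult:
    """Rejection-ABC prediction error per parameter.

    For each of ``n_reps`` pseudo-observed rows of the model, the
    posterior median of the accepted draws (self excluded) is the point
    estimate; the error is sum((est - true)^2) / (n_reps * Var(true)),
    so 0 is perfect estimation and ~1 means the posterior carries no
    information beyond the prior."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(rng)
    sub = table.df[table.df["model"] == model].reset_index(drop=True)
    params = list(MODEL_PARAMS[model])
    X = sub[list(STAT_NAMES)].to_numpy()
    theta = sub[params].to_numpy(float)
    mad = mad_scale(X)
    Xs, keep = _scaled(X, mad)
    chosen = rng.choice(len(sub), size=min(n_reps, len(sub)), replace=False)
    n_acc = _n_accept(tolerance, len(sub) - 1)
    est = np.empty((len(chosen), len(params)))
    for r, i in enumerate(chosen):
        d = np.sqrt(((Xs - Xs[i]) ** 2).sum(axis=1))
        d[i] = np.inf
        idx = np.argsort(d, kind="stable")[:n_acc]
        est[r] = np.median(theta[idx], axis=0)
    true = theta[chosen]
    var = np.var(true, axis=0)
    if (var == 0).any():
        raise ValueError("a parameter has zero variance among the sampled "
                         "true values")
    err = ((est - true) ** 2).sum(axis=0) / (len(chosen) * var)
    return CVResult(len(chosen), tolerance,
                    prediction_error=pd.Series(err, index=params))


@dataclass
class GofResult:
    """Prior-predictive goodness of fit: observed median accepted
    distance against its null distribution over pseudo-observations."""

    statistic: float
    null: np.ndarray
    p_value: float


def goodness_of_fit(
    obs, table: ReferenceTable, model: str, n_null: int = 1000,
    tolerance: float = DEFAULT_TOLERANCE,
    rng: np.random.Generator | None = None,
) -> GofResult:
    """Hypothesis test of model fit: the statistic is the median
    distance between the observed and accepted summary statistics; the
    null distribution recomputes it for pseudo-observations drawn from
    the model's own simulations.  Large p = the model fits."""
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    rng = np.random.default_rng(rng)
    sub = table.df[table.df["model"] == model]
    X = sub[list(STAT_NAMES)].to_numpy()
    mad = mad_scale(X)
    Xs, keep = _scaled(X, mad)
    obs_v = _as_stat_vector(obs)
    n_acc = _n_accept(tolerance, len(X))

    def _stat(xs, exclude=None):
        d = np.sqrt(((Xs - xs) ** 2).sum(axis=1))
        if exclude is not None:
            d[exclude] = np.inf
        idx = np.argpartition(d, n_acc - 1)[:n_acc]
        return float(np.median(d[idx]))

    observed = _stat(obs_v[keep] / mad[keep])
    picks = rng.integers(0, len(X), size=n_null)
    null = np.array([_stat(Xs[i], exclude=i) for i in picks])
    p = float(np.mean(null >= observed))
    return GofResult(observed, null, p)


def _row_to_params(model: str, row: pd.Series) -> DemographicParams:
    """DemographicParams from a posterior draw, nudging the bottleneck
    times back into t_bot_end < t_bot_start if the independent
    regression adjustments inverted them."""
    r = dict(row)
    for name in PARAM_NAMES:
        r.setdefault(name, np.nan)
    if model == BOTTLENECK:
        te, ts = float(r["t_bot_end"]), float(r["t_bot_start"])
        te = max(te, 1.0)
        if te >= ts:
            te = max(1.0, min(te, ts - 1e-3))
            ts = max(ts, te + 1e-3)
        r["t_bot_end"], r["t_bot_start"] = te, ts
        r["ne_bot"] = max(float(r["ne_bot"]), 1.0)
    r["ne"] = max(float(r["ne"]), 1.0)
    r["ne_hist"] = max(float(r["ne_hist"]), 1.0)
    return DemographicParams.from_row(model, r)


def posterior_predictive(
    posterior: PosteriorSample, model: str, n_draws: int = 1000,
    n_ind: int = 40, n_loci: int = 10,
    rng: np.random.Generator | None = None, unbiased: bool = True,
) -> pd.DataFrame:
    """Simulate summary statistics under joint parameter draws from the
    adjusted posterior (rows resampled with their kernel weights, so
    cross-parameter dependence is preserved); one simulated panel per
    draw.  Returns an (n_draws, 5) statistic table for predictive
    checks against the observed vector."""
    if len(posterior.adjusted) == 0:
        raise ValueError("empty posterior")
    rng = np.random.default_rng(rng)
    picks = rng.choice(len(posterior.adjusted), size=n_draws, replace=True,
                       p=posterior.weights)
    out = np.empty((n_draws, 5))
    row5 = np.empty(5)
    for r, i in enumerate(picks):
        p = _row_to_params(model, posterior.adjusted.iloc[i])
        bounds, sizes = p.epochs()
        if bounds.shape[0] == 1:  # pad to the kernel's 3-epoch layout
            bounds = np.array([bounds[0], bounds[0]])
            sizes = np.array([sizes[0], sizes[1], sizes[1]])
        _kernels.seed_kernel_rng(int(rng.integers(1, 2**31 - 1)))
        _kernels.simulate_dataset_stats(
            2 * n_ind, n_loci, bounds, sizes, p.mu, 0.0, 1.0 - p.gsm_par,
            unbiased, row5,
        )
        out[r] = row5
    return pd.DataFrame(out, columns=list(STAT_NAMES))
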