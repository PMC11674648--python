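"""Bootstrap-based logistic NTCP model building and evaluation.

The model-building procedure draws B bootstrap resamples of the training
cohort and, within each resample, (1) screens candidate predictors by
univariable logistic regression (reject p > 0.2), (2) resolves
multicollinearity by repeatedly dropping the less outcome-correlated member
of the most Spearman-correlated pair until the variance inflation factor is
at most 5, and (3) runs backward elimination on a multivariable logistic
model using the change-in-deviance chi-squared test at 0.01. Predictors
selected in at least a quarter of the resamples form the final signature
(with a most-selected fallback, plus a forced clinical covariate); final
coefficients are medians over B fresh bootstrap fits, and the intercept is
refit on the full data by maximum likelihood with slopes frozen.

All logistic fits use an in-package Newton-Raphson solver: the procedure
needs tens of thousands of small fits per model, and a single vectorized
univariable pass over all candidates keeps a B=1000 run in seconds.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

SURGERY = "abdominal_surgery"
SCHEME_CODE = "scheme_code"


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class CohortData:
    """Per-patient predictors and outcome for one training or test cohort.

    ``features`` holds the (normalized) dosiomic features; ``covariates``
    holds clinical/binary columns (``abdominal_surgery`` and, for combined
    cohorts, ``scheme_code``); ``outcome`` is grade >=2 late rectal bleeding.
    """

    features: pd.DataFrame
    covariates: pd.DataFrame
    outcome: np.ndarray
    scheme: str | None = None
    representation: str | None = None

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=np.int8)
        if len(self.features) != len(self.outcome) or len(self.covariates) != len(
            self.outcome
        ):
            raise ValueError("features/covariates/outcome length mismatch")
        if self.features.isna().any().any() or self.covariates.isna().any().any():
            raise ValueError("missing values in cohort data")

    @property
    def n(self) -> int:
        return len(self.outcome)

    @property
    def n_events(self) -> int:
        return int(self.outcome.sum())

    @property
    def ids(self):
        return self.features.index

    def column(self, name: str) -> np.ndarray:
        if name in self.features.columns:
            return self.features[name].to_numpy(dtype=np.float64)
        return self.covariates[name].to_numpy(dtype=np.float64)

    def matrix(self, names: Sequence[str]) -> np.ndarray:
        cols = [self.column(n) for n in names]
        return np.column_stack(cols) if cols else np.empty((self.n, 0))

    def subset(self, idx: np.ndarray) -> "CohortData":
        return CohortData(
            self.features.iloc[idx],
            self.covariates.iloc[idx],
            self.outcome[idx],
            scheme=self.scheme,
            representation=self.representation,
        )


@dataclass
class SelectionFrequencies:
    """How often each candidate entered a bootstrap signature."""

    counts: dict[str, int]
    n_bootstrap: int

    def __post_init__(self) -> None:
        if any(c > self.n_bootstrap for c in self.counts.values()):
            raise ValueError("selection count exceeds number of bootstraps")

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts).sort_values(ascending=False)


@dataclass
class FinalModel:
    """A fitted NTCP model: signature, median coefficients, refit intercept."""

    signature: list[str]
    coefficients: dict[str, float]
    intercept: float
    median_p: dict[str, float]
    n_bootstrap: int
    seed: int
    representation: str | None = None
    training: str | None = None
    name: str | None = None

    @property
    def odds_ratios(self) -> dict[str, float]:
        return {k: float(np.exp(v)) for k, v in self.coefficients.items()}

    @property
    def baseline_odds(self) -> float:
        return float(np.exp(self.intercept))

    def linear_predictor(self, cohort: CohortData) -> np.ndarray:
        X = cohort.matrix(self.signature)
        beta = np.array([self.coefficients[s] for s in self.signature])
        return self.intercept + X @ beta

    def predict_proba(self, cohort: CohortData) -> np.ndarray:
        return expit(self.linear_predictor(cohort))

    def to_json(self, path=None) -> str:
        payload = {
            "name": self.name,
            "training": self.training,
            "representation": self.representation,
            "signature": self.signature,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "odds_ratios": self.odds_ratios,
            "baseline_odds": self.baseline_odds,
            "median_p": self.median_p,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "FinalModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            signature=list(d["signature"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            intercept=float(d["intercept"]),
            median_p={k: float(v) for k, v in d["median_p"].items()},
            n_bootstrap=int(d["n_bootstrap"]),
            seed=int(d["seed"]),
            representation=d.get("representation"),
            training=d.get("training"),
            name=d.get("name"),
        )


@dataclass
class PerformanceReport:
    auc: float
    cal_slope: float
    cal_intercept: float
    n: int
    n_events: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC outside [0, 1]")


# ---------------------------------------------------------------------------
# logistic regression core
# ---------------------------------------------------------------------------


@dataclass
class LogitFit:
    beta: np.ndarray  # intercept first
    se: np.ndarray
    deviance: float
    converged: bool


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * (y * np.log(p) + (1 - y) * np.log(1 - p)).sum())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray | float = 0.0,
    ridge: float = 0.0,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> LogitFit:
    """Newton-Raphson logistic regression with an intercept column prepended.

    ``offset`` enters the linear predictor with coefficient fixed at 1. On a
    singular or non-converging fit the Hessian is ridge-stabilized and the
    result flagged ``converged=False``.
    """
    n = len(y)
    Xd = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    k = Xd.shape[1]
    beta = np.zeros(k)
    ybar = float(np.mean(y))
    beta[0] = logit(min(max(ybar, 1e-6), 1 - 1e-6))
    converged = False
    H = np.eye(k)
    for _ in range(max_iter):
        eta = Xd @ beta + offset
        p = expit(eta)
        w = p * (1 - p)
        g = Xd.T @ (y - p) - ridge * beta
        H = (Xd * w[:, None]).T @ Xd + ridge * np.eye(k)
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            H = H + 1e-6 * np.eye(k)
            delta = np.linalg.solve(H, g)
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > 1e3 or not np.all(np.isfinite(beta)):
        converged = False
    p = expit(Xd @ beta + offset)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.inf)
    return LogitFit(beta=beta, se=se, deviance=_deviance(y, p), converged=converged)


def _wald_p(beta: float, se: float) -> float:
    if not np.isfinite(se) or se <= 0:
        return 1.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _univariable_batch(
    X: np.ndarray, y: np.ndarray, max_iter: int = 40, tol: float = 1e-9
):
    """Vectorized univariable logistic fits, one per column of X.

    Returns (slopes, p-values, converged, constant) arrays. Constant columns
    carry no information and get p = 1.
    """
    n, k = X.shape
    const = X.std(axis=0) == 0
    ybar = float(np.mean(y))
    b0 = np.full(k, logit(min(max(ybar, 1e-6), 1 - 1e-6)))
    b1 = np.zeros(k)
    conv = np.zeros(k, dtype=bool)
    yc = y[:, None]
    det = np.ones(k)
    h00 = h01 = h11 = np.ones(k)
    for _ in range(max_iter):
        eta = b0[None, :] + X * b1[None, :]
        p = expit(eta)
        w = p * (1 - p)
        r = yc - p
        g0 = r.sum(axis=0)
        g1 = (r * X).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * X).sum(axis=0)
        h11 = (w * X * X).sum(axis=0)
        det = h00 * h11 - h01 * h01
        bad = (det <= 1e-300) | const
        det_safe = np.where(bad, 1.0, det)
        d0 = np.where(bad, 0.0, (h11 * g0 - h01 * g1) / det_safe)
        d1 = np.where(bad, 0.0, (-h01 * g0 + h00 * g1) / det_safe)
        b0 = b0 + d0
        b1 = b1 + d1
        step = np.maximum(np.abs(d0), np.abs(d1))
        conv = step < tol
        if conv.all():
            break
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(np.where(det > 0, h00 / np.where(det > 0, det, 1.0), np.inf))
    z = np.where(se1 > 0, b1 / se1, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    # slopes this large on screened (normalized) predictors mean
    # (quasi-)separation; Wald p is then unusable (Hauck-Donner)
    diverged = (np.abs(b1) > 30.0) | ~np.isfinite(b1)
    conv = conv & ~diverged & ~const
    pvals = np.where(const, 1.0, pvals)
    pvals = np.where(diverged, 0.0, pvals)  # separation: treat as p < alpha
    return b1, pvals, conv, const


# ---------------------------------------------------------------------------
# step 1: univariable screening
# ---------------------------------------------------------------------------


def univariable_screen(
    cohort: CohortData,
    candidates: Sequence[str],
    alpha: float = 0.2,
) -> tuple[list[str], pd.DataFrame]:
    """Keep candidates with univariable logistic Wald p <= alpha.

    Non-converging (perfectly separating) candidates are retained with their
    p treated as below the threshold, and flagged. The returned frame also
    carries each survivor's association sign and Spearman correlation with
    the outcome for the collinearity step.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    names = list(candidates)
    if not names:
        return [], pd.DataFrame(
            columns=["slope", "p", "spearman_outcome", "flagged"]
        )
    X = cohort.matrix(names)
    y = cohort.outcome.astype(np.float64)
    slopes, pvals, conv, const = _univariable_batch(X, y)
    keep = (pvals <= alpha) & ~const
    rho = _spearman_to_outcome(X, y)
    info = pd.DataFrame(
        {
            "slope": slopes,
            "p": pvals,
            "spearman_outcome": rho,
            "flagged": ~conv & ~const,
        },
        index=names,
    )
    survivors = [n for n, k in zip(names, keep) if k]
    return survivors, info.loc[survivors]


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=0)


def _spearman_to_outcome(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    rx = _rank(X)
    ry = stats.rankdata(y)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, rx.T @ ry / np.where(denom > 0, denom, 1.0), 0.0)
    return rho


def _spearman_matrix(X: np.ndarray) -> np.ndarray:
    rx = _rank(X)
    sd = rx.std(axis=0)
    rx = rx - rx.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(rx, rowvar=False)
    c = np.atleast_2d(np.nan_to_num(c, nan=0.0))
    c[:, sd == 0] = 0.0
    c[sd == 0, :] = 0.0
    np.fill_diagonal(c, 1.0)
    return c


# ---------------------------------------------------------------------------
# step 2: collinearity resolution
# ---------------------------------------------------------------------------


def variance_inflation_factors(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 - R²_j) from regressing column j on the others.

    Computed as the diagonal of the inverse correlation matrix; degenerate
    (constant or perfectly collinear) columns get VIF = inf.
    """
    k = X.shape[1]
    if k < 2:
        return np.ones(k)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        out = np.full(k, np.inf)
        out[sd > 0] = variance_inflation_factors(X[:, sd > 0])
        return out
    R = np.corrcoef(X, rowvar=False)
    try:
        inv = np.linalg.inv(R)
        vif = np.diag(inv).copy()
    except np.linalg.LinAlgError:
        return np.full(k, np.inf)
    vif[vif < 0] = np.inf  # numerically singular
    return vif


def resolve_collinearity(
    cohort: CohortData,
    survivors: Sequence[str],
    vif_max: float = 5.0,
) -> list[str]:
    """Prune collinear predictors until max VIF <= vif_max.

    At each step the pair with the largest absolute Spearman correlation is
    found and its member with the smaller absolute Spearman correlation to
    the outcome is dropped. Correlations are invariant under column drops,
    so they are computed once; only the VIF submatrix inverse is updated.
    """
    names = list(survivors)
    if len(names) < 2:
        return names
    y = cohort.outcome.astype(np.float64)
    X = cohort.matrix(names)
    sd = X.std(axis=0)
    S = np.abs(_spearman_matrix(X))
    np.fill_diagonal(S, 0.0)
    rho_out = np.abs(_spearman_to_outcome(X, y))
    nondeg = sd > 0
    R = np.eye(len(names))
    if nondeg.sum() >= 2:
        Rsub = np.corrcoef(X[:, nondeg], rowvar=False)
        R[np.ix_(nondeg, nondeg)] = Rsub
    alive = list(range(len(names)))

    def max_vif(idx: list[int]) -> float:
        if len(idx) < 2:
            return 1.0
        if not all(nondeg[i] for i in idx):
            return np.inf
        sub = R[np.ix_(idx, idx)]
        try:
            vif = np.diag(np.linalg.inv(sub))
        except np.linalg.LinAlgError:
            return np.inf
        if np.any(vif < 0):
            return np.inf
        return float(vif.max())

    while len(alive) >= 2 and max_vif(alive) > vif_max:
        Ssub = S[np.ix_(alive, alive)]
        a_, b_ = np.unravel_index(np.argmax(Ssub), Ssub.shape)
        a, b = alive[a_], alive[b_]
        # drop the member least correlated with the outcome (ties: later name)
        if rho_out[a] < rho_out[b]:
            drop = a
        elif rho_out[b] < rho_out[a]:
            drop = b
        else:
            drop = a if names[a] > names[b] else b
        alive.remove(drop)
    return [names[i] for i in alive]


# ---------------------------------------------------------------------------
# step 3: backward elimination
# ---------------------------------------------------------------------------


def backward_eliminate(
    cohort: CohortData,
    candidates: Sequence[str],
    p_remove: float = 0.01,
) -> list[str]:
    """Backward elimination by the change-in-deviance chi-squared test.

    Starting from the full multivariable model, the predictor whose deletion
    gives the largest deviance-test p is removed while that p exceeds
    ``p_remove``. May return the empty list.
    """
    names = list(candidates)
    y = cohort.outcome.astype(np.float64)
    X = cohort.matrix(names)
    alive = list(range(len(names)))
    while alive:
        full = _stable_fit(X[:, alive], y)
        devs = np.empty(len(alive))
        for jj, j in enumerate(alive):
            reduced = [i for i in alive if i != j]
            red = _stable_fit(X[:, reduced], y)
            devs[jj] = max(red.deviance - full.deviance, 0.0)
        pvals = stats.chi2.sf(devs, 1)
        worst = int(np.argmax(pvals))
        if pvals[worst] > p_remove:
            alive.pop(worst)
        else:
            break
    return [names[i] for i in alive]


def _stable_fit(X: np.ndarray, y: np.ndarray) -> LogitFit:
    fit = fit_logistic(X, y)
    if not fit.converged:
        logger.debug("non-convergent fit; ridge-stabilized refit")
        fit = fit_logistic(X, y, ridge=1e-4)
    return fit


# ---------------------------------------------------------------------------
# bootstrap machinery
# ---------------------------------------------------------------------------


def _bootstrap_indices(
    y: np.ndarray, seed: int, stage: int, b: int
) -> np.ndarray:
    """Deterministic bootstrap resample with both outcome classes present.

    Substreams are keyed by (seed, stage, b, attempt) so changing B never
    reshuffles earlier samples; single-class resamples are redrawn.
    """
    n = len(y)
    for attempt in range(1000):
        rng = np.random.default_rng([seed, stage, b, attempt])
        idx = rng.integers(0, n, n)
        s = int(y[idx].sum())
        if 0 < s < n:
            if attempt:
                logger.debug("bootstrap %d: redrew %d single-class resamples", b, attempt)
            return idx
    raise RuntimeError("could not draw a two-class bootstrap resample")


def bootstrap_feature_selection(
    cohort: CohortData,
    candidates: Sequence[str],
    n_bootstrap: int = 1000,
    seed: int = 0,
    alpha: float = 0.2,
    vif_max: float = 5.0,
    p_remove: float = 0.01,
) -> SelectionFrequencies:
    """Run screen -> collinearity pruning -> backward elimination on each of
    ``n_bootstrap`` resamples and count signature memberships."""
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    counts = dict.fromkeys(candidates, 0)
    y = cohort.outcome
    for b in range(n_bootstrap):
        idx = _bootstrap_indices(y, seed, 1, b)
        sub = cohort.subset(idx)
        survivors, _ = univariable_screen(sub, candidates, alpha=alpha)
        pruned = resolve_collinearity(sub, survivors, vif_max=vif_max)
        signature = backward_eliminate(sub, pruned, p_remove=p_remove)
        for name in signature:
            counts[name] += 1
    return SelectionFrequencies(counts=counts, n_bootstrap=n_bootstrap)


def build_signature(
    freqs: SelectionFrequencies,
    cohort: CohortData,
    forced: Sequence[str] = (SURGERY,),
    vif_max: float = 5.0,
) -> list[str]:
    """Final signature: candidates selected in >= B/4 bootstraps plus forced
    covariates; a most-selected fallback guarantees at least one candidate.

    Ties on the fallback break by the smaller full-data univariable p, then
    lexicographic name. Candidate members with VIF > 5 on the full data are
    pruned with the same rule as in-bootstrap collinearity resolution.
    """
    B = freqs.n_bootstrap
    selected = [n for n, c in freqs.counts.items() if 4 * c >= B]
    if not selected:
        top = max(freqs.counts.values(), default=0)
        tied = [n for n, c in freqs.counts.items() if c == top]
        if top == 0:
            warnings.warn("all selection frequencies are zero; falling back")
        if len(tied) > 1:
            _, info = univariable_screen(cohort, tied, alpha=1 - 1e-9)
            pv = info["p"].reindex(tied).fillna(1.0)
            tied = sorted(tied, key=lambda n: (pv[n], n))
        selected = [tied[0]] if tied else []
    selected = sorted(selected, key=lambda n: (-freqs.counts[n], n))
    selected = resolve_collinearity(cohort, selected, vif_max=vif_max)
    return selected + [f for f in forced if f not in selected]


def fit_final_coefficients(
    cohort: CohortData,
    signature: Sequence[str],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Median coefficients and median Wald p over B bootstrap refits of the
    signature model."""
    if not signature:
        raise ValueError("empty signature")
    names = list(signature)
    y = cohort.outcome
    betas = np.empty((n_bootstrap, len(names)))
    pvals = np.empty((n_bootstrap, len(names)))
    for b in range(n_bootstrap):
        idx = _bootstrap_indices(y, seed, 2, b)
        sub = cohort.subset(idx)
        fit = _stable_fit(sub.matrix(names), sub.outcome.astype(np.float64))
        betas[b] = fit.beta[1:]
        pvals[b] = [_wald_p(bb, ss) for bb, ss in zip(fit.beta[1:], fit.se[1:])]
    med_b = np.median(betas, axis=0)
    med_p = np.median(pvals, axis=0)
    return dict(zip(names, map(float, med_b))), dict(zip(names, map(float, med_p)))


def refit_intercept(cohort: CohortData, coefficients: Mapping[str, float]) -> float:
    """MLE intercept with all slopes frozen.

    The one-dimensional negative log-likelihood is convex in the intercept;
    its score equation says the mean predicted probability equals the
    observed event rate, which is how the root is solved.
    """
    y = cohort.outcome.astype(np.float64)
    names = list(coefficients)
    eta = (
        cohort.matrix(names) @ np.array([coefficients[n] for n in names])
        if names
        else np.zeros(cohort.n)
    )
    return _offset_mle_intercept(eta, y)


def _offset_mle_intercept(eta: np.ndarray, y: np.ndarray) -> float:
    """MLE intercept of a logistic model whose linear predictor ``eta``
    enters as an offset with coefficient 1.

    The NLL is convex in the intercept and its score equation is
    mean(expit(b0 + eta)) = mean(y); the root is bracketed and solved
    directly, which stays stable even when many probabilities saturate."""
    ybar = float(np.mean(y))
    if ybar in (0.0, 1.0):
        raise ValueError("outcome has a single class; intercept is unbounded")

    def score(b0: float) -> float:
        return float(np.mean(expit(b0 + eta)) - ybar)

    lo, hi = -40.0, 40.0
    while score(lo) > 0 and lo > -500:
        lo *= 2
    while score(hi) < 0 and hi < 500:
        hi *= 2
    return float(brentq(score, lo, hi, xtol=1e-12))


def build_final_model(
    cohort: CohortData,
    candidates: Sequence[str],
    n_bootstrap: int = 1000,
    seed: int = 0,
    forced: Sequence[str] = (SURGERY,),
    name: str | None = None,
) -> tuple[FinalModel, SelectionFrequencies]:
    """Full procedure: bootstrap selection, signature, median fit, intercept."""
    freqs = bootstrap_feature_selection(
        cohort, candidates, n_bootstrap=n_bootstrap, seed=seed
    )
    signature = build_signature(freqs, cohort, forced=forced)
    coefs, med_p = fit_final_coefficients(
        cohort, signature, n_bootstrap=n_bootstrap, seed=seed
    )
    intercept = refit_intercept(cohort, coefs)
    model = FinalModel(
        signature=list(signature),
        coefficients=coefs,
        intercept=intercept,
        median_p=med_p,
        n_bootstrap=n_bootstrap,
        seed=seed,
        representation=cohort.representation,
        training=cohort.scheme,
        name=name,
    )
    return model, freqs


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def auc_score(y: np.ndarray, score: np.ndarray) -> float:
    """Rank-based AUC: probability a random event outranks a random
    non-event, ties counted half (Mann-Whitney formulation)."""
    y = np.asarray(y)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both outcome classes")
    ranks = stats.rankdata(score)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def evaluate(model: FinalModel, cohort: CohortData) -> PerformanceReport:
    """Discrimination (AUC) and calibration of a model on a cohort.

    The calibration slope is the slope of a logistic regression of the
    outcome on the model's linear predictor; the calibration intercept
    (calibration-in-the-large) is refit with the linear predictor entering
    as an offset with coefficient fixed at 1. Ideal values: 1 and 0.
    """
    if model.representation is not None and cohort.representation is not None:
        if model.representation != cohort.representation:
            raise ValueError(
                f"representation mismatch: model {model.representation!r} "
                f"vs cohort {cohort.representation!r}"
            )
    eta = model.linear_predictor(cohort)
    y = cohort.outcome.astype(np.float64)
    if float(np.std(eta)) == 0.0:
        warnings.warn("degenerate constant linear predictor; AUC=0.5, slope=0")
        auc = 0.5
        slope = 0.0
    else:
        auc = auc_score(cohort.outcome, eta)
        slope = float(_stable_fit(eta[:, None], y).beta[1])
    cal_intercept = _offset_mle_intercept(eta, y)
    return PerformanceReport(
        auc=auc,
        cal_slope=slope,
        cal_intercept=cal_intercept,
        n=cohort.n,
        n_events=cohort.n_events,
    )


def cross_evaluate(
    models: Mapping[str, FinalModel],
    evaluations: Mapping[str, Sequence[tuple[str, CohortData, str]]],
) -> pd.DataFrame:
    """Evaluate each model on its planned cohorts.

    ``evaluations[model_name]`` is a list of (cohort_label, cohort, kind)
    where kind is "apparent" for a model's own training data and "test"
    otherwise. Returns one row per (model, cohort).
    """
    rows = []
    for mname, plan in evaluations.items():
        model = models[mname]
        for label, cohort, kind in plan:
            rep = evaluate(model, cohort)
            rows.append(
                {
                    "model": mname,
                    "data": label,
                    "kind": kind,
                    "auc": rep.auc,
                    "cal_slope": rep.cal_slope,
                    "cal_intercept": rep.cal_intercept,
                    "n": rep.n,
                    "n_events": rep.n_events,
                }
            )
    return pd.DataFrame(rows)
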