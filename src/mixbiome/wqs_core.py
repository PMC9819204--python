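"""Weighted quantile sum regression with random subsets (WQS_RS).

The mixture index is WQS_j = sum_i w_i q_ij: a weighted sum of the
zero-anchored quantile scores q, with the weights w on the simplex
(w_i >= 0, sum w_i = 1).  Because the number of taxa typically exceeds the
number of samples, weights are estimated on many random subsets of m taxa:
for each subset the GLM

    g(mu) = alpha + beta1 * (sum_i w_i q_i) + delta' Z

is maximized over (alpha, beta1, delta, w) with w on the m-simplex and,
optionally, the sign of beta1 constrained.  Per-taxon weights are then
combined across subsets by a signal-weighted average (signal = t^2,
exp|t| or |t| of each subset's beta1), renormalized to the full simplex,
and the resulting index is tested in an ordinary, unconstrained GLM on a
held-out validation partition.

Implementation notes
--------------------
The product parameterization v_i = beta1 * w_i maps the constrained set
{beta1 * w : w on the simplex, beta1 >= 0} onto the nonnegative orthant
{v >= 0} (and the negative direction onto v <= 0), which turns each
subset fit into an ordinary sign-constrained GLM — a concave problem with
a unique optimum, solved by bound-constrained L-BFGS with an analytic
gradient.  An unconstrained-direction fit solves both orthants and keeps
the better one.  Back on the original scale, beta1 = sum(v) and
w = v / sum(v).  The Wald t of beta1 comes from the observed information
of the GLM (intercept, index, covariates) evaluated at the optimum with
the weights held at their estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import statsmodels.api as sm
from scipy.special import expit

from .ranking import RankedMatrix
from .tables_io import AbundanceTable

__all__ = [
    "WQSConfig",
    "SubsetFit",
    "GlmEstimates",
    "WQSResult",
    "draw_random_subsets",
    "estimate_subset_weights",
    "signal_value",
    "signal_average",
    "build_index",
    "validate_index",
    "determine_direction",
    "run_wqs_rs",
]

SIGNAL_KINDS = ("t2", "exp_t", "abs_t")
DIRECTIONS = ("positive", "negative", "unconstrained")
FAMILIES = ("binomial", "gaussian")

_EXP_T_CLIP = 30.0  # exp(|t|) is unbounded; |t| is clipped here before exponentiation


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class WQSConfig:
    """Settings for one WQS_RS pass.

    m: subset size; B: number of random subsets; signal: subset-averaging
    signal function (t2 is the customary default); direction: sign
    constraint on the index coefficient ("auto" resolves it by majority
    sign of an unconstrained pass); train_fraction: share of samples used
    to estimate weights (0.40 train / 0.60 validation).
    """

    m: int = 30
    B: int = 1000
    signal: str = "t2"
    direction: str = "auto"
    family: str = "binomial"
    train_fraction: float = 0.40
    restarts: int = 1  # the orthant-parameterized fit is concave; 1 start suffices
    rank_within_training: bool = False
    reference_levels: dict = field(default_factory=dict)

    def validated(self) -> "WQSConfig":
        if self.signal not in SIGNAL_KINDS:
            raise ValueError(f"unknown signal {self.signal!r}")
        if self.direction not in DIRECTIONS + ("auto",):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.m < 1 or self.B < 1:
            raise ValueError("m and B must be positive")
        return self


@dataclass
class SubsetFit:
    """One random subset's constrained fit: simplex weights, beta1, Wald t."""

    taxon_indices: np.ndarray
    weights: np.ndarray
    beta1: float
    t_stat: float
    converged: bool
    loglik: float = np.nan


@dataclass
class GlmEstimates:
    """Unconstrained validation GLM estimates for the WQS index."""

    alpha: float
    beta1: float
    beta1_se: float
    beta1_ci: tuple
    covariate_coefs: pd.Series
    family: str
    odds_ratio: float | None = None
    odds_ratio_ci: tuple | None = None
    warnings: list = field(default_factory=list)


@dataclass
class WQSResult:
    """One full WQS_RS pass: final weights, split, validation GLM."""

    final_weights: pd.Series
    train_ids: list
    validation_ids: list
    direction: str
    signal: str
    family: str
    index_values: pd.Series
    glm_estimates: GlmEstimates
    n_subsets: int
    n_converged: int
    direction_scan: dict | None = None  # {"positive": k, "negative": j} from auto pass
    warnings: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# subset machinery
# ---------------------------------------------------------------------------

def draw_random_subsets(p: int, m: int, B: int, seed) -> list[np.ndarray]:
    """Draw B subsets of m distinct taxon indices, uniformly without replacement."""
    if m > p:
        raise ValueError(f"subset size m={m} exceeds number of taxa p={p}")
    if m < 1 or B < 1:
        raise ValueError("m and B must be positive")
    rng = np.random.default_rng(seed)
    return [rng.choice(p, size=m, replace=False) for _ in range(B)]


def _check_design(Z: np.ndarray | None, names=None):
    """Raise if [1, Z] is rank deficient, naming the collinear columns."""
    if Z is None or Z.shape[1] == 0:
        return
    X = np.column_stack([np.ones(Z.shape[0]), Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        names = list(names) if names is not None else [f"z{i}" for i in range(Z.shape[1])]
        raise ValueError(f"rank-deficient covariate design; columns: {names}")


def _nll_grad_factory(Q, y, Z, family):
    """Return f(theta) -> (nll, grad) for the orthant-parameterized likelihood.

    theta = [alpha, delta (k), v (m)] with eta = alpha + Q v + Z delta;
    the direction constraint is imposed through sign bounds on v.
    """
    n, m = Q.shape
    k = 0 if Z is None else Z.shape[1]

    def fun(theta):
        a = theta[0]
        d = theta[1 : 1 + k]
        v = theta[1 + k :]
        eta = a + Q @ v
        if k:
            eta = eta + Z @ d
        if family == "binomial":
            nll = np.logaddexp(0.0, eta).sum() - y @ eta
            r = expit(eta) - y  # dnll/deta
        else:
            res = y - eta
            rss = res @ res
            nll = 0.5 * n * np.log(rss)
            r = -(n / rss) * res
        grad = np.empty_like(theta)
        grad[0] = r.sum()
        if k:
            grad[1 : 1 + k] = Z.T @ r
        grad[1 + k :] = Q.T @ r
        return nll, grad

    return fun


def _loglik_from_nll(nll: float, n: int, family: str) -> float:
    """Convert the optimized objective to a proper maximum log-likelihood."""
    if family == "binomial":
        return -nll
    # gaussian objective is 0.5*n*log(RSS); llf = -n/2*(log(2*pi*RSS/n)+1)
    rss = np.exp(2.0 * nll / n)
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


def _wald_t(Q, y, Z, w, beta1, alpha, delta, family):
    """Wald t of beta1 from the observed information at the optimum (w fixed)."""
    n = Q.shape[0]
    u = Q @ w
    cols = [np.ones(n), u]
    if Z is not None and Z.shape[1]:
        cols.append(Z)
    X = np.column_stack(cols)
    eta = alpha + beta1 * u
    if Z is not None and Z.shape[1]:
        eta = eta + Z @ delta
    try:
        if family == "binomial":
            p = expit(eta)
            W = p * (1.0 - p)
            info = X.T @ (X * W[:, None])
            cov = np.linalg.inv(info)
        else:
            res = y - eta
            dof = max(n - X.shape[1], 1)
            sigma2 = (res @ res) / dof
            cov = sigma2 * np.linalg.inv(X.T @ X)
    except np.linalg.LinAlgError:
        return np.nan
    var = cov[1, 1]
    if not np.isfinite(var) or var <= 0:
        return np.nan
    return beta1 / np.sqrt(var)


_LBFGS_OPTS = {"maxiter": 500, "ftol": 1e-10, "gtol": 1e-8}


def _solve_orthant(fun, n_free, m, sign, restarts, rng):
    """Maximize the likelihood over one orthant of v; returns the best result."""
    if sign > 0:
        vb = [(0.0, None)] * m
    else:
        vb = [(None, 0.0)] * m
    bounds = [(None, None)] * n_free + vb
    best = None
    for r in range(max(1, restarts)):
        theta0 = np.zeros(n_free + m)
        if r > 0:  # concave problem: extra starts only guard the line search
            theta0[n_free:] = sign * rng.exponential(0.1, size=m)
        res = scipy.optimize.minimize(
            fun, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
            options=_LBFGS_OPTS,
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def estimate_subset_weights(
    scores,
    outcome,
    covariates=None,
    family: str = "binomial",
    direction: str = "unconstrained",
    restarts: int = 1,
    seed=0,
    taxon_indices=None,
    covariate_names=None,
) -> SubsetFit:
    """Fit one random subset's simplex weights and index coefficient.

    ``scores`` is the training-sample score matrix restricted to the subset
    (n x m); ``outcome`` the training outcome; ``covariates`` an optional
    n x k design (already encoded).  Maximizes the GLM likelihood over
    (alpha, beta1, delta, w) with w on the simplex and sign(beta1)
    constrained per ``direction`` — solved exactly in the product
    parameterization v = beta1 * w (see module notes).  ``direction
    = "unconstrained"`` fits both orthants and keeps the better one.
    """
    Q = np.asarray(getattr(scores, "values", scores), dtype=float)
    if Q.ndim == 1:
        Q = Q[:, None]
    y = np.asarray(outcome, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("outcome is constant")
    Z = None
    if covariates is not None:
        Z = np.asarray(getattr(covariates, "values", covariates), dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        _check_design(Z, covariate_names)
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")

    n, m = Q.shape
    k = 0 if Z is None else Z.shape[1]
    fun = _nll_grad_factory(Q, y, Z, family)
    rng = np.random.default_rng(seed)
    if direction == "positive":
        best = _solve_orthant(fun, 1 + k, m, +1, restarts, rng)
    elif direction == "negative":
        best = _solve_orthant(fun, 1 + k, m, -1, restarts, rng)
    else:
        pos = _solve_orthant(fun, 1 + k, m, +1, restarts, rng)
        neg = _solve_orthant(fun, 1 + k, m, -1, restarts, rng)
        best = pos if pos.fun <= neg.fun else neg

    theta = best.x
    alpha = float(theta[0])
    delta = theta[1 : 1 + k]
    v = theta[1 + k :]
    beta1 = float(v.sum())
    if beta1 != 0.0:
        w = v / v.sum()
    else:  # boundary optimum: the index drops out, weights are undetermined
        w = np.full(m, 1.0 / m)
    t = _wald_t(Q, y, Z, w, beta1, alpha, delta, family) if beta1 != 0.0 else 0.0
    converged = bool(best.success) and np.isfinite(t)
    idx = (
        np.asarray(taxon_indices, dtype=int)
        if taxon_indices is not None
        else np.arange(m)
    )
    return SubsetFit(
        taxon_indices=idx,
        weights=np.asarray(w, dtype=float),
        beta1=beta1,
        t_stat=float(t) if np.isfinite(t) else np.nan,
        converged=converged,
        loglik=_loglik_from_nll(best.fun, n, family),
    )


# ---------------------------------------------------------------------------
# signal functions and averaging
# ---------------------------------------------------------------------------

def signal_value(t: float, kind: str = "t2") -> float:
    """Nonnegative emphasis given to a subset with index t statistic ``t``."""
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if kind == "t2":
        return float(t * t)
    if kind == "exp_t":
        return float(np.exp(min(abs(t), _EXP_T_CLIP)))
    if kind == "abs_t":
        return float(abs(t))
    raise ValueError(f"unknown signal kind {kind!r}")


def signal_average(fits: list[SubsetFit], p: int, kind: str = "t2") -> np.ndarray:
    """Signal-weighted per-taxon mean of subset weights, renormalized to the simplex.

    For each taxon, averages its weight over the converged subsets that
    contain it, using the signal value as the averaging weight; the full
    p-vector is then renormalized to sum to 1.  Taxa in no converged subset
    get weight 0 (with a warning).
    """
    good = [f for f in fits if f.converged]
    if not good:
        raise ValueError("no converged subset fits to average")
    num = np.zeros(p)
    den = np.zeros(p)
    raw_num = np.zeros(p)  # unweighted fallback when all signals vanish
    raw_den = np.zeros(p)
    for f in good:
        s = signal_value(f.t_stat, kind)
        num[f.taxon_indices] += s * f.weights
        den[f.taxon_indices] += s
        raw_num[f.taxon_indices] += f.weights
        raw_den[f.taxon_indices] += 1.0
    covered = raw_den > 0
    if not covered.all():
        warnings.warn(
            f"{int((~covered).sum())} taxa appear in no converged subset; "
            "their final weight is 0"
        )
    mean = np.zeros(p)
    use_signal = den > 0
    mean[use_signal] = num[use_signal] / den[use_signal]
    fallback = covered & ~use_signal
    mean[fallback] = raw_num[fallback] / raw_den[fallback]
    total = mean.sum()
    if total <= 0:
        raise ValueError("signal-averaged weights sum to 0")
    return mean / total


def build_index(scores, weights) -> np.ndarray:
    """WQS index: per-sample dot product of quantile scores with simplex weights."""
    S = np.asarray(getattr(scores, "values", scores), dtype=float)
    w = np.asarray(weights, dtype=float)
    if S.shape[1] != w.shape[0]:
        raise ValueError(
            f"dimension mismatch: scores have {S.shape[1]} taxa, weights {w.shape[0]}"
        )
    return S @ w


# ---------------------------------------------------------------------------
# validation GLM
# ---------------------------------------------------------------------------

def _ridge_logit(X, y, lam=1e-4):
    """Ridge-penalized IRLS fallback for separated logistic fits."""
    n, q = X.shape
    beta = np.zeros(q)
    for _ in range(100):
        eta = X @ beta
        p = expit(eta)
        W = np.clip(p * (1 - p), 1e-10, None)
        H = X.T @ (X * W[:, None]) + lam * np.eye(q)
        g = X.T @ (y - p) - lam * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    p = expit(eta)
    W = np.clip(p * (1 - p), 1e-10, None)
    info = X.T @ (X * W[:, None])
    Hinv = np.linalg.inv(info + lam * np.eye(q))
    cov = Hinv @ info @ Hinv
    return beta, np.sqrt(np.diag(cov))


def validate_index(
    index, outcome, covariates=None, family: str = "binomial", covariate_names=None
) -> GlmEstimates:
    """Ordinary (unconstrained) GLM of the outcome on the WQS index + covariates."""
    u = np.asarray(index, dtype=float)
    y = np.asarray(outcome, dtype=float)
    cols = {"const": np.ones(len(u)), "wqs": u}
    if covariates is not None:
        Z = np.asarray(getattr(covariates, "values", covariates), dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        names = (
            list(covariate_names)
            if covariate_names is not None
            else (
                list(covariates.columns)
                if isinstance(covariates, pd.DataFrame)
                else [f"z{i}" for i in range(Z.shape[1])]
            )
        )
        for j, nm in enumerate(names):
            cols[nm] = Z[:, j]
    X = pd.DataFrame(cols)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(
            f"rank-deficient validation design; columns: {list(X.columns)}"
        )
    fam = sm.families.Binomial() if family == "binomial" else sm.families.Gaussian()
    msgs = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=fam).fit()
        params, bse = fit.params.to_numpy(), fit.bse.to_numpy()
        if not np.all(np.isfinite(bse)) or np.any(np.abs(params) > 1e3):
            raise ValueError("separation suspected")
    except Exception:
        if family == "binomial":
            params, bse = _ridge_logit(X.to_numpy(), y)
            msgs.append("separation in binomial fit; ridge-penalized fallback used")
        else:
            raise
    beta1, se1 = float(params[1]), float(bse[1])
    ci = (beta1 - 1.96 * se1, beta1 + 1.96 * se1)
    est = GlmEstimates(
        alpha=float(params[0]),
        beta1=beta1,
        beta1_se=se1,
        beta1_ci=ci,
        covariate_coefs=pd.Series(params[2:], index=list(X.columns)[2:]),
        family=family,
        warnings=msgs,
    )
    if family == "binomial":
        est.odds_ratio = float(np.exp(beta1))
        est.odds_ratio_ci = (float(np.exp(ci[0])), float(np.exp(ci[1])))
    return est


def determine_direction(fits_unconstrained: list[SubsetFit]) -> tuple[str, dict]:
    """Majority sign of beta1 across converged unconstrained subset fits.

    Returns the direction and the count split.  An exact tie defaults to
    "negative" with a warning.
    """
    good = [f for f in fits_unconstrained if f.converged]
    if not good:
        raise ValueError("no converged unconstrained fits")
    n_neg = sum(1 for f in good if f.beta1 < 0)
    n_pos = len(good) - n_neg
    counts = {"positive": n_pos, "negative": n_neg}
    if n_pos == n_neg:
        warnings.warn("exact tie in direction scan; defaulting to negative")
        return "negative", counts
    return ("negative" if n_neg > n_pos else "positive"), counts


# ---------------------------------------------------------------------------
# covariate encoding and the full WQS_RS pass
# ---------------------------------------------------------------------------

def encode_covariates(
    metadata: pd.DataFrame, covariates, reference_levels: dict | None = None
) -> pd.DataFrame | None:
    """Build a numeric design from metadata columns.

    Categorical columns are dummy-encoded against an explicit reference
    level (``reference_levels[col]``); without a declaration the first
    level in sorted order is the reference.
    """
    if covariates is None:
        return None
    if isinstance(covariates, (pd.DataFrame, np.ndarray)):
        return pd.DataFrame(covariates)
    reference_levels = reference_levels or {}
    out = {}
    for col in covariates:
        s = metadata[col]
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2:
            out[col] = s.astype(float)
        elif pd.api.types.is_numeric_dtype(s) and set(s.unique()) <= {0, 1}:
            out[col] = s.astype(float)
        else:
            levels = sorted(s.astype(str).unique())
            ref = str(reference_levels.get(col, levels[0]))
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not found in {col!r}")
            for lev in levels:
                if lev == ref:
                    continue
                out[f"{col}[{lev}]"] = (s.astype(str) == lev).astype(float)
    return pd.DataFrame(out, index=metadata.index)


def _resolve_outcome(outcome, metadata: pd.DataFrame) -> pd.Series:
    if isinstance(outcome, str):
        return metadata[outcome].astype(float)
    return pd.Series(np.asarray(outcome, dtype=float), index=metadata.index)


def run_wqs_rs(
    table: AbundanceTable,
    ranked: RankedMatrix,
    outcome,
    covariates,
    config: WQSConfig,
    seed,
    split=None,
) -> WQSResult:
    """One full WQS_RS pass: split, subset fits, signal average, validation GLM.

    ``outcome`` may be a metadata column name or a vector; ``covariates`` a
    list of metadata column names (encoded via ``encode_covariates``), a
    design matrix, or None.  ``split`` can supply a precomputed
    (train_ids, validation_ids) pair; otherwise an outcome-stratified split
    at ``config.train_fraction`` is drawn.
    """
    config = config.validated()
    y_all = _resolve_outcome(outcome, table.metadata)
    Z_all = encode_covariates(table.metadata, covariates, config.reference_levels)
    sample_ids = list(ranked.scores.index)
    p = ranked.scores.shape[1]
    if config.m > p:
        raise ValueError(f"subset size m={config.m} exceeds p={p}")

    # seed may be an int or a counter-scheme list (master seed + repetition)
    entropy = [int(s) for s in seed] if isinstance(seed, (list, tuple)) else [int(seed)]
    part_seed, subset_seed = np.random.SeedSequence(entropy + [0]).spawn(2)

    if split is None:
        from .holdouts import stratified_partition  # lazy: avoids import cycle

        strat_cols = None
        if isinstance(covariates, (list, tuple)):
            cats = [
                c
                for c in covariates
                if not pd.api.types.is_numeric_dtype(table.metadata[c])
                or table.metadata[c].nunique() <= 2
            ]
            strat_cols = table.metadata[cats] if cats else None
        train_ids, valid_ids = stratified_partition(
            y_all, strat_cols, config.train_fraction, part_seed
        )
    else:
        train_ids, valid_ids = list(split[0]), list(split[1])

    if config.rank_within_training:
        rel = table.data
        scores = np.empty(rel.shape, dtype=float)
        for j, tx in enumerate(rel.columns):
            ref = rel.loc[train_ids, tx].to_numpy()
            scores[:, j] = zero_anchored_rank_with_reference(
                rel[tx].to_numpy(), ref, ranked.levels, ranked.split
            )
        score_df = pd.DataFrame(scores, index=rel.index, columns=rel.columns)
    else:
        score_df = ranked.scores.astype(float)

    S_train = score_df.loc[train_ids].to_numpy(dtype=float)
    y_train = y_all.loc[train_ids].to_numpy(dtype=float)
    Z_train = Z_all.loc[train_ids] if Z_all is not None else None
    cov_names = list(Z_all.columns) if Z_all is not None else None
    if Z_train is not None:
        _check_design(Z_train.to_numpy(dtype=float), cov_names)

    subsets = draw_random_subsets(p, config.m, config.B, subset_seed)
    fit_seeds = np.random.SeedSequence(entropy + [1]).spawn(config.B)

    def _fit_all(direction):
        fits = []
        for b, idx in enumerate(subsets):
            fits.append(
                estimate_subset_weights(
                    S_train[:, idx],
                    y_train,
                    Z_train,
                    family=config.family,
                    direction=direction,
                    restarts=config.restarts,
                    seed=fit_seeds[b],
                    taxon_indices=idx,
                    covariate_names=cov_names,
                )
            )
        return fits

    result_warnings = []
    direction = config.direction
    direction_scan = None
    if direction == "auto":
        direction, direction_scan = determine_direction(_fit_all("unconstrained"))
    fits = _fit_all(direction)
    if direction == "unconstrained" and direction_scan is None:
        good = [f for f in fits if f.converged]
        n_neg = sum(1 for f in good if f.beta1 < 0)
        direction_scan = {"positive": len(good) - n_neg, "negative": n_neg}

    n_conv = sum(f.converged for f in fits)
    if n_conv < 0.5 * len(fits):
        result_warnings.append(
            f"only {n_conv}/{len(fits)} subset fits converged"
        )
    final_w = signal_average(fits, p, config.signal)

    S_valid = score_df.loc[valid_ids].to_numpy(dtype=float)
    index_valid = build_index(S_valid, final_w)
    y_valid = y_all.loc[valid_ids].to_numpy(dtype=float)
    Z_valid = Z_all.loc[valid_ids] if Z_all is not None else None
    glm = validate_index(
        index_valid, y_valid, Z_valid, family=config.family, covariate_names=cov_names
    )
    result_warnings.extend(glm.warnings)

    return WQSResult(
        final_weights=pd.Series(final_w, index=score_df.columns, name="weight"),
        train_ids=list(train_ids),
        validation_ids=list(valid_ids),
        direction=direction,
        signal=config.signal,
        family=config.family,
        index_values=pd.Series(index_valid, index=valid_ids, name="wqs"),
        glm_estimates=glm,
        n_subsets=len(fits),
        n_converged=n_conv,
        direction_scan=direction_scan,
        warnings=result_warnings,
    )


def zero_anchored_rank_with_reference(values, reference, levels, split):
    """Score ``values`` using cut points estimated from ``reference`` positives."""
    x = np.asarray(values, dtype=float)
    ref_pos = np.asarray(reference, dtype=float)
    ref_pos = ref_pos[ref_pos > 0]
    scores = np.zeros(x.shape, dtype=float)
    pos_mask = x > 0
    if ref_pos.size == 0 or not pos_mask.any():
        scores[pos_mask] = 1.0
        return scores
    if split == "median":
        med = np.median(ref_pos)
        scores[pos_mask] = np.where(x[pos_mask] < med, 1.0, 2.0)
        return scores
    if levels == 2:
        scores[pos_mask] = 1.0
        return scores
    cuts = np.quantile(ref_pos, np.arange(1, levels - 1) / (levels - 1))
    scores[pos_mask] = 1 + (x[pos_mask, None] > cuts[None, :]).sum(axis=1)
    return scores
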