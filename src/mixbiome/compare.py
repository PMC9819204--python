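"""Standard microbiome comparators: diversity, PERMANOVA, SIMPER, random forest.

These are the benchmark methods a microbiome analyst would reach for
before (or alongside) a mixture model: Shannon alpha-diversity, Bray-Curtis
and Aitchison beta-diversity with sequential PERMANOVA, SIMPER
decomposition of between-group dissimilarity, and a random-forest
importance screen.  The random forest itself is delegated to
scikit-learn; this module owns only the normalization, the 1/p importance
cutoff, and reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from skbio.stats.composition import clr, closure

from .tables_io import AbundanceTable

__all__ = [
    "DistanceMatrix",
    "shannon_index",
    "bray_curtis",
    "aitchison_distance",
    "beta_diversity",
    "permanova",
    "simper",
    "rf_importance_screen",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances between samples, with a metric label."""

    sample_ids: list
    matrix: np.ndarray
    metric: str

    def __post_init__(self):
        M = np.asarray(self.matrix, dtype=float)
        if M.shape[0] != M.shape[1]:
            raise ValueError("distance matrix must be square")
        if np.abs(M - M.T).max() > 1e-12:
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(M)).max() != 0:
            raise ValueError("distance matrix diagonal must be 0")
        self.matrix = M


def shannon_index(relabund_row) -> float:
    """Shannon diversity H = -sum p ln p (natural log) of one sample row."""
    x = np.asarray(relabund_row, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    if x.sum() == 0:
        raise ValueError("all-zero sample row")
    return float(entropy(x))  # scipy normalizes and uses natural log


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return float(np.abs(a - b).sum() / (a + b).sum())


def aitchison_distance(a, b, pseudocount: float = 1e-6) -> float:
    """Euclidean distance between clr transforms of pseudocounted compositions."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    a = closure(np.asarray(a, dtype=float) + pseudocount)
    b = closure(np.asarray(b, dtype=float) + pseudocount)
    return float(np.linalg.norm(clr(a) - clr(b)))


def beta_diversity(
    table: AbundanceTable, metric: str = "braycurtis", pseudocount: float = 1e-6
) -> DistanceMatrix:
    """All-pairs distance matrix for a table (braycurtis or aitchison)."""
    X = table.values
    if metric == "braycurtis":
        D = squareform(pdist(X, metric="braycurtis"))
    elif metric == "aitchison":
        logX = np.log(closure(X + pseudocount))
        clrX = logX - logX.mean(axis=1, keepdims=True)
        D = squareform(pdist(clrX, metric="euclidean"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(sample_ids=table.sample_ids, matrix=D, metric=metric)


# ---------------------------------------------------------------------------
# PERMANOVA (sequential / Type-I, adonis2-style)
# ---------------------------------------------------------------------------

def _term_design(values: pd.Series) -> np.ndarray:
    """Expand one model term to columns (dummy-encode non-numeric terms)."""
    if pd.api.types.is_numeric_dtype(values):
        return values.to_numpy(dtype=float)[:, None]
    levels = sorted(values.astype(str).unique())
    return np.column_stack(
        [(values.astype(str) == lev).astype(float) for lev in levels[1:]]
    )


def _hat(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return Q @ Q.T


def permanova(
    dist: DistanceMatrix,
    terms: pd.DataFrame,
    n_permutations: int = 999,
    seed=0,
) -> pd.DataFrame:
    """Sequential PERMANOVA of a distance matrix on ordered model terms.

    Partitions the Gower-centered matrix G = -1/2 J D^2 J term by term
    (Type-I order given by the columns of ``terms``); per-term pseudo-F is
    tested by freely permuting sample labels.  Returns a DataFrame with
    SumOfSqs, R2, F and the permutation p-value per term plus a residual
    row.  p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    D = dist.matrix
    n = D.shape[0]
    terms = pd.DataFrame(terms)
    if len(terms) != n:
        raise ValueError("terms must align with the distance matrix samples")
    for col in terms.columns:
        if terms[col].nunique() < 2:
            raise ValueError(f"constant model term {col!r}")

    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    ss_total = np.trace(G)

    designs = [_term_design(terms[c]) for c in terms.columns]
    dfs = np.array([X.shape[1] for X in designs])

    # sequential hat-matrix increments are fixed; permutations only move G,
    # so each term's SS is an elementwise product with the permuted G
    increments = []
    X = np.ones((n, 1))
    H_prev = _hat(X)
    for Xt in designs:
        X = np.column_stack([X, Xt])
        H = _hat(X)
        increments.append(H - H_prev)
        H_prev = H
    resid_proj = np.eye(n) - H_prev

    # a perfectly fitted model leaves residual SS ~ +/-1e-16; clamp so the
    # pseudo-F stays finite and extreme rather than sign-flipping
    ss_floor = 1e-12 * max(abs(ss_total), 1.0)

    def term_stats(Gmat):
        ss = np.array([float((Hd * Gmat).sum()) for Hd in increments])
        return ss, float((resid_proj * Gmat).sum())

    def pseudo_f(ss, ss_res):
        return (ss / dfs) / (max(ss_res, ss_floor) / df_res)

    ss_obs, ss_res_obs = term_stats(G)
    df_res = n - 1 - int(dfs.sum())
    F_obs = pseudo_f(ss_obs, ss_res_obs)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(designs))
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        ss_p, ss_res_p = term_stats(Gp)
        exceed += pseudo_f(ss_p, ss_res_p) >= F_obs
    pvals = (1.0 + exceed) / (1.0 + n_permutations)

    rows = []
    for i, col in enumerate(terms.columns):
        rows.append(
            {
                "term": col,
                "df": dfs[i],
                "SumOfSqs": ss_obs[i],
                "R2": ss_obs[i] / ss_total,
                "F": F_obs[i],
                "p": pvals[i],
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_res,
            "SumOfSqs": ss_res_obs,
            "R2": ss_res_obs / ss_total,
            "F": np.nan,
            "p": np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------

def _simper_contributions(X: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Per-taxon mean contribution to between-group Bray-Curtis dissimilarity."""
    A = X[g == g.min()]
    B = X[g == g.max()]
    diffs = np.abs(A[:, None, :] - B[None, :, :])  # n1 x n2 x p
    denom = (A[:, None, :] + B[None, :, :]).sum(axis=2)  # n1 x n2
    return (diffs / denom[:, :, None]).mean(axis=(0, 1))


def simper(
    table: AbundanceTable,
    groups,
    n_permutations: int = 999,
    cumulative_cutoff: float = 0.70,
    seed=0,
) -> pd.DataFrame:
    """SIMPER: decompose mean between-group Bray-Curtis dissimilarity by taxon.

    Contributions sum to the mean between-group dissimilarity; taxa are
    ranked descending and the identified set is the shortest prefix whose
    cumulative share reaches ``cumulative_cutoff``.  Per-taxon permutation
    p-values (group-label shuffles) are reported when ``n_permutations > 0``.
    """
    g = np.asarray(pd.Series(groups))
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError("SIMPER needs exactly two nonempty groups")
    if min((g == lv).sum() for lv in levels) < 1:
        raise ValueError("both groups must be nonempty")
    X = table.values
    contrib = _simper_contributions(X, g)
    total = contrib.sum()

    order = np.argsort(-contrib)
    share = contrib[order] / total
    cum = np.cumsum(share)
    n_identified = int(np.searchsorted(cum, cumulative_cutoff) + 1)
    identified = np.zeros(len(contrib), dtype=bool)
    identified[order[:n_identified]] = True

    pvals = np.full(len(contrib), np.nan)
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(contrib))
        for _ in range(n_permutations):
            gp = rng.permutation(g)
            exceed += _simper_contributions(X, gp) >= contrib
        pvals = (1.0 + exceed) / (1.0 + n_permutations)

    out = pd.DataFrame(
        {
            "contribution": contrib,
            "share": contrib / total,
            "identified": identified,
            "p": pvals,
        },
        index=pd.Index(table.taxon_ids, name="taxon_id"),
    )
    return out.sort_values("contribution", ascending=False)


# ---------------------------------------------------------------------------
# random-forest importance screen
# ---------------------------------------------------------------------------

def rf_importance_screen(
    table: AbundanceTable,
    response,
    covariate_columns=None,
    n_trees: int = 100,
    seed=0,
) -> tuple[pd.Series, list]:
    """Random-forest importance screen over taxa (+ optional covariates).

    Fits a scikit-learn forest (classifier for a binary response, regressor
    otherwise), normalizes impurity importances to sum 1, and identifies
    predictors whose share exceeds the equi-importance cutoff
    1/(number of predictors).
    """
    y = np.asarray(pd.Series(response))
    Xdf = table.data.copy()
    if covariate_columns:
        from .wqs_core import encode_covariates

        Z = encode_covariates(table.metadata, list(covariate_columns))
        for col in Z.columns:
            Xdf[col] = Z[col]
    binary = pd.Series(y).nunique() == 2
    cls = RandomForestClassifier if binary else RandomForestRegressor
    forest = cls(n_estimators=n_trees, random_state=np.random.default_rng(seed).integers(2**31))
    forest.fit(Xdf.to_numpy(), y)
    imp = forest.feature_importances_
    total = imp.sum()
    if total <= 0:
        raise ValueError("random forest produced all-zero importances")
    imp = pd.Series(imp / total, index=Xdf.columns, name="importance")
    cutoff = 1.0 / Xdf.shape[1]
    identified = list(imp.index[imp > cutoff])
    return imp, identified
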