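"""Repeated holdouts (WQS_RSRH): stratified partitions, ensembles, genus pooling.

A single train/validation split leaves the weight estimates at the mercy
of one random partition; repeating the whole WQS_RS pass over R
independent stratified partitions (40%/60% by default) and aggregating
gives distributionally robust weights and effect estimates.  Stratification
guarantees every level of the outcome (and of declared categorical
covariates) appears in both partitions, so no repetition fails for lack of
outcome variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ranking import RankedMatrix
from .tables_io import AbundanceTable
from .wqs_core import WQSConfig, WQSResult, run_wqs_rs

__all__ = [
    "HoldoutEnsemble",
    "GenusWeights",
    "stratified_partition",
    "run_wqs_rsrh",
    "aggregate_weights_by_genus",
]


@dataclass
class HoldoutEnsemble:
    """R repetitions' WQSResults plus aggregated weights and beta1 summaries."""

    results: list
    mean_weights: pd.Series
    beta_summary: dict  # mean, percentile interval, sign fractions
    direction: str
    config: WQSConfig
    warnings: list = field(default_factory=list)

    @property
    def betas(self) -> np.ndarray:
        return np.array([r.glm_estimates.beta1 for r in self.results])

    @property
    def odds_ratios(self) -> np.ndarray | None:
        if self.config.family != "binomial":
            return None
        return np.array([r.glm_estimates.odds_ratio for r in self.results])

    def weight_matrix(self) -> pd.DataFrame:
        """Per-holdout final weights, one row per repetition."""
        return pd.DataFrame([r.final_weights for r in self.results]).reset_index(
            drop=True
        )


@dataclass
class GenusWeights:
    """Per-genus pooled weights across holdouts with the 1/c equi-weight threshold."""

    table: pd.DataFrame  # index genus, columns: phylum, mean_weight, above_threshold
    per_holdout: pd.DataFrame  # rows = repetitions, columns = genera
    threshold: float
    n_genera: int


def stratified_partition(
    outcome, categorical_covariates, train_fraction: float, seed
) -> tuple[list, list]:
    """Outcome/covariate-stratified train-validation split.

    Samples are grouped into strata by the joint levels of the outcome and
    any declared categorical covariates; each stratum is split so that both
    partitions contain at least one of its members, with totals allocated
    by largest remainder so |train| = round(train_fraction * n).
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    y = pd.Series(outcome)
    # a continuous outcome (many distinct values) is not stratified on
    strat = y.astype(str) if y.nunique() <= max(10, int(0.05 * len(y))) else pd.Series(
        "all", index=y.index
    )
    if categorical_covariates is not None:
        cov = pd.DataFrame(categorical_covariates)
        for col in cov.columns:
            strat = strat + "|" + cov[col].astype(str)
    sizes = strat.value_counts()
    singles = sizes[sizes < 2]
    if len(singles):
        raise ValueError(
            f"infeasible stratification; levels with a single subject: "
            f"{list(singles.index)}"
        )
    n = len(y)
    n_train = int(round(train_fraction * n))
    rng = np.random.default_rng(seed)

    groups = {k: list(strat.index[strat == k]) for k in sizes.index}
    # largest-remainder allocation, clamped so both sides keep >= 1 per stratum
    quotas = {k: train_fraction * sizes[k] for k in groups}
    base = {k: int(np.clip(np.floor(quotas[k]), 1, sizes[k] - 1)) for k in groups}
    short = n_train - sum(base.values())
    order = sorted(groups, key=lambda k: -(quotas[k] - np.floor(quotas[k])))
    i = 0
    while short != 0 and i < 10 * len(order):
        k = order[i % len(order)]
        if short > 0 and base[k] < sizes[k] - 1:
            base[k] += 1
            short -= 1
        elif short < 0 and base[k] > 1:
            base[k] -= 1
            short += 1
        i += 1
    train_ids, valid_ids = [], []
    for k in sorted(groups):
        ids = list(groups[k])
        rng.shuffle(ids)
        train_ids.extend(ids[: base[k]])
        valid_ids.extend(ids[base[k] :])
    return sorted(train_ids), sorted(valid_ids)


def run_wqs_rsrh(
    table: AbundanceTable,
    ranked: RankedMatrix,
    outcome,
    covariates,
    config: WQSConfig,
    n_repeats: int = 30,
    seed: int = 0,
) -> HoldoutEnsemble:
    """Run WQS_RS over ``n_repeats`` independent stratified partitions.

    When ``config.direction == "auto"`` the sign constraint is resolved
    once, by a majority-sign scan of an unconstrained pass on the first
    derived partition, and then held fixed for every repetition.
    Per-repetition sub-seeds derive from the master seed by a counter
    scheme, so the ensemble is reproducible and repetitions independent.
    """
    config = config.validated()
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    # master seed may be an int or a counter-scheme list of ints
    entropy = [int(s) for s in seed] if isinstance(seed, (list, tuple)) else [int(seed)]
    ens_warnings = []
    direction = config.direction
    if direction == "auto":
        scan_cfg = WQSConfig(**{**config.__dict__, "direction": "unconstrained"})
        scan = run_wqs_rs(
            table, ranked, outcome, covariates, scan_cfg, seed=entropy + [90001]
        )
        # rebuild subset fits' majority sign from the scan result's stored scan
        # (the unconstrained pass records beta1 per subset via direction_scan)
        direction, counts = _direction_from_scan(scan)
        ens_warnings.append(
            f"direction fixed to {direction!r} by unconstrained scan "
            f"({counts['negative']}/{counts['negative'] + counts['positive']} negative)"
        )
    run_cfg = WQSConfig(**{**config.__dict__, "direction": direction})

    results = []
    for r in range(n_repeats):
        try:
            res = run_wqs_rs(
                table, ranked, outcome, covariates, run_cfg, seed=entropy + [r]
            )
        except Exception as exc:  # noqa: BLE001 - annotate which repetition failed
            raise RuntimeError(f"repetition {r} failed: {exc}") from exc
        results.append(res)
        ens_warnings.extend(f"repetition {r}: {w}" for w in res.warnings)

    W = pd.DataFrame([res.final_weights for res in results])
    mean_weights = W.mean(axis=0)
    mean_weights = mean_weights / mean_weights.sum()
    betas = np.array([res.glm_estimates.beta1 for res in results])
    frac_neg = float(np.mean(betas < 0))
    beta_summary = {
        "mean": float(betas.mean()),
        "percentile_2.5": float(np.percentile(betas, 2.5)),
        "percentile_97.5": float(np.percentile(betas, 97.5)),
        "fraction_negative": frac_neg,
        "fraction_positive": 1.0 - frac_neg,
    }
    if run_cfg.family == "binomial":
        ors = np.array([res.glm_estimates.odds_ratio for res in results])
        beta_summary["mean_odds_ratio"] = float(ors.mean())
    return HoldoutEnsemble(
        results=results,
        mean_weights=mean_weights,
        beta_summary=beta_summary,
        direction=direction,
        config=run_cfg,
        warnings=ens_warnings,
    )


def _direction_from_scan(scan: WQSResult) -> tuple[str, dict]:
    counts = scan.direction_scan
    if counts is None:
        # unconstrained pass: majority sign over its subset betas is not stored,
        # fall back to the validation estimate's sign
        sign = "negative" if scan.glm_estimates.beta1 < 0 else "positive"
        return sign, {"positive": int(sign == "positive"), "negative": int(sign == "negative")}
    if counts["negative"] == counts["positive"]:
        warnings.warn("exact tie in direction scan; defaulting to negative")
        return "negative", counts
    return ("negative" if counts["negative"] > counts["positive"] else "positive"), counts


def aggregate_weights_by_genus(
    ensemble: HoldoutEnsemble, taxonomy: pd.DataFrame
) -> GenusWeights:
    """Pool per-taxon weights to genus level within each holdout.

    Unclassified genera are labeled "unclassified (<phylum>)" so they pool
    within their phylum.  The equi-weight threshold is 1/c for c genera;
    genera whose mean pooled weight exceeds it are flagged.
    """
    W = ensemble.weight_matrix()
    missing = [t for t in W.columns if t not in taxonomy.index]
    if missing:
        raise ValueError(f"taxonomy missing taxa: {missing[:5]}")
    tax = taxonomy.loc[W.columns]
    genus = tax["genus"].astype(str).copy()
    unclassified = genus.str.lower().isin(["unclassified", "nan", ""])
    genus[unclassified] = "unclassified (" + tax.loc[unclassified, "phylum"].astype(str) + ")"
    per_holdout = W.T.groupby(genus.values).sum().T
    c = per_holdout.shape[1]
    threshold = 1.0 / c
    mean_w = per_holdout.mean(axis=0)
    phylum = tax.groupby(genus.values)["phylum"].first()
    out = pd.DataFrame(
        {
            "phylum": phylum,
            "mean_weight": mean_w,
            "above_threshold": mean_w > threshold,
        }
    ).sort_values("mean_weight", ascending=False)
    return GenusWeights(
        table=out, per_holdout=per_holdout, threshold=threshold, n_genera=c
    )
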