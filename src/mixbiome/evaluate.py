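"""Sensitivity/specificity of taxon identification against a known signal set.

Given estimated mixture weights and the set of taxa that truly carry
signal, sensitivity at a cutoff c is the fraction of signal taxa with
weight strictly above c, and specificity the fraction of non-signal taxa
strictly below c (ties at the cutoff count toward neither — "exceeding"
and "below" are both strict).  The customary cutoff is the equi-weight
threshold 1/p: a weight above it contributes more than under equal
weighting of all p components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EvalCurve",
    "equi_weight_threshold",
    "sensitivity_specificity",
    "ensemble_sensitivity_specificity",
    "proportion_ci",
]

DEFAULT_CUTOFFS = np.arange(0.0005, 0.002 + 1e-12, 0.00005)


@dataclass
class EvalCurve:
    """Sensitivity/specificity over a grid of weight cutoffs."""

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    per_stratum: pd.DataFrame | None  # rows = cutoffs, columns = strata
    n_signal: int
    n_nonsignal: int

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )
        if self.per_stratum is not None:
            for col in self.per_stratum.columns:
                df[f"sensitivity_{col}"] = self.per_stratum[col].to_numpy()
        return df

    def at(self, cutoff: float) -> dict:
        i = int(np.argmin(np.abs(self.cutoffs - cutoff)))
        out = {
            "cutoff": float(self.cutoffs[i]),
            "sensitivity": float(self.sensitivity[i]),
            "specificity": float(self.specificity[i]),
        }
        if self.per_stratum is not None:
            out.update(
                {
                    f"sensitivity_{c}": float(self.per_stratum[c].iloc[i])
                    for c in self.per_stratum.columns
                }
            )
        return out


def equi_weight_threshold(n_components: int) -> float:
    """1/c for a c-component index (the equal-weight benchmark)."""
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    return 1.0 / n_components


def sensitivity_specificity(
    weights, signal_set, cutoffs=None, strata: dict | None = None
) -> EvalCurve:
    """Evaluate weight-based identification of signal taxa over cutoffs.

    ``weights`` is a Series (taxon -> weight) or array; ``signal_set`` the
    true signal taxon ids (or indices for an unnamed array).  ``strata``
    optionally maps signal taxon -> stratum label (e.g. strong/medium/weak)
    for per-stratum sensitivities.
    """
    w = pd.Series(weights) if not isinstance(weights, pd.Series) else weights
    signal = list(signal_set)
    if not signal:
        raise ValueError("signal set is empty")
    missing = [t for t in signal if t not in w.index]
    if missing:
        raise ValueError(f"signal taxa missing from weights: {missing[:5]}")
    cutoffs = np.asarray(DEFAULT_CUTOFFS if cutoffs is None else cutoffs, dtype=float)
    if np.any(cutoffs <= 0):
        raise ValueError("cutoffs must be positive")
    w_sig = w.loc[signal].to_numpy()
    w_non = w.drop(index=signal).to_numpy()
    sens = (w_sig[None, :] > cutoffs[:, None]).mean(axis=1)
    spec = (w_non[None, :] < cutoffs[:, None]).mean(axis=1)
    per_stratum = None
    if strata:
        lab = pd.Series({t: strata.get(t, "unlabeled") for t in signal})
        cols = {}
        for s in sorted(lab.unique()):
            ws = w.loc[lab.index[lab == s]].to_numpy()
            cols[s] = (ws[None, :] > cutoffs[:, None]).mean(axis=1)
        per_stratum = pd.DataFrame(cols)
    return EvalCurve(
        cutoffs=cutoffs,
        sensitivity=sens,
        specificity=spec,
        per_stratum=per_stratum,
        n_signal=len(w_sig),
        n_nonsignal=len(w_non),
    )


def ensemble_sensitivity_specificity(
    ensemble, signal_set, cutoffs=None, strata=None, mode: str = "per-holdout"
) -> EvalCurve:
    """Evaluate a holdout ensemble's weights.

    ``mode="per-holdout"`` (default) evaluates each repetition's final
    weights and averages the per-holdout sensitivities/specificities;
    ``mode="mean-weights"`` evaluates the ensemble mean weight vector once.
    """
    if mode == "mean-weights":
        return sensitivity_specificity(ensemble.mean_weights, signal_set, cutoffs, strata)
    if mode != "per-holdout":
        raise ValueError(f"unknown mode {mode!r}")
    curves = [
        sensitivity_specificity(res.final_weights, signal_set, cutoffs, strata)
        for res in ensemble.results
    ]
    first = curves[0]
    sens = np.mean([c.sensitivity for c in curves], axis=0)
    spec = np.mean([c.specificity for c in curves], axis=0)
    per_stratum = None
    if first.per_stratum is not None:
        per_stratum = (
            pd.concat([c.per_stratum for c in curves])
            .groupby(level=0)
            .mean()
        )
    return EvalCurve(
        cutoffs=first.cutoffs,
        sensitivity=sens,
        specificity=spec,
        per_stratum=per_stratum,
        n_signal=first.n_signal,
        n_nonsignal=first.n_nonsignal,
    )


def proportion_ci(p: float, n: int) -> tuple:
    """Normal-approximation CI p +/- 1.96*sqrt(pq/n), clipped to [0, 1]."""
    if not (0 <= p <= 1):
        raise ValueError("p must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    half = 1.96 * np.sqrt(p * (1.0 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))
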