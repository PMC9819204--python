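"""Synthetic abundance tables and simulated outcome variables.

Two jobs live here.  First, generating sample × taxon tables whose
zero-inflation and dominance structure emulate a first-visit adult stool
16S working set (defaults: n=210 samples, p=868 taxa, per-taxon zero
fractions drawn uniformly on [0.35, 0.88], lognormal positive abundances
closed to relative abundances).  Second, simulating a binary "test"
variable driven by 20 designated signal taxa through a potency-adjusted
logistic model, plus an independent Bernoulli "control" variable for
negative-control analyses.

The potency adjustment log2(log10(x+1)/log10(max+1)) standardizes a
taxon's abundance against its own maximum (both on the percent scale)
before the strength coefficient is applied; it is 0 at x = max and
negative below, so under the default zero convention an *absent* taxon
contributes 0 to the logit while a *present* one contributes negatively —
presence of a signal taxon lowers the log-odds of the simulated outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .tables_io import AbundanceTable

__all__ = [
    "SimulationDesign",
    "potency_adjust",
    "simulate_test_variable",
    "simulate_control_variable",
    "synthesize_abundance_table",
    "assign_signal_taxa",
]

STRENGTH_BETAS = {"strong": 8.0, "medium": 4.0, "weak": 2.0}
DEFAULT_INTERCEPT = -5.0
_AS_FORMULA_CLIP = -50.0

_PHYLA = [
    "Firmicutes",
    "Bacteroidetes",
    "Actinobacteria",
    "Proteobacteria",
    "Verrucomicrobia",
]


@dataclass
class SimulationDesign:
    """Which taxa carry signal, at what strength, plus model constants.

    ``signal_taxa`` maps taxon_id -> strength label; strengths multiply the
    potency-adjusted abundance by 8 (strong), 4 (medium) or 2 (weak).
    ``covariate_effects`` lists (metadata column, level-or-None, beta):
    e.g. ("sex", "female", -1.0) adds -1 to the logit for females (males
    the reference).  ``zero_handling`` picks the convention for absent
    taxa: "zero_contribution" (default: contributes 0) or "as_formula"
    (the literal transform, -inf guarded by clipping at -50).
    """

    signal_taxa: dict
    strength_betas: dict = field(default_factory=lambda: dict(STRENGTH_BETAS))
    intercept: float = DEFAULT_INTERCEPT
    covariate_effects: list = field(
        default_factory=lambda: [("sex", "female", -1.0)]
    )
    zero_handling: str = "zero_contribution"
    calibrate_prevalence: float | None = None
    calibrated_intercept: float | None = None

    def strengths(self) -> pd.Series:
        return pd.Series(self.signal_taxa, name="strength")


def potency_adjust(x: float, max: float, zero_handling: str = "zero_contribution"):
    """log2(log10(x+1)/log10(max+1)) on the percent scale, with a zero convention.

    Vectorized over ``x``.  Returns 0 for x = max; negative below.  At
    x = 0 the literal formula is -inf: the default convention returns 0
    (an absent taxon contributes nothing), "as_formula" returns the
    literal value clipped at -50.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundance must be nonnegative")
    if max <= 0:
        raise ValueError("taxon maximum must be positive")
    if np.any(x > max * (1 + 1e-12)):
        raise ValueError("abundance exceeds the taxon maximum")
    with np.errstate(divide="ignore"):
        val = np.log2(np.log10(x + 1.0) / np.log10(max + 1.0))
    if zero_handling == "zero_contribution":
        val = np.where(x == 0, 0.0, val)
    elif zero_handling == "as_formula":
        clipped = val < _AS_FORMULA_CLIP
        if np.any(clipped):
            warnings.warn("potency values clipped at -50 under as_formula handling")
        val = np.maximum(val, _AS_FORMULA_CLIP)
    else:
        raise ValueError(f"unknown zero_handling {zero_handling!r}")
    return val if val.ndim else float(val)


def _logit_contributions(table: AbundanceTable, design: SimulationDesign) -> np.ndarray:
    """Taxon + covariate contributions to the logit (everything but the intercept)."""
    contrib = np.zeros(table.n_samples)
    for taxon, strength in design.signal_taxa.items():
        if taxon not in table.data.columns:
            raise ValueError(f"signal taxon {taxon!r} not in table")
        beta = design.strength_betas[strength]
        x_pct = table.data[taxon].to_numpy() * 100.0  # potency is percent-scale
        contrib += beta * potency_adjust(
            x_pct, float(x_pct.max()), design.zero_handling
        )
    for col, level, beta in design.covariate_effects:
        s = table.metadata[col]
        ind = (s.astype(str) == str(level)).astype(float) if level is not None else s.astype(float)
        contrib += beta * ind.to_numpy()
    return contrib


def _calibrate_intercept(contrib: np.ndarray, target: float, tol: float = 0.005) -> float:
    """Bisect the intercept so the mean Bernoulli probability hits ``target``."""
    lo, hi = -50.0, 50.0
    mean_p = lambda b0: float(expit(b0 + contrib).mean())
    while mean_p(lo) > target and lo > -2000:
        lo *= 2
    while mean_p(hi) < target and hi < 2000:
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if abs(mean_p(mid) - target) <= tol:
            return mid
        if mean_p(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def outcome_probabilities(table: AbundanceTable, design: SimulationDesign) -> np.ndarray:
    """Per-sample Bernoulli probabilities of the test variable (no draw).

    Applies intercept calibration first when ``design.calibrate_prevalence``
    is set, exactly as :func:`simulate_test_variable` would.
    """
    contrib = _logit_contributions(table, design)
    b0 = design.intercept
    if design.calibrate_prevalence is not None:
        b0 = _calibrate_intercept(contrib, design.calibrate_prevalence)
        design.calibrated_intercept = b0
    return expit(b0 + contrib)


def simulate_test_variable(
    table: AbundanceTable, design: SimulationDesign, seed=0
) -> np.ndarray:
    """Draw the binary test variable from the potency-adjusted logistic model.

    logit = b0 + sum_signal beta_strength * potency(x, max) + covariate effects,
    outcome ~ Bernoulli(expit(logit)).  When ``design.calibrate_prevalence``
    is set, the intercept is first adjusted by bisection so the mean fitted
    probability matches the target within 0.005 (stored on the design as
    ``calibrated_intercept``).
    """
    if table.mode != "relative":
        raise ValueError("simulate_test_variable expects a relative-abundance table")
    probs = outcome_probabilities(table, design)
    rng = np.random.default_rng(seed)
    return (rng.random(table.n_samples) < probs).astype(int)


def simulate_control_variable(n: int, prevalence: float, seed=0) -> np.ndarray:
    """An i.i.d. Bernoulli(prevalence) vector, independent of any table."""
    if not (0 < prevalence < 1):
        raise ValueError("prevalence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    return (rng.random(n) < prevalence).astype(int)


def synthesize_abundance_table(
    n_samples: int = 210,
    n_taxa: int = 868,
    zero_fraction_range: tuple = (0.35, 0.88),
    abundance_shape: tuple = (0.0, 1.5),
    taxonomy_breadth: int = 48,
    seed=0,
) -> AbundanceTable:
    """Generate a zero-inflated relative-abundance table with a toy taxonomy.

    Per taxon, a zero probability is drawn uniformly on
    ``zero_fraction_range`` and a lognormal location is drawn so a few taxa
    dominate (abundance_shape = (mu, sigma) of the log-scale base);
    nonzero cells are lognormal draws, rows are closed to sum 1.  Sample
    metadata gets a balanced two-level ``sex`` column.  Taxa are assigned
    to ``taxonomy_breadth`` genera nested in families and phyla.
    """
    lo, hi = zero_fraction_range
    if not (0 <= lo < hi <= 0.95):
        raise ValueError("zero_fraction_range must satisfy 0 <= lo < hi <= 0.95")
    rng = np.random.default_rng(seed)
    zero_p = rng.uniform(lo, hi, size=n_taxa)
    mu, sigma = abundance_shape
    taxon_mu = rng.normal(mu, 1.0, size=n_taxa)  # taxon-level dominance spread
    present = rng.random((n_samples, n_taxa)) >= zero_p[None, :]
    vals = np.where(
        present,
        rng.lognormal(mean=taxon_mu[None, :], sigma=sigma, size=(n_samples, n_taxa)),
        0.0,
    )
    # all-zero samples can occur at small n_taxa: redraw those rows, then fail
    for _ in range(20):
        empty = vals.sum(axis=1) == 0
        if not empty.any():
            break
        k = int(empty.sum())
        pres = rng.random((k, n_taxa)) >= zero_p[None, :]
        vals[empty] = np.where(
            pres, rng.lognormal(taxon_mu[None, :], sigma, size=(k, n_taxa)), 0.0
        )
    else:
        raise ValueError("could not avoid all-zero samples; adjust parameters")
    row_sums = vals.sum(axis=1)
    rel = vals / row_sums[:, None]

    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    taxon_ids = [f"OTU{j:04d}" for j in range(n_taxa)]
    genera = [f"genus{g:03d}" for g in range(taxonomy_breadth)]
    genus_of = rng.integers(0, taxonomy_breadth, size=n_taxa)
    genus_phylum = rng.integers(0, len(_PHYLA), size=taxonomy_breadth)
    taxonomy = pd.DataFrame(
        {
            "phylum": [_PHYLA[genus_phylum[g]] for g in genus_of],
            "family": [f"family{g // 4:02d}" for g in genus_of],
            "genus": [genera[g] for g in genus_of],
        },
        index=pd.Index(taxon_ids, name="taxon_id"),
    )
    sex = np.where(rng.random(n_samples) < 0.5, "male", "female")
    metadata = pd.DataFrame(
        {"sex": sex}, index=pd.Index(sample_ids, name="sample_id")
    )
    data = pd.DataFrame(rel, index=metadata.index, columns=taxonomy.index)
    return AbundanceTable(data=data, mode="relative", taxonomy=taxonomy, metadata=metadata)


def assign_signal_taxa(
    table: AbundanceTable,
    n_strong: int = 2,
    n_medium: int = 8,
    n_weak: int = 10,
    min_prevalence: float = 0.10,
    seed=0,
    **design_kwargs,
) -> SimulationDesign:
    """Randomly pick signal taxa and assign strength labels (2/8/10 by default)."""
    total = n_strong + n_medium + n_weak
    frac_nonzero = (table.data.to_numpy() > 0).mean(axis=0)
    eligible = [t for t, f in zip(table.data.columns, frac_nonzero) if f >= min_prevalence]
    if len(eligible) < total:
        raise ValueError(
            f"only {len(eligible)} taxa meet min_prevalence={min_prevalence}; "
            f"{total} needed"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(np.asarray(eligible, dtype=object), size=total, replace=False)
    labels = ["strong"] * n_strong + ["medium"] * n_medium + ["weak"] * n_weak
    return SimulationDesign(
        signal_taxa={t: s for t, s in zip(chosen, labels)}, **design_kwargs
    )
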