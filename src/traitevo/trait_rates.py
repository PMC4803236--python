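"""Site-specific transition rates for a binary trait on a fixed phylogeny.

The trait (disorder, structured/loop, phosphosite presence) evolves under
a symmetric two-state continuous-time Markov process: the 0->1 and 1->0
rates are equal, the stationary and root distribution is (1/2, 1/2), and
among-site rate variation follows a discretized gamma distribution with
equal-probability categories (default 6).  The gamma shape is fit by
maximum likelihood on the whole matrix; per-site rates are the posterior
mean category rate given the site's pattern (empirical Bayes); profiles
are reported as z-scores with mean 0 and sample standard deviation 1.

Branch lengths are taken from the input tree as-is, on the amino-acid
substitution scale; the trait process reuses that scale, so raw rates are
relative, and the comparable output across traits is the z-score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _likelihood
from ._likelihood import discretize_gamma, zscore_normalize  # noqa: F401
from .model import (MISSING, BinarizationConfig, BinaryPhyleticMatrix,
                    CladeAssignment, EstimationError, PhyloTree,
                    SiteRateProfile, ValidationError)


@dataclass
class TwoStateModel:
    """Symmetric two-state substitution process with gamma site rates.

    The base exchange rate is fixed at 1 per branch-length unit; gain/loss
    asymmetry is deliberately excluded.
    """

    gamma_shape: float = 1.0
    n_categories: int = 6
    root_freqs: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self):
        if self.gamma_shape <= 0:
            raise ValidationError("gamma_shape must be positive")
        if self.n_categories < 1:
            raise ValidationError("need at least one rate category")
        if abs(sum(self.root_freqs) - 1.0) > 1e-12:
            raise ValidationError("root frequencies must sum to 1")


def two_state_transition_matrix(rate: float, t: float) -> np.ndarray:
    """Closed-form transition probabilities of the symmetric process:
    P(same) = (1 + exp(-2 r t)) / 2, P(different) = (1 - exp(-2 r t)) / 2.
    """
    if rate <= 0:
        raise ValidationError(f"rate must be positive, got {rate}")
    if t < 0:
        raise ValidationError(f"branch length must be >= 0, got {t}")
    e = math.exp(-2.0 * rate * t)
    same = 0.5 * (1.0 + e)
    diff = 0.5 * (1.0 - e)
    return np.array([[same, diff], [diff, same]])


def _transition_for_rate(rate: float):
    cache: dict[float, np.ndarray] = {}

    def trans(t: float) -> np.ndarray:
        p = cache.get(t)
        if p is None:
            p = cache[t] = two_state_transition_matrix(rate, t)
        return p

    return trans


def _leaf_partials(tree: PhyloTree, matrix: BinaryPhyleticMatrix
                   ) -> dict[str, np.ndarray]:
    """Per-leaf (n_sites, 2) conditional likelihoods; missing -> ones."""
    index = {t: i for i, t in enumerate(matrix.taxa)}
    missing = set(tree.leaf_labels) - set(matrix.taxa)
    if missing:
        raise ValidationError(
            f"matrix lacks rows for leaves: {sorted(missing)}")
    lut = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])  # 0, 1, MISSING
    out = {}
    for label in tree.leaf_labels:
        states = matrix.data[index[label]]
        out[label] = lut[np.where(states == MISSING, 2, states)]
    return out


def pattern_log_likelihood(tree: PhyloTree, pattern: dict[str, int],
                           rate: float,
                           model: TwoStateModel | None = None) -> float:
    """Pruning log-likelihood of one site pattern at a fixed rate.

    ``pattern`` maps leaf label to 0, 1 or MISSING; absent leaves are
    treated as missing.  Returns -inf for impossible patterns.
    """
    model = model or TwoStateModel()
    unknown = set(pattern) - set(tree.leaf_labels)
    if unknown:
        raise ValidationError(f"pattern has non-leaf entries: "
                              f"{sorted(unknown)}")
    lut = {0: [1.0, 0.0], 1: [0.0, 1.0], MISSING: [1.0, 1.0]}
    partials = {
        label: np.array([lut[pattern.get(label, MISSING)]])
        for label in tree.leaf_labels}
    ll = _likelihood.prune_site_logliks(
        tree, partials, _transition_for_rate(rate),
        np.asarray(model.root_freqs))
    return float(ll[0])


def estimate_gamma_shape(tree: PhyloTree, matrix: BinaryPhyleticMatrix,
                         model: TwoStateModel | None = None,
                         included: np.ndarray | None = None) -> float:
    """ML gamma shape over the included columns (default: all columns with
    at least one non-missing entry)."""
    model = model or TwoStateModel()
    if included is None:
        included = (matrix.data != MISSING).any(axis=0)
    if not included.any():
        raise EstimationError("no usable columns: matrix is all-missing")
    sub = BinaryPhyleticMatrix(matrix.taxa, matrix.data[:, included],
                               matrix.kind)
    partials = _leaf_partials(tree, sub)
    return _likelihood.estimate_gamma_shape(
        tree, partials, _transition_for_rate, model.n_categories,
        np.asarray(model.root_freqs))


def posterior_site_rate(tree: PhyloTree, pattern: dict[str, int],
                        alpha: float, k: int = 6,
                        model: TwoStateModel | None = None) -> float:
    """Empirical-Bayes posterior-mean rate for one site pattern."""
    model = model or TwoStateModel()
    rates = discretize_gamma(alpha, k)
    cat_ll = np.array([[pattern_log_likelihood(tree, pattern, r, model)]
                       for r in rates]).reshape(k, 1)
    raw, valid = _likelihood.posterior_rates(cat_ll, rates)
    if not valid[0]:
        raise EstimationError("pattern impossible in every rate category")
    return float(raw[0])


def trait_rate_profile(tree: PhyloTree, matrix: BinaryPhyleticMatrix,
                       trait: str, scope: str = "family",
                       clades: CladeAssignment | None = None,
                       cfg: BinarizationConfig | None = None,
                       model: TwoStateModel | None = None
                       ) -> SiteRateProfile:
    """Full pipeline: (optional clade restriction) -> ML gamma shape ->
    empirical-Bayes posterior rate per column -> z-normalization.

    Columns that are entirely missing within the scope, or whose pattern
    is impossible in every category, carry NaN in both raw and z vectors.
    """
    model = model or TwoStateModel()
    if scope != "family":
        if clades is None:
            raise ValidationError("clade scope requires a CladeAssignment")
        members = clades.members(scope)
        tree = tree.pruned_to(members)
        matrix = matrix.subset(tree.leaf_labels)
    elif set(tree.leaf_labels) != set(matrix.taxa):
        matrix = matrix.subset(tree.leaf_labels)

    n_cols = matrix.n_columns
    included = (matrix.data != MISSING).any(axis=0)
    if included.sum() < 2:
        raise EstimationError("fewer than 2 usable columns in scope")
    sub = BinaryPhyleticMatrix(matrix.taxa, matrix.data[:, included],
                               matrix.kind)
    partials = _leaf_partials(tree, sub)
    root_freqs = np.asarray(model.root_freqs)
    alpha = _likelihood.estimate_gamma_shape(
        tree, partials, _transition_for_rate, model.n_categories, root_freqs)
    rates = discretize_gamma(alpha, model.n_categories)
    cat_ll = _likelihood.category_logliks(
        tree, partials, _transition_for_rate, rates, root_freqs)
    raw_sub, valid = _likelihood.posterior_rates(cat_ll, rates)

    raw = np.full(n_cols, np.nan)
    raw[np.flatnonzero(included)] = raw_sub
    z = np.full(n_cols, np.nan)
    ok = ~np.isnan(raw)
    z[ok] = zscore_normalize(raw[ok])
    n_missing = (matrix.data == MISSING).sum(axis=0)
    return SiteRateProfile(trait=trait, scope=scope, raw=raw, z=z,
                           alpha=alpha, n_missing=n_missing)
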