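"""Shared likelihood machinery: discretized-gamma rate heterogeneity,
Felsenstein pruning over many sites at once, maximum-likelihood fit of the
gamma shape, and empirical-Bayes posterior site rates.

The engines for binary traits and amino acids differ only in their state
space and transition-probability function; everything here is generic in
the number of states.  Likelihoods are accumulated with per-node scaling
so that only genuinely impossible patterns reach -inf.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as _gamma_dist

from .model import EstimationError, PhyloTree, logger

ALPHA_BOUNDS = (math.log(0.01), math.log(100.0))
ALPHA_XTOL = 1e-6


def discretize_gamma(alpha: float, k: int) -> np.ndarray:
    """Mean-of-slice discretization of Gamma(alpha, 1/alpha) into ``k``
    equal-probability categories.

    Category rates are the conditional means of the mean-1 gamma on each
    quantile slice; they are renormalized so their arithmetic mean is
    exactly 1.
    """
    if alpha <= 0:
        raise EstimationError(f"gamma shape must be positive, got {alpha}")
    if k < 1:
        raise EstimationError(f"need at least 1 category, got {k}")
    if k == 1:
        return np.ones(1)
    edges = _gamma_dist.ppf(np.linspace(0.0, 1.0, k + 1),
                            alpha, scale=1.0 / alpha)
    # integral of x f(x; a, s) over (0, b] equals a*s * F(b; a+1, s);
    # with s = 1/a the prefactor is 1, so slice means are K * dF(a+1)
    cdf_up = _gamma_dist.cdf(edges, alpha + 1.0, scale=1.0 / alpha)
    rates = k * np.diff(cdf_up)
    return rates / rates.mean()


def prune_site_logliks(tree: PhyloTree,
                       leaf_partials: dict[str, np.ndarray],
                       transition: Callable[[float], np.ndarray],
                       root_freqs: np.ndarray) -> np.ndarray:
    """Log-likelihood per site by postorder pruning.

    leaf_partials maps each leaf label to an (n_sites, n_states) array of
    conditional likelihoods (all-ones rows encode missing data).
    ``transition(t)`` returns the (n_states, n_states) matrix of
    probabilities P[parent_state, child_state] over a branch of length t.
    """
    root_freqs = np.asarray(root_freqs, dtype=float)
    partial: dict[int, np.ndarray] = {}
    logscale: np.ndarray | None = None
    for node in tree.postorder():
        if node.is_leaf:
            partial[id(node)] = leaf_partials[node.name]
            continue
        acc = None
        for child in node.children:
            pmat = transition(child.branch_length)
            contrib = partial.pop(id(child)) @ pmat.T
            acc = contrib if acc is None else acc * contrib
        scale = acc.max(axis=1)
        if logscale is None:
            logscale = np.zeros(len(scale))
        ok = scale > 0
        acc[ok] /= scale[ok, None]
        with np.errstate(divide="ignore"):
            logscale += np.where(ok, np.log(scale, where=ok,
                                            out=np.zeros_like(scale)),
                                 -np.inf)
        partial[id(node)] = acc
    root_partial = partial[id(tree.root)]
    if logscale is None:  # degenerate: tree of bare leaves cannot occur
        logscale = np.zeros(root_partial.shape[0])
    lik = root_partial @ root_freqs
    with np.errstate(divide="ignore"):
        return np.log(lik, where=lik > 0,
                      out=np.full(lik.shape, -np.inf)) + logscale


def category_logliks(tree: PhyloTree, leaf_partials: dict[str, np.ndarray],
                     transition_for_rate: Callable[[float],
                                                   Callable[[float],
                                                            np.ndarray]],
                     rates: np.ndarray,
                     root_freqs: np.ndarray) -> np.ndarray:
    """(K, n_sites) matrix of per-category site log-likelihoods."""
    return np.stack([
        prune_site_logliks(tree, leaf_partials,
                           transition_for_rate(rate), root_freqs)
        for rate in rates])


def _mixture_loglik(cat_ll: np.ndarray) -> float:
    """Total log-likelihood under the equal-weight category mixture.

    Sites impossible in every category (only possible over zero-length
    branches) carry no rate information and are left out of the sum; they
    are excluded from the profile downstream.
    """
    top = cat_ll.max(axis=0)
    finite = np.isfinite(top)
    if not finite.any():
        return -np.inf
    sub = cat_ll[:, finite]
    site_ll = top[finite] + np.log(np.exp(sub - top[finite]).mean(axis=0))
    return float(site_ll.sum())


def estimate_gamma_shape(tree: PhyloTree,
                         leaf_partials: dict[str, np.ndarray],
                         transition_for_rate, k: int,
                         root_freqs: np.ndarray) -> float:
    """ML estimate of the gamma shape by bounded 1-D search on log alpha."""
    if not leaf_partials:
        raise EstimationError("no data to estimate gamma shape from")

    def negloglik(log_alpha: float) -> float:
        rates = discretize_gamma(math.exp(log_alpha), k)
        cat_ll = category_logliks(tree, leaf_partials, transition_for_rate,
                                  rates, root_freqs)
        return -_mixture_loglik(cat_ll)

    res = minimize_scalar(negloglik, bounds=ALPHA_BOUNDS, method="bounded",
                          options={"xatol": ALPHA_XTOL})
    if not np.isfinite(res.fun):
        raise EstimationError("all site patterns have zero likelihood")
    alpha = math.exp(res.x)
    for bound in ALPHA_BOUNDS:
        if abs(res.x - bound) < 10 * ALPHA_XTOL:
            logger.warning(
                "gamma shape estimate %.4g hit the search bound; the data "
                "carry little or no rate-heterogeneity signal", alpha)
    return alpha


def posterior_rates(cat_ll: np.ndarray, rates: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-mean rate per site under equal category priors.

    Returns (raw_rates, valid) where sites whose likelihood is zero in
    every category are flagged invalid (NaN rate).
    """
    top = cat_ll.max(axis=0)
    valid = np.isfinite(top)
    raw = np.full(cat_ll.shape[1], np.nan)
    if valid.any():
        w = np.exp(cat_ll[:, valid] - top[valid])
        raw[valid] = (rates[:, None] * w).sum(axis=0) / w.sum(axis=0)
    if (~valid).any():
        logger.warning("%d site(s) with zero likelihood in every category "
                       "excluded from the rate profile", int((~valid).sum()))
    return raw, valid


def zscore_normalize(raw: np.ndarray) -> np.ndarray:
    """Standardize to mean 0 and sample (n-1) standard deviation 1."""
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise EstimationError("need at least 2 rates to normalize")
    sd = raw.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise EstimationError("rates are constant; z-scores undefined")
    return (raw - raw.mean()) / sd
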