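"""Independent oracles used by the test suite.

These deliberately avoid the package's pruning code path: likelihoods are
computed by exhaustive enumeration over internal-node state assignments,
transition probabilities by a generic matrix exponential, and gamma
category means by numerical quadrature.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from traitevo.model import PhyloTree


def expm_transition(generator: np.ndarray, rate: float,
                    t: float) -> np.ndarray:
    """P(t) via scipy's matrix exponential of the scaled generator."""
    return expm(generator * rate * t)


def brute_force_loglik(tree: PhyloTree, leaf_states: dict[str, int | None],
                       pmats: dict[int, np.ndarray],
                       root_freqs: np.ndarray) -> float:
    """Sum the pattern likelihood over every assignment of states to
    internal nodes (and to leaves whose state is None, i.e. missing).

    ``pmats`` maps id(node) -> the transition matrix on the branch above
    that node.
    """
    n_states = len(root_freqs)
    nodes = tree.postorder()
    free = [n for n in nodes
            if (not n.is_leaf) or leaf_states.get(n.name) is None]
    fixed = {id(n): leaf_states[n.name] for n in nodes
             if n.is_leaf and leaf_states.get(n.name) is not None}
    total = 0.0
    for assign in itertools.product(range(n_states), repeat=len(free)):
        state = dict(fixed)
        state.update({id(n): s for n, s in zip(free, assign)})
        prob = root_freqs[state[id(tree.root)]]
        for node in nodes:
            if node is tree.root:
                continue
            parent = state[id(node.parent)]
            prob *= pmats[id(node)][parent, state[id(node)]]
        total += prob
    return np.log(total) if total > 0 else -np.inf


def gamma_category_means(alpha: float, k: int) -> np.ndarray:
    """Conditional mean of Gamma(alpha, 1/alpha) on each equal-probability
    quantile slice, by adaptive quadrature."""
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), alpha,
                           scale=1.0 / alpha)
    means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        hi_eff = hi if np.isfinite(hi) else gamma_dist.ppf(
            1 - 1e-12, alpha, scale=1.0 / alpha)
        val, _ = quad(
            lambda x: x * gamma_dist.pdf(x, alpha, scale=1.0 / alpha),
            lo, hi_eff, limit=200)
        means.append(val * k)
    return np.asarray(means)
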