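"""Site-specific amino-acid substitution rates (SEQ) on a fixed phylogeny.

Columns of the protein alignment evolve under the Jones-Taylor-Thornton
(JTT) empirical replacement model with discretized-gamma rate variation
(default 16 equal-probability categories).  The generator is normalized to
one expected substitution per unit branch length, the gamma shape is fit
by maximum likelihood with branch lengths held fixed, per-site rates are
empirical-Bayes posterior means, and profiles are z-normalized exactly as
for the binary traits.

Transition matrices exp(Q r t) come from the symmetric eigendecomposition
of the reversible generator, computed once per model and cached per
(rate, branch length).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import _likelihood
from ._likelihood import discretize_gamma, zscore_normalize
from .model import (AA_INDEX, AA_LETTERS, GAP, UNKNOWN, Alignment,
                    CladeAssignment, EstimationError, PhyloTree,
                    SiteRateProfile, ValidationError)


def _load_jtt() -> tuple[np.ndarray, np.ndarray]:
    """Parse the shipped JTT table: 19 lower-triangle rows then a
    frequency line (PAML residue order)."""
    text = (resources.files("traitevo") / "data" / "jtt.dat").read_text()
    rows = [ln.split() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]
    tri, freqs = rows[:19], np.array(rows[19], dtype=float)
    s = np.zeros((20, 20))
    for i, vals in enumerate(tri, start=1):
        s[i, :i] = vals
        s[:i, i] = vals
    return s, freqs / freqs.sum()


@dataclass
class AAModel:
    """Empirical reversible amino-acid model with gamma site rates.

    Q[i, j] = S[i, j] * pi[j] off-diagonal, rows summing to zero, scaled
    so that -sum_i pi_i Q_ii = 1 (branch lengths in expected substitutions
    per site).  Detailed balance pi_i Q_ij = pi_j Q_ji holds because S is
    symmetric.
    """

    gamma_shape: float = 1.0
    n_categories: int = 16

    exchangeabilities: np.ndarray = field(default=None, repr=False)
    freqs: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.exchangeabilities is None or self.freqs is None:
            self.exchangeabilities, self.freqs = _load_jtt()
        if self.gamma_shape <= 0:
            raise ValidationError("gamma_shape must be positive")
        q = self.exchangeabilities * self.freqs[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(self.freqs * np.diag(q)).sum()
        q /= mu
        self.generator = q
        # symmetric form B = D^(1/2) Q D^(-1/2); eigendecompose once
        sqrt_pi = np.sqrt(self.freqs)
        b = sqrt_pi[:, None] * q / sqrt_pi[None, :]
        lam, vec = np.linalg.eigh((b + b.T) / 2.0)
        self._lam = lam
        self._left = vec / sqrt_pi[:, None]      # D^(-1/2) V
        self._right = (vec * sqrt_pi[:, None]).T  # V' D^(1/2)

    def transition_matrix(self, rate: float, t: float) -> np.ndarray:
        """P(rate * t) = exp(Q * rate * t), a stochastic matrix."""
        if t < 0:
            raise ValidationError(f"branch length must be >= 0, got {t}")
        return (self._left * np.exp(self._lam * rate * t)) @ self._right


def _transition_for_rate_factory(model: AAModel):
    def transition_for_rate(rate: float):
        cache: dict[float, np.ndarray] = {}

        def trans(t: float) -> np.ndarray:
            p = cache.get(t)
            if p is None:
                p = cache[t] = model.transition_matrix(rate, t)
            return p

        return trans

    return transition_for_rate


def _column_partial(column: str | dict[str, str], label: str) -> np.ndarray:
    residue = column[label] if isinstance(column, dict) else column
    if residue in (GAP, UNKNOWN):
        return np.ones((1, 20))
    if residue not in AA_INDEX:
        raise ValidationError(f"unknown residue {residue!r} for {label!r}")
    vec = np.zeros((1, 20))
    vec[0, AA_INDEX[residue]] = 1.0
    return vec


def aa_pattern_log_likelihood(tree: PhyloTree, column: dict[str, str],
                              rate: float,
                              model: AAModel | None = None) -> float:
    """Pruning log-likelihood of one alignment column at a fixed rate.

    ``column`` maps leaf label to a one-letter residue; '-' and 'X' are
    fully ambiguous.  The root is weighted by the stationary frequencies.
    """
    model = model or AAModel()
    partials = {label: _column_partial(column.get(label, GAP), label)
                for label in tree.leaf_labels}
    trans = _transition_for_rate_factory(model)(rate)
    ll = _likelihood.prune_site_logliks(tree, partials, trans, model.freqs)
    return float(ll[0])


def _alignment_partials(tree: PhyloTree, alignment: Alignment
                        ) -> dict[str, np.ndarray]:
    lut = np.vstack([np.eye(20),
                     np.ones((1, 20))])  # index 20 = ambiguous
    code = {a: i for i, a in enumerate(AA_LETTERS)}
    code[GAP] = 20
    code[UNKNOWN] = 20
    out = {}
    for label in tree.leaf_labels:
        row = alignment.row(label)
        try:
            idx = np.array([code[c] for c in row])
        except KeyError as exc:
            raise ValidationError(
                f"unknown residue {exc} in row {label!r}") from exc
        out[label] = lut[idx]
    return out


def aa_site_rates(tree: PhyloTree, alignment: Alignment,
                  k: int = 16, scope: str = "family",
                  clades: CladeAssignment | None = None,
                  model: AAModel | None = None) -> SiteRateProfile:
    """SEQ profile: ML gamma shape, empirical-Bayes posterior rate per
    column, z-normalized.  Columns fully gapped within the scope are NaN.
    """
    model = model or AAModel()
    if scope != "family":
        if clades is None:
            raise ValidationError("clade scope requires a CladeAssignment")
        members = clades.members(scope)
        tree = tree.pruned_to(members)
        alignment = Alignment(
            list(tree.leaf_labels),
            [alignment.row(lb) for lb in tree.leaf_labels])

    gapmat = alignment.gap_matrix()
    order = [alignment.labels.index(lb) for lb in tree.leaf_labels]
    gapmat = gapmat[order]
    included = ~gapmat.all(axis=0)
    if included.sum() < 2:
        raise EstimationError("fewer than 2 usable columns in scope")

    sub = Alignment(list(alignment.labels),
                    ["".join(np.array(list(r))[included]) for r in
                     alignment.rows])
    partials = _alignment_partials(tree, sub)
    tff = _transition_for_rate_factory(model)
    alpha = _likelihood.estimate_gamma_shape(tree, partials, tff, k,
                                             model.freqs)
    rates = discretize_gamma(alpha, k)
    cat_ll = _likelihood.category_logliks(tree, partials, tff, rates,
                                          model.freqs)
    raw_sub, valid = _likelihood.posterior_rates(cat_ll, rates)

    n_cols = alignment.n_columns
    raw = np.full(n_cols, np.nan)
    raw[np.flatnonzero(included)] = raw_sub
    z = np.full(n_cols, np.nan)
    ok = ~np.isnan(raw)
    z[ok] = zscore_normalize(raw[ok])
    return SiteRateProfile(trait="SEQ", scope=scope, raw=raw, z=z,
                           alpha=alpha, n_missing=gapmat.sum(axis=0))
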