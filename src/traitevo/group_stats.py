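"""Per-protein composition statistics and non-parametric group tests.

Composition: fraction of predicted disorder per protein (optionally over
a sub-region), Ser/Thr/Tyr fraction, pairwise percent identity.  Group
comparison follows the standard non-parametric protocol: a Shapiro-Wilk
normality screen per group, a Kruskal-Wallis omnibus test for three or
more groups, and all pairwise Mann-Whitney U tests with Bonferroni
correction (raw p times the number of pairwise tests, capped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .model import GAP, PHOSPHO_RESIDUES, ValidationError


def disorder_fraction(binary: np.ndarray,
                      region: tuple[int, int] | None = None) -> float:
    """Fraction of residues scored disordered, over the protein's own
    (ungapped) residues or a [start, end) sub-region of them."""
    binary = np.asarray(binary)
    if region is not None:
        start, end = region
        binary = binary[start:end]
    if binary.size == 0:
        raise ValidationError("empty residue scope")
    return float((binary == 1).sum() / binary.size)


def sty_fraction(sequence: str) -> float:
    """Fraction of Ser/Thr/Tyr in an ungapped sequence."""
    seq = sequence.replace(GAP, "")
    if not seq:
        raise ValidationError("empty sequence")
    return sum(c in PHOSPHO_RESIDUES for c in seq) / len(seq)


def pairwise_percent_identity(row_a: str, row_b: str,
                              denominator: str = "both-residues") -> float:
    """Percent identity between two rows of the same alignment.

    denominator: 'both-residues' (columns where both rows have residues,
    the default), 'shorter' (ungapped length of the shorter sequence), or
    'alignment' (all columns).
    """
    if len(row_a) != len(row_b):
        raise ValidationError("rows come from different alignments")
    a = np.array(list(row_a))
    b = np.array(list(row_b))
    both = (a != GAP) & (b != GAP)
    matches = int(((a == b) & both).sum())
    if denominator == "both-residues":
        denom = int(both.sum())
    elif denominator == "shorter":
        denom = min(int((a != GAP).sum()), int((b != GAP).sum()))
    elif denominator == "alignment":
        denom = len(a)
    else:
        raise ValidationError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValidationError("no columns where both rows have residues")
    return 100.0 * matches / denom


@dataclass
class GroupComparisonResult:
    """Summary of a non-parametric multi-group comparison."""

    summary: pd.DataFrame     # per group: n, mean, sd, shapiro_p
    omnibus_stat: float | None
    omnibus_p: float | None
    pairwise: pd.DataFrame    # group_a, group_b, U, p_raw, p_bonferroni
    alpha: float = 0.05

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.pairwise[self.pairwise["p_bonferroni"] < self.alpha]
        return list(zip(sig["group_a"], sig["group_b"]))


def compare_group_means(groups: dict[str, np.ndarray],
                        alpha: float = 0.05) -> GroupComparisonResult:
    """Normality screen, rank-based omnibus test (>= 3 groups), and all
    pairwise rank-sum tests with Bonferroni correction."""
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if v.size < 3:
            raise ValidationError(f"group {g!r} has n < 3")

    rows = []
    for g, v in arrays.items():
        if np.ptp(v) == 0:
            shapiro_p = np.nan  # constant sample: normality test undefined
        else:
            shapiro_p = float(stats.shapiro(v).pvalue)
        rows.append({"group": g, "n": v.size, "mean": float(v.mean()),
                     "sd": float(v.std(ddof=1)), "shapiro_p": shapiro_p})
    summary = pd.DataFrame(rows).set_index("group")

    omnibus_stat = omnibus_p = None
    if len(arrays) >= 3:
        try:
            res = stats.kruskal(*arrays.values())
            omnibus_stat, omnibus_p = float(res.statistic), \
                float(res.pvalue)
        except ValueError:
            # all observations identical across all groups
            omnibus_stat, omnibus_p = 0.0, 1.0

    pairs = list(combinations(arrays, 2))
    n_tests = len(pairs)
    records = []
    for ga, gb in pairs:
        a, b = arrays[ga], arrays[gb]
        if np.ptp(np.concatenate([a, b])) == 0:
            u, p_raw = a.size * b.size / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            u, p_raw = float(res.statistic), float(res.pvalue)
        records.append({"group_a": ga, "group_b": gb, "U": u,
                        "p_raw": p_raw,
                        "p_bonferroni": min(1.0, p_raw * n_tests)})
    pairwise = pd.DataFrame.from_records(records)
    return GroupComparisonResult(summary, omnibus_stat, omnibus_p,
                                 pairwise, alpha)


def correlate_disorder_vs_domains(disorder_pct: np.ndarray,
                                  domain_counts: np.ndarray
                                  ) -> dict[str, float]:
    """Product-moment correlation between per-protein disorder percentage
    and domain count, with R^2 and a two-sided p-value."""
    x = np.asarray(disorder_pct, dtype=float)
    y = np.asarray(domain_counts, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("need paired vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in one of the vectors")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return {"r": r, "r_squared": r * r, "p_value": float(res.pvalue)}
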