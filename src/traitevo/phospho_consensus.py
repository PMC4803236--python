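"""Majority-rule consensus phosphosite calling and shared/clade-specific
classification.

A column is a consensus phosphosite for a group when strictly more than
``majority_threshold`` (default 50%) of the group's sequences are
predicted phosphorylated there.  By default the denominator counts every
sequence in the group, gapped or not ("gaps included"); a non-gap
denominator is available behind ``cfg.consensus_denominator``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (MISSING, Alignment, BinarizationConfig,
                    BinaryPhyleticMatrix, PHOSPHO_RESIDUES,
                    ValidationError)


@dataclass
class ConsensusPhosphoSet:
    """Consensus phosphosites for one scope: column -> supporting
    fraction (all strictly above the majority threshold)."""

    scope: str
    fractions: dict[int, float]

    @property
    def columns(self) -> set[int]:
        return set(self.fractions)


def consensus_phospho_sites(matrix: BinaryPhyleticMatrix,
                            rows: list[str] | None = None,
                            scope: str = "family",
                            cfg: BinarizationConfig | None = None
                            ) -> ConsensusPhosphoSet:
    """Columns phosphorylated in strictly more than the threshold fraction
    of the scope's sequences."""
    cfg = cfg or BinarizationConfig()
    if matrix.kind != "phospho":
        raise ValidationError(f"need a phospho matrix, got {matrix.kind!r}")
    data = matrix.data
    if rows is not None:
        if not rows:
            raise ValidationError("empty row scope")
        index = {t: i for i, t in enumerate(matrix.taxa)}
        data = data[[index[r] for r in rows]]
    ones = (data == 1).sum(axis=0)
    if cfg.consensus_denominator == "all":
        denom = np.full(data.shape[1], data.shape[0], dtype=float)
    else:
        denom = (data != MISSING).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, ones / denom, 0.0)
    hits = np.flatnonzero(frac > cfg.majority_threshold)
    return ConsensusPhosphoSet(scope,
                               {int(c): float(frac[c]) for c in hits})


def classify_site_sharing(sets: dict[str, ConsensusPhosphoSet]
                          ) -> pd.DataFrame:
    """Partition the union of per-clade consensus columns into shared and
    clade-specific categories by exact set algebra.

    For clades A, B, C the categories are A&B&C, A&B, A&C, B&C, A-only,
    B-only, C-only (the generalization to any number of clades is the
    power-set partition by membership).
    """
    if not sets:
        raise ValidationError("no consensus sets given")
    names = list(sets)
    columns = sorted(set().union(*(s.columns for s in sets.values())))
    records = []
    for col in columns:
        members = [n for n in names if col in sets[n].columns]
        if len(members) == len(names):
            category = "all-" + "&".join(names) if len(names) > 2 \
                else "&".join(names)
        elif len(members) == 1:
            category = f"{members[0]}-only"
        else:
            category = "&".join(members)
        records.append({"column": col, "column1": col + 1,
                        "category": category,
                        "n_clades": len(members)})
    return pd.DataFrame.from_records(
        records, columns=["column", "column1", "category", "n_clades"])


def sharing_counts(classified: pd.DataFrame) -> dict[str, int]:
    """Category -> number of columns; values sum to the union size."""
    return classified["category"].value_counts().to_dict()


def consensus_residue_composition(alignment: Alignment,
                                  columns: set[int] | list[int],
                                  rows: list[str] | None = None
                                  ) -> pd.DataFrame:
    """Per consensus column, counts of Ser/Thr/Tyr (and other residues)
    among the scope's sequences — supports reasoning about Ser<->Thr vs
    Ser<->Tyr switches without any kinase inference."""
    chars = alignment.char_matrix()
    if rows is not None:
        index = {t: i for i, t in enumerate(alignment.labels)}
        chars = chars[[index[r] for r in rows]]
    records = []
    for col in sorted(columns):
        residues = chars[:, col]
        rec = {"column": col, "column1": col + 1}
        for aa in sorted(PHOSPHO_RESIDUES):
            rec[aa] = int((residues == aa).sum())
        rec["other"] = int((~np.isin(residues,
                                     sorted(PHOSPHO_RESIDUES))).sum())
        records.append(rec)
    return pd.DataFrame.from_records(
        records, columns=["column", "column1", "S", "T", "Y", "other"])


def write_consensus_tsv(sets: dict[str, ConsensusPhosphoSet],
                        classified: pd.DataFrame,
                        path: str | Path) -> None:
    cat = dict(zip(classified["column"], classified["category"]))
    with open(path, "w") as fh:
        fh.write("column1\tscope\tfraction\tcategory\n")
        for scope, cset in sets.items():
            for col in sorted(cset.fractions):
                fh.write(f"{col + 1}\t{scope}\t"
                         f"{cset.fractions[col]:.4f}\t{cat.get(col, '')}\n")
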