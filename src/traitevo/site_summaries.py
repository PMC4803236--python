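"""Downstream per-site summaries: gap filtering, fast/slow classification,
per-region rapid-site counts, accumulated rate profiles, disorder
conservation, and mapping per-site values onto PDB structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (GAP, MISSING, Alignment, BinarizationConfig,
                    BinaryPhyleticMatrix, RegionAnnotation, SiteRateProfile,
                    TraitEvoError, ValidationError, logger)


def filter_sites_by_gaps(source: Alignment | BinaryPhyleticMatrix,
                         rows: list[str] | None = None,
                         cfg: BinarizationConfig | None = None
                         ) -> np.ndarray:
    """Boolean mask over columns: kept iff the gap fraction among the
    scope's rows is strictly below ``gap_fraction_max``.

    The mask depends only on the rows in scope, so clade-level masks are
    computed on clade rows alone.
    """
    cfg = cfg or BinarizationConfig()
    if isinstance(source, Alignment):
        labels, gaps = source.labels, source.gap_matrix()
    else:
        labels, gaps = source.taxa, source.data == MISSING
    if rows is not None:
        if not rows:
            raise ValidationError("empty row scope")
        index = {t: i for i, t in enumerate(labels)}
        gaps = gaps[[index[r] for r in rows]]
    frac = gaps.sum(axis=0) / gaps.shape[0]
    return frac < cfg.gap_fraction_max


def classify_site_rates(profiles: dict[str, SiteRateProfile],
                        cfg: BinarizationConfig | None = None
                        ) -> pd.DataFrame:
    """Per-column fast/slow calls per trait plus ALL_fast / ALL_slow flags.

    fast iff z > rapid_threshold, slow iff z < rapid_threshold; a z exactly
    at the threshold is neither.  Columns lacking a z-score in any trait
    are excluded from the ALL_* flags (and reported).
    """
    cfg = cfg or BinarizationConfig()
    if not profiles:
        raise ValidationError("no profiles given")
    lengths = {len(p.z) for p in profiles.values()}
    if len(lengths) != 1:
        raise ValidationError("profiles disagree on column count")
    n_cols = lengths.pop()
    out = pd.DataFrame(index=pd.RangeIndex(n_cols, name="column"))
    complete = np.ones(n_cols, dtype=bool)
    for trait, prof in profiles.items():
        out[f"{trait}_fast"] = prof.z > cfg.rapid_threshold
        out[f"{trait}_slow"] = prof.z < cfg.rapid_threshold
        complete &= ~np.isnan(prof.z)
    fast_cols = [c for c in out.columns if c.endswith("_fast")]
    slow_cols = [c for c in out.columns if c.endswith("_slow")]
    out["ALL_fast"] = out[fast_cols].all(axis=1) & complete
    out["ALL_slow"] = out[slow_cols].all(axis=1) & complete
    out["complete"] = complete
    if (~complete).any():
        logger.info("%d column(s) lack a z-score in some trait and are "
                    "excluded from ALL_fast/ALL_slow",
                    int((~complete).sum()))
    return out


@dataclass
class RegionRapidTable:
    """Per-region counts of kept sites and of fast sites per trait,
    including ALL_fast / ALL_slow."""

    table: pd.DataFrame  # index: region label; columns: n_sites, <trait>,
    #                      ALL_fast, ALL_slow

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")


def count_rapid_by_region(classification: pd.DataFrame,
                          regions: RegionAnnotation,
                          gap_mask: np.ndarray) -> RegionRapidTable:
    """Count fast sites per (region, trait) over gap-filtered columns.

    Unannotated columns are counted under auto-generated linker labels.
    """
    regions = regions.with_linkers()
    if len(gap_mask) != regions.n_columns:
        raise ValidationError("gap mask length does not match regions")
    labels = regions.column_labels()
    traits = [c[:-5] for c in classification.columns
              if c.endswith("_fast") and not c.startswith("ALL")]
    records = []
    for label, start, end in regions.regions:
        keep = gap_mask[start:end]
        cols = np.arange(start, end)[keep]
        sub = classification.loc[cols]
        rec = {"region": label, "start": start, "end": end,
               "n_sites": len(cols)}
        for trait in traits:
            rec[trait] = int(sub[f"{trait}_fast"].sum())
        rec["ALL_fast"] = int(sub["ALL_fast"].sum())
        rec["ALL_slow"] = int(sub["ALL_slow"].sum())
        records.append(rec)
    table = pd.DataFrame.from_records(records).set_index("region")
    assert table["n_sites"].sum() == int(gap_mask.sum())
    return RegionRapidTable(table)


def accumulate_site_rates(profiles: dict[str, SiteRateProfile],
                          flag_above: float = 10.0) -> pd.DataFrame:
    """Per-site sum of z-scores across traits.

    Columns missing any trait's z-score carry NaN and are flagged
    ``incomplete``; accumulated values above ``flag_above`` are flagged
    ``extreme`` (mirrors marking sites with accumulated value > 10).
    """
    if not profiles:
        raise ValidationError("no profiles given")
    zs = pd.DataFrame({t: p.z for t, p in profiles.items()})
    out = pd.DataFrame(index=pd.RangeIndex(len(zs), name="column"))
    out["accumulated"] = zs.sum(axis=1, skipna=False)
    out["incomplete"] = zs.isna().any(axis=1)
    out["extreme"] = out["accumulated"] > flag_above
    return out


def site_disorder_conservation(matrix: BinaryPhyleticMatrix,
                               rows: list[str] | None = None) -> np.ndarray:
    """Fraction of rows scored 1 per column, gaps included: the denominator
    is the total number of rows in scope, so gapped rows dilute the
    fraction."""
    data = matrix.data
    if rows is not None:
        if not rows:
            raise ValidationError("empty row scope")
        index = {t: i for i, t in enumerate(matrix.taxa)}
        data = data[[index[r] for r in rows]]
    return (data == 1).sum(axis=0) / data.shape[0]


# ---------------------------------------------------------------------------
# PDB B-factor export
# ---------------------------------------------------------------------------

_SENTINEL = -1.0


def map_values_to_structure(values: np.ndarray,
                            mapping: dict[int, tuple[str, int]],
                            pdb_in: str | Path,
                            pdb_out: str | Path) -> None:
    """Write per-column values into the B-factor field of a PDB file.

    ``mapping`` sends an alignment column to a (chain id, residue number);
    every atom of a mapped residue receives that column's value, unmapped
    residues get the sentinel -1.  All records other than the B-factor
    field (columns 61-66) are preserved byte-identically.
    """
    values = np.asarray(values, dtype=float)
    target: dict[tuple[str, int], float] = {}
    for col, (chain, resnum) in mapping.items():
        v = values[col]
        if np.isnan(v):
            continue
        target[(chain, resnum)] = float(v)

    lines = Path(pdb_in).read_text().splitlines(keepends=True)
    present: set[tuple[str, int]] = set()
    out_lines = []
    for line in lines:
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 66:
            chain = line[21]
            resnum = int(line[22:26])
            present.add((chain, resnum))
            value = target.get((chain, resnum), _SENTINEL)
            line = line[:60] + f"{value:6.2f}" + line[66:]
        out_lines.append(line)
    absent = sorted(set(target) - present)
    if absent:
        raise TraitEvoError(
            f"mapped residues absent from structure: {absent}")
    Path(pdb_out).write_text("".join(out_lines))
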