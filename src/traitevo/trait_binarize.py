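"""Projection of per-residue predictions onto alignment columns and
binarization into phyletic patterns.

Each unaligned sequence carries one prediction value per residue; the
k-th value lands in the k-th non-gap column of that sequence's alignment
row, and gap columns are missing.  Binarization rules (boundary inclusive
on the "present" side):

* disorder: propensity >= 0.4 -> 1 (disordered), else 0 (ordered)
* secondary structure: H or E -> 1 (structured), C -> 0 (loop)
* phosphorylation: score >= 0.75 on Ser/Thr/Tyr -> 1; any score on a
  non-S/T/Y residue -> 0 (non-phosphorylatable); gap -> missing
"""

from __future__ import annotations

import numpy as np

from .model import (GAP, MISSING, PHOSPHO_RESIDUES, Alignment,
                    BinarizationConfig, BinaryPhyleticMatrix,
                    ResidueTrackSet, TraitEvoError, logger)


class ProjectionError(TraitEvoError):
    """Track length does not match the ungapped alignment row."""


def project_track(track: np.ndarray, aligned_row: str,
                  label: str = "?") -> np.ndarray:
    """Spread per-residue values along a gapped alignment row.

    Returns a float vector (NaN at gaps) for numeric tracks, or a
    single-character vector ('-' at gaps) for ss label tracks.
    """
    row = np.array(list(aligned_row), dtype="<U1")
    residue_cols = np.flatnonzero(row != GAP)
    track = np.asarray(track)
    if len(track) != len(residue_cols):
        raise ProjectionError(
            f"sequence {label!r}: {len(track)} track values for "
            f"{len(residue_cols)} residues")
    if track.dtype.kind in "fiu":
        out = np.full(len(row), np.nan)
        out[residue_cols] = track.astype(float)
    else:
        out = np.full(len(row), GAP, dtype="<U1")
        out[residue_cols] = track
    return out


def binarize_disorder(values: np.ndarray,
                      cfg: BinarizationConfig | None = None) -> np.ndarray:
    """Propensity >= cutoff is disordered (1); NaN stays missing."""
    cfg = cfg or BinarizationConfig()
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, MISSING, dtype=np.int8)
    present = ~np.isnan(values)
    out[present] = (values[present] >= cfg.disorder_cutoff).astype(np.int8)
    return out


def binarize_secondary_structure(labels: np.ndarray) -> np.ndarray:
    """H and E collapse to 1 (structured), C to 0 (loop); '-' is missing."""
    labels = np.asarray(labels, dtype="<U1")
    out = np.full(labels.shape, MISSING, dtype=np.int8)
    out[np.isin(labels, ("H", "E"))] = 1
    out[labels == "C"] = 0
    bad = ~np.isin(labels, ("H", "E", "C", GAP))
    if bad.any():
        raise TraitEvoError(
            f"invalid secondary-structure labels: "
            f"{sorted(set(labels[bad].tolist()))}")
    return out


def binarize_phospho(scores: np.ndarray, residues: np.ndarray,
                     cfg: BinarizationConfig | None = None) -> np.ndarray:
    """Score >= cutoff on a Ser/Thr/Tyr is a phosphosite.

    Non-S/T/Y residues (including 'X') are state 0 — absence of a
    phosphosite — rather than missing, so the matrix is defined at every
    non-gap column.  A positive score on a non-S/T/Y residue is accepted
    but forced to 0 with a warning.
    """
    cfg = cfg or BinarizationConfig()
    scores = np.asarray(scores, dtype=float)
    residues = np.asarray(residues, dtype="<U1")
    out = np.full(scores.shape, MISSING, dtype=np.int8)
    nongap = residues != GAP
    phosphorylatable = np.isin(residues, list(PHOSPHO_RESIDUES))
    out[nongap] = 0
    hit = phosphorylatable & ~np.isnan(scores) & (scores >= cfg.phospho_cutoff)
    out[hit] = 1
    stray = (~phosphorylatable & nongap & ~np.isnan(scores)
             & (scores >= cfg.phospho_cutoff))
    if stray.any():
        logger.warning(
            "%d high phospho scores on non-S/T/Y residues forced to 0",
            int(stray.sum()))
    return out


def aligned_track_matrix(alignment: Alignment,
                         tracks: ResidueTrackSet) -> np.ndarray:
    """taxa x columns matrix of projected raw values (the heat-map layer):
    floats with NaN at gaps, or characters with '-' at gaps for ss."""
    rows = []
    for label, row in zip(alignment.labels, alignment.rows):
        if label not in tracks:
            raise TraitEvoError(f"no {tracks.kind} track for {label!r}")
        rows.append(project_track(tracks[label], row, label))
    return np.stack(rows)


def assemble_phyletic_matrix(alignment: Alignment, tracks: ResidueTrackSet,
                             kind: str,
                             cfg: BinarizationConfig | None = None
                             ) -> BinaryPhyleticMatrix:
    """Project and binarize every row into one binary phyletic matrix."""
    cfg = cfg or BinarizationConfig()
    if kind != tracks.kind:
        raise TraitEvoError(
            f"requested {kind!r} from a {tracks.kind!r} track set")
    projected = aligned_track_matrix(alignment, tracks)
    if kind == "disorder":
        data = binarize_disorder(projected, cfg)
    elif kind == "ss":
        data = binarize_secondary_structure(projected)
    elif kind == "phospho":
        residues = alignment.char_matrix()
        data = binarize_phospho(projected, residues, cfg)
    else:
        raise TraitEvoError(f"unknown trait kind {kind!r}")
    return BinaryPhyleticMatrix(list(alignment.labels), data, kind)
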