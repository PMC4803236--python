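"""Readers and writers for all external formats.

Trees are Newick, alignments FASTA, prediction tracks TSV
(label, 1-based residue index, value), regions BED-like TSV
(label, 0-based start, exclusive end), clade maps TSV (leaf, clade).
Binary matrices and rate profiles are serialized as TSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import (GAP, MISSING, SS_LABELS, Alignment, BinaryPhyleticMatrix,
                    CladeAssignment, ParseError, PhyloTree, RegionAnnotation,
                    ResidueTrackSet, SiteRateProfile, TreeNode,
                    ValidationError, logger)

# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def _from_dendropy(dnode: dendropy.Node) -> TreeNode:
    if dnode.is_leaf():
        name = dnode.taxon.label if dnode.taxon else dnode.label
        node = TreeNode(name, dnode.edge.length)
    else:
        node = TreeNode(dnode.label, dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(_from_dendropy(child))
    return node


def parse_newick(text: str) -> PhyloTree:
    """Parse a single Newick string into a validated :class:`PhyloTree`."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,  # duplicates reach our validator
            preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parser classes
        raise ParseError(f"malformed Newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    root.branch_length = None
    return PhyloTree(root)


def read_newick(path: str | Path) -> PhyloTree:
    return parse_newick(Path(path).read_text())


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file.  Letters are uppercased and '.' gaps
    normalized to '-'; ragged inputs raise listing the offending labels."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ParseError(f"{path}: need at least 2 FASTA records")
    labels = [r.id for r in records]
    rows = [str(r.seq).upper().replace(".", GAP) for r in records]
    return Alignment(labels, rows)


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for label, row in zip(aln.labels, aln.rows):
            fh.write(f">{label}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# per-residue tracks
# ---------------------------------------------------------------------------


def read_track_tsv(path: str | Path, kind: str) -> ResidueTrackSet:
    """Read a track TSV with columns (label, 1-based index, value) into
    dense per-sequence vectors.  Indices must be contiguous from 1."""
    per_seq: dict[str, list[tuple[int, str]]] = {}
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            label, idx_s, value = row
            try:
                idx = int(idx_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad index {idx_s!r}") \
                    from exc
            per_seq.setdefault(label, []).append((idx, value))

    tracks: dict[str, np.ndarray] = {}
    for label, entries in per_seq.items():
        entries.sort()
        indices = [i for i, _ in entries]
        if indices != list(range(1, len(entries) + 1)):
            raise ValidationError(
                f"track {label!r}: residue indices not contiguous from 1")
        values = [v for _, v in entries]
        if kind == "ss":
            bad = set(values) - set(SS_LABELS)
            if bad:
                raise ValidationError(
                    f"track {label!r}: invalid ss labels {sorted(bad)} "
                    "(only H/E/C accepted)")
            tracks[label] = np.array(values, dtype="<U1")
        else:
            arr = np.array([float(v) for v in values])
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValidationError(
                    f"track {label!r}: values outside [0, 1]")
            tracks[label] = arr
    return ResidueTrackSet(kind, tracks)


def write_track_tsv(tracks: ResidueTrackSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for label, vec in tracks.tracks.items():
            for i, v in enumerate(vec, 1):
                if tracks.kind == "ss":
                    fh.write(f"{label}\t{i}\t{v}\n")
                else:
                    fh.write(f"{label}\t{i}\t{v:.6f}\n")


# ---------------------------------------------------------------------------
# regions and clades
# ---------------------------------------------------------------------------


def read_regions(path: str | Path, n_columns: int) -> RegionAnnotation:
    """Read BED-like (label, start, end) 0-based half-open intervals."""
    regions = []
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            label, start_s, end_s = row
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad interval") from exc
            regions.append((label, start, end))
    return RegionAnnotation(regions, n_columns)


def write_regions(regions: RegionAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for label, start, end in regions.regions:
            fh.write(f"{label}\t{start}\t{end}\n")


def read_clade_map(path: str | Path, tree: PhyloTree) -> CladeAssignment:
    """Read (leaf, clade) TSV; must cover the tree's leaves exactly."""
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            leaf, clade = row
            if leaf in assignment:
                raise ValidationError(f"leaf {leaf!r} assigned twice")
            assignment[leaf] = clade
    ca = CladeAssignment(assignment)
    ca.validate_against(tree.leaf_labels)
    return ca


def write_clade_map(clades: CladeAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for leaf, clade in clades.assignment.items():
            fh.write(f"{leaf}\t{clade}\n")


# ---------------------------------------------------------------------------
# derived-object serialization
# ---------------------------------------------------------------------------


def write_binary_matrix(matrix: BinaryPhyleticMatrix,
                        path: str | Path) -> None:
    """taxa x columns TSV with symbols 0/1/? (missing)."""
    sym = {0: "0", 1: "1", MISSING: "?"}
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(
            str(c) for c in range(matrix.n_columns)) + "\n")
        for taxon, row in zip(matrix.taxa, matrix.data):
            fh.write(taxon + "\t" + "\t".join(sym[int(v)] for v in row)
                     + "\n")


def read_binary_matrix(path: str | Path, kind: str) -> BinaryPhyleticMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    inv = {"0": 0, "1": 1, "?": MISSING}
    try:
        data = df.map(lambda s: inv[s]).to_numpy(dtype=np.int8)
    except KeyError as exc:
        raise ParseError(f"{path}: invalid matrix symbol {exc}") from exc
    return BinaryPhyleticMatrix(list(df.index), data, kind)


def write_profile_tsv(profile: SiteRateProfile, path: str | Path) -> None:
    """Column index (0- and 1-based), trait, scope, raw rate, z-score,
    and per-column missing count."""
    n_missing = profile.n_missing
    with open(path, "w") as fh:
        fh.write("column0\tcolumn1\ttrait\tscope\traw_rate\tz_score"
                 "\tn_missing\n")
        for col in range(len(profile.raw)):
            raw = profile.raw[col]
            z = profile.z[col]
            miss = "" if n_missing is None else int(n_missing[col])
            fh.write(f"{col}\t{col + 1}\t{profile.trait}\t{profile.scope}\t"
                     f"{'' if np.isnan(raw) else f'{raw:.6f}'}\t"
                     f"{'' if np.isnan(z) else f'{z:.6f}'}\t{miss}\n")


# ---------------------------------------------------------------------------
# cross validation
# ---------------------------------------------------------------------------


def cross_validate(tree: PhyloTree, alignment: Alignment,
                   tracks: dict[str, ResidueTrackSet] | None = None,
                   clades: CladeAssignment | None = None) -> None:
    """Assert that tree leaves, alignment rows, track labels and the clade
    map all describe the same set of sequences, and that every track has
    the length of its ungapped alignment row."""
    leaves = set(tree.leaf_labels)
    rows = set(alignment.labels)
    if leaves != rows:
        raise ValidationError(
            f"tree/alignment mismatch; tree-only: {sorted(leaves - rows)}, "
            f"alignment-only: {sorted(rows - leaves)}")
    if clades is not None:
        clades.validate_against(tree.leaf_labels)
    for kind, trackset in (tracks or {}).items():
        for label in alignment.labels:
            if label not in trackset:
                raise ValidationError(
                    f"{kind} track missing for sequence {label!r}")
            expect = len(alignment.ungapped(label))
            got = len(trackset[label])
            if got != expect:
                raise ValidationError(
                    f"{kind} track for {label!r} has {got} values, "
                    f"ungapped row has {expect} residues")
    logger.info("cross-validation passed: %d sequences, %d columns",
                alignment.n_rows, alignment.n_columns)
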