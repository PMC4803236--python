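"""Core data model shared by every stage of the pipeline.

The pipeline operates on five kinds of objects: a rooted phylogeny with
fixed branch lengths (:class:`PhyloTree`), a protein multiple sequence
alignment (:class:`Alignment`), per-residue prediction tracks for the
*unaligned* sequences (:class:`ResidueTrackSet`), labeled intervals over
alignment columns (:class:`RegionAnnotation`), and a leaf-to-clade map
(:class:`CladeAssignment`).  Binary phyletic patterns derived from the
tracks live in :class:`BinaryPhyleticMatrix`; inferred site rates in
:class:`SiteRateProfile`.

Alignment columns are 0-based half-open everywhere internally; report
writers additionally print 1-based inclusive coordinates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("traitevo")

AA_LETTERS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_LETTERS)}
GAP = "-"
UNKNOWN = "X"
SS_LABELS = ("H", "E", "C")
PHOSPHO_RESIDUES = frozenset("STY")

#: sentinel for a missing entry in an integer-coded binary matrix
MISSING = -1


class TraitEvoError(Exception):
    """Base class for all package errors."""


class ParseError(TraitEvoError):
    """Malformed input file."""


class ValidationError(TraitEvoError):
    """Input violates a structural invariant."""


class EstimationError(TraitEvoError):
    """Likelihood machinery cannot produce an estimate."""


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

class TreeNode:
    """A node of a rooted tree.  Leaves carry labels; every non-root node
    carries a branch length in expected substitutions per site."""

    __slots__ = ("name", "branch_length", "children", "parent")

    def __init__(self, name: str | None = None,
                 branch_length: float | None = None):
        self.name = name
        self.branch_length = branch_length
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted phylogeny with branch lengths, validated at construction.

    Invariants: one root, >= 2 leaves, unique leaf labels, all branch
    lengths >= 0.  Unnamed internal nodes are assigned generated names.
    Branch lengths are taken as given and never re-optimized.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._postorder: list[TreeNode] = []
        self._fill_postorder(root)
        self._autoname_internal()
        self._validate()

    def _fill_postorder(self, node: TreeNode) -> None:
        for child in node.children:
            self._fill_postorder(child)
        self._postorder.append(node)

    def _autoname_internal(self) -> None:
        counter = itertools.count(1)
        for node in self._postorder:
            if not node.is_leaf and not node.name:
                node.name = f"_internal_{next(counter)}"

    def _validate(self) -> None:
        leaves = self.leaves
        if len(leaves) < 2:
            raise ValidationError("tree must have at least 2 leaves")
        labels = [lf.name for lf in leaves]
        if any(lb is None or lb == "" for lb in labels):
            raise ValidationError("every leaf must be labeled")
        dupes = {lb for lb in labels if labels.count(lb) > 1}
        if dupes:
            raise ValidationError(f"duplicate leaf labels: {sorted(dupes)}")
        for node in self._postorder:
            if node is self.root:
                continue
            if node.branch_length is None:
                if node.is_leaf:
                    raise ValidationError(
                        f"leaf {node.name!r} has no branch length")
                logger.warning(
                    "internal node %s has no branch length; defaulting to 0",
                    node.name)
                node.branch_length = 0.0
            if node.branch_length < 0:
                raise ValidationError(
                    f"negative branch length on {node.name!r}")

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> list[TreeNode]:
        return list(self._postorder)

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self._postorder if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.name for n in self.leaves]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                name = "" if node.name.startswith("_internal_") else node.name
                body = f"({inner}){name}"
            if node is self.root or node.branch_length is None:
                return body
            return f"{body}:{node.branch_length:.10g}"

        return fmt(self.root) + ";"

    # -- editing -----------------------------------------------------------

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.branch_length)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return PhyloTree(clone(self.root))

    def pruned_to(self, keep: set[str] | list[str]) -> "PhyloTree":
        """Restrict the tree to a subset of leaves.

        Unifurcations created by the pruning are collapsed, summing branch
        lengths, so path lengths among kept leaves are preserved.
        """
        keep = set(keep)
        missing = keep - set(self.leaf_labels)
        if missing:
            raise ValidationError(f"unknown leaves: {sorted(missing)}")
        if len(keep) < 2:
            raise ValidationError("pruned tree needs at least 2 leaves")

        def prune(node: TreeNode) -> TreeNode | None:
            if node.is_leaf:
                if node.name in keep:
                    return TreeNode(node.name, node.branch_length)
                return None
            kept = [c for c in (prune(ch) for ch in node.children)
                    if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                if node.parent is not None and child.branch_length is not None:
                    child.branch_length += node.branch_length or 0.0
                elif node.parent is None:
                    # new root: drop the dangling stem length
                    child.branch_length = None
                return child
            new = TreeNode(node.name, node.branch_length)
            for c in kept:
                new.add_child(c)
            return new

        root = prune(self.root)
        assert root is not None
        root.branch_length = None
        return PhyloTree(root)


# ---------------------------------------------------------------------------
# alignment and tracks
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Protein multiple sequence alignment: ordered (label, row) pairs over
    the 20 amino-acid letters, '-' for gaps and 'X' for unknown residues."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise ValidationError("labels and rows differ in count")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate sequence labels")
        if not self.rows:
            raise ValidationError("empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            bad = [lb for lb, r in zip(self.labels, self.rows)
                   if len(r) != len(self.rows[0])]
            raise ValidationError(f"ragged alignment; offending rows: {bad}")
        if len(self.rows[0]) < 1:
            raise ValidationError("alignment has zero columns")
        allowed = set(AA_LETTERS) | {GAP, UNKNOWN}
        for lb, r in zip(self.labels, self.rows):
            extra = set(r) - allowed
            if extra:
                raise ValidationError(
                    f"row {lb!r} has invalid letters {sorted(extra)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]

    def ungapped(self, label: str) -> str:
        return self.row(label).replace(GAP, "")

    def char_matrix(self) -> np.ndarray:
        """(n_rows, n_columns) array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="<U1")

    def gap_matrix(self) -> np.ndarray:
        """Boolean (n_rows, n_columns); True where the row has a gap."""
        return self.char_matrix() == GAP


@dataclass
class ResidueTrackSet:
    """One per-residue prediction track per sequence, on the *ungapped*
    coordinates of that sequence.

    kind 'disorder' and 'phospho' hold float vectors in [0, 1]; kind 'ss'
    holds vectors of labels from {H, E, C}.
    """

    kind: str
    tracks: dict[str, np.ndarray]

    def __post_init__(self):
        if self.kind not in ("disorder", "ss", "phospho"):
            raise ValidationError(f"unknown track kind {self.kind!r}")
        for label, vec in self.tracks.items():
            if self.kind == "ss":
                bad = set(np.asarray(vec).tolist()) - set(SS_LABELS)
                if bad:
                    raise ValidationError(
                        f"track {label!r}: invalid ss labels {sorted(bad)}")
            else:
                arr = np.asarray(vec, dtype=float)
                if arr.size and (arr.min() < 0 or arr.max() > 1):
                    raise ValidationError(
                        f"track {label!r}: values outside [0, 1]")
                self.tracks[label] = arr

    def __contains__(self, label: str) -> bool:
        return label in self.tracks

    def __getitem__(self, label: str) -> np.ndarray:
        return self.tracks[label]


@dataclass
class RegionAnnotation:
    """Labeled, non-overlapping half-open intervals over alignment columns
    (e.g. Pfam domain envelopes); unannotated stretches can be auto-labeled
    as linkers."""

    regions: list[tuple[str, int, int]]
    n_columns: int

    def __post_init__(self):
        self.regions = sorted(self.regions, key=lambda r: r[1])
        labels = [r[0] for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate region labels")
        prev_end = 0
        for label, start, end in self.regions:
            if not (0 <= start < end <= self.n_columns):
                raise ValidationError(
                    f"region {label!r}: bad interval [{start}, {end}) "
                    f"for {self.n_columns} columns")
            if start < prev_end:
                raise ValidationError(f"region {label!r} overlaps previous")
            prev_end = end

    def with_linkers(self) -> "RegionAnnotation":
        """Fill unannotated stretches with auto-named linkers L1, L2, ...

        Mirrors the convention of naming inter-domain segments L1..Ln in
        order along the alignment.
        """
        out: list[tuple[str, int, int]] = []
        cursor = 0
        n_linker = 0
        for label, start, end in self.regions:
            if start > cursor:
                n_linker += 1
                out.append((f"L{n_linker}", cursor, start))
            out.append((label, start, end))
            cursor = end
        if cursor < self.n_columns:
            n_linker += 1
            out.append((f"L{n_linker}", cursor, self.n_columns))
        return RegionAnnotation(out, self.n_columns)

    def column_labels(self) -> np.ndarray:
        """Per-column region label; '' where unannotated."""
        labels = np.full(self.n_columns, "", dtype=object)
        for label, start, end in self.regions:
            labels[start:end] = label
        return labels


@dataclass
class CladeAssignment:
    """Total map leaf label -> clade label."""

    assignment: dict[str, str]

    def __post_init__(self):
        if not self.assignment:
            raise ValidationError("empty clade assignment")

    @property
    def clades(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.assignment.values():
            seen.setdefault(c)
        return list(seen)

    def members(self, clade: str) -> list[str]:
        out = [lf for lf, c in self.assignment.items() if c == clade]
        if not out:
            raise ValidationError(f"unknown clade {clade!r}")
        return out

    def validate_against(self, leaf_labels: list[str]) -> None:
        leaves = set(leaf_labels)
        mapped = set(self.assignment)
        missing = leaves - mapped
        extra = mapped - leaves
        if missing or extra:
            raise ValidationError(
                f"clade map mismatch; unmapped leaves: {sorted(missing)}, "
                f"unknown leaves: {sorted(extra)}")


# ---------------------------------------------------------------------------
# derived objects
# ---------------------------------------------------------------------------

@dataclass
class BinarizationConfig:
    """Cutoffs and thresholds used throughout the pipeline.

    disorder_cutoff: propensity >= cutoff is scored disordered (1).
    phospho_cutoff: score >= cutoff on a Ser/Thr/Tyr is a phosphosite (1).
    gap_fraction_max: a column is kept iff its gap fraction is strictly
        below this value.
    majority_threshold: consensus requires a supporting fraction strictly
        above this value.
    rapid_threshold: z-scores strictly above are 'fast', strictly below
        'slow'; a z exactly at the threshold is neither.
    """

    disorder_cutoff: float = 0.4
    phospho_cutoff: float = 0.75
    gap_fraction_max: float = 0.10
    majority_threshold: float = 0.5
    rapid_threshold: float = 0.0
    consensus_denominator: str = "all"  # 'all' (gaps included) | 'non-gap'

    def __post_init__(self):
        for name in ("disorder_cutoff", "phospho_cutoff",
                     "gap_fraction_max", "majority_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.consensus_denominator not in ("all", "non-gap"):
            raise ValidationError("consensus_denominator must be "
                                  "'all' or 'non-gap'")


@dataclass
class BinaryPhyleticMatrix:
    """taxa x columns matrix over {0, 1, MISSING}; one per binary trait.

    Entries are MISSING exactly where the alignment row has a gap.
    """

    taxa: list[str]
    data: np.ndarray  # int8, values in {0, 1, MISSING}
    kind: str  # disorder | ss | phospho

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValidationError("matrix shape does not match taxa")
        bad = ~np.isin(self.data, (0, 1, MISSING))
        if bad.any():
            raise ValidationError("matrix entries must be 0, 1 or missing")

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def subset(self, taxa: list[str]) -> "BinaryPhyleticMatrix":
        index = {t: i for i, t in enumerate(self.taxa)}
        rows = [index[t] for t in taxa]
        return BinaryPhyleticMatrix(list(taxa), self.data[rows], self.kind)


@dataclass
class SiteRateProfile:
    """Per-column empirical-Bayes rates for one trait in one scope.

    ``raw`` and ``z`` are full-length (n_columns) vectors with NaN at
    columns excluded from the inference (all-missing within the scope or
    degenerate likelihood).  z-scores over included columns have mean 0 and
    sample (n-1) standard deviation 1.
    """

    trait: str  # DOT | SLT | PT | SEQ
    scope: str  # 'family' or a clade label
    raw: np.ndarray
    z: np.ndarray
    alpha: float
    n_missing: np.ndarray = field(default=None)  # per-column missing count

    @property
    def included(self) -> np.ndarray:
        return ~np.isnan(self.z)
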