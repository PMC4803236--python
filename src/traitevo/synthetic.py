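"""Seeded synthetic datasets with the statistical structure the pipeline
assumes: a clock-free birth tree, binary traits evolved under the
symmetric two-state process with discretized-gamma site rates, amino-acid
columns evolved under the JTT model, continuous predictor tracks
consistent with the binary truth, phylogenetically autocorrelated
alignment gaps, and designated clades with domain/linker regions.

One integer seed drives a single :class:`numpy.random.Generator` threaded
through every draw; regeneration from the same parameters and seed is
bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_core
from ._likelihood import discretize_gamma
from .model import (AA_LETTERS, GAP, MISSING, PHOSPHO_RESIDUES, Alignment,
                    BinaryPhyleticMatrix, CladeAssignment, PhyloTree,
                    RegionAnnotation, ResidueTrackSet, TreeNode,
                    ValidationError)
from .seq_rates import AAModel
from .trait_rates import two_state_transition_matrix


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def simulate_yule_tree(n_taxa: int, birth_rate: float = 1.0,
                       seed: int | np.random.Generator = 0,
                       depth: float = 1.0,
                       label_prefix: str = "t") -> PhyloTree:
    """Pure-birth tree on ``n_taxa`` leaves, rescaled so the mean
    root-to-tip path length equals ``depth``."""
    if n_taxa < 2:
        raise ValidationError("need at least 2 taxa")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    root = TreeNode()
    tips = [root.add_child(TreeNode(branch_length=0.0)),
            root.add_child(TreeNode(branch_length=0.0))]
    while True:
        wait = rng.exponential(1.0 / (birth_rate * len(tips)))
        for tip in tips:
            tip.branch_length += wait
        if len(tips) == n_taxa:
            break
        parent = tips.pop(rng.integers(len(tips)))
        tips.append(parent.add_child(TreeNode(branch_length=0.0)))
        tips.append(parent.add_child(TreeNode(branch_length=0.0)))
    width = int(math.log10(n_taxa)) + 1
    for i, tip in enumerate(tips, 1):
        tip.name = f"{label_prefix}{i:0{width}d}"
    tree = PhyloTree(root)
    _rescale_depth(tree, depth)
    return tree


def _rescale_depth(tree: PhyloTree, depth: float) -> None:
    tip_depths = []

    def walk(node: TreeNode, d: float) -> None:
        d += node.branch_length or 0.0
        if node.is_leaf:
            tip_depths.append(d)
        for c in node.children:
            walk(c, d)

    walk(tree.root, 0.0)
    mean = float(np.mean(tip_depths))
    if mean <= 0:
        return
    factor = depth / mean
    for node in tree.postorder():
        if node.branch_length is not None:
            node.branch_length *= factor


def join_clades(subtrees: dict[str, PhyloTree],
                stem_length: float = 0.3) -> tuple[PhyloTree,
                                                   CladeAssignment]:
    """Join clade subtrees under a shared root.

    Three clades are joined as ((B, C), A) — the first clade is the
    outgroup, mirroring a duplication history where the last two clades
    are sisters.  Other counts are joined as a fan at the root.
    """
    names = list(subtrees)
    roots = {}
    for name, sub in subtrees.items():
        clone = sub.copy()
        clone.root.branch_length = stem_length
        roots[name] = clone.root
    top = TreeNode()
    if len(names) == 3:
        inner = TreeNode(branch_length=stem_length)
        inner.add_child(roots[names[1]])
        inner.add_child(roots[names[2]])
        top.add_child(inner)
        top.add_child(roots[names[0]])
    else:
        for name in names:
            top.add_child(roots[name])
    assignment = {leaf: name for name, sub in subtrees.items()
                  for leaf in sub.leaf_labels}
    return PhyloTree(top), CladeAssignment(assignment)


# ---------------------------------------------------------------------------
# character simulation on the tree
# ---------------------------------------------------------------------------


def _simulate_markov(tree: PhyloTree, root_states: np.ndarray,
                     site_rates: np.ndarray,
                     pmatrix_fn, n_states: int,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Evolve per-site discrete states down the tree.

    ``pmatrix_fn(rate, t)`` gives the (n_states, n_states) transition
    matrix; sites sharing a rate category are evolved together.
    """
    categories = {}
    for rate in np.unique(site_rates):
        categories[rate] = np.flatnonzero(site_rates == rate)
    states = {id(tree.root): root_states}
    leaf_states: dict[str, np.ndarray] = {}

    def walk(node: TreeNode) -> None:
        parent_states = states[id(node)]
        for child in node.children:
            child_states = np.empty_like(parent_states)
            for rate, idx in categories.items():
                pmat = pmatrix_fn(float(rate), child.branch_length)
                cum = pmat.cumsum(axis=1)
                u = rng.random(len(idx))
                child_states[idx] = (
                    u[:, None] > cum[parent_states[idx]]).sum(axis=1)
            states[id(child)] = child_states
            if child.is_leaf:
                leaf_states[child.name] = child_states
            else:
                walk(child)
        del states[id(node)]

    walk(tree.root)
    return leaf_states


def simulate_binary_trait_matrix(tree: PhyloTree, n_sites: int,
                                 alpha: float,
                                 seed: int | np.random.Generator = 0,
                                 k: int = 6, kind: str = "disorder"
                                 ) -> tuple[BinaryPhyleticMatrix,
                                            np.ndarray, np.ndarray]:
    """Binary trait evolved under the symmetric two-state process.

    Each site draws one of ``k`` equal-weight gamma categories; the root
    state is uniform on {0, 1}.  Returns (matrix, true per-site category
    rates, category indices).
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    rates = discretize_gamma(alpha, k)
    cats = rng.integers(k, size=n_sites)
    site_rates = rates[cats]
    root = (rng.random(n_sites) < 0.5).astype(np.int64)

    def pmat(rate: float, t: float) -> np.ndarray:
        if rate <= 0 or t == 0:
            return np.eye(2)
        return two_state_transition_matrix(rate, t)

    leaf_states = _simulate_markov(tree, root, site_rates, pmat, 2, rng)
    taxa = tree.leaf_labels
    data = np.stack([leaf_states[t] for t in taxa]).astype(np.int8)
    return (BinaryPhyleticMatrix(taxa, data, kind), site_rates, cats)


def simulate_aa_alignment(tree: PhyloTree, n_sites: int, alpha: float,
                          seed: int | np.random.Generator = 0,
                          k: int = 16, model: AAModel | None = None
                          ) -> tuple[Alignment, np.ndarray, np.ndarray]:
    """Amino-acid columns evolved under the JTT model with gamma rates;
    root residues are drawn from the stationary frequencies."""
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    model = model or AAModel()
    rates = discretize_gamma(alpha, k)
    cats = rng.integers(k, size=n_sites)
    site_rates = rates[cats]
    root = rng.choice(20, size=n_sites, p=model.freqs)

    def pmat(rate: float, t: float) -> np.ndarray:
        if rate <= 0 or t == 0:
            return np.eye(20)
        p = model.transition_matrix(rate, t)
        p = np.clip(p, 0.0, None)
        return p / p.sum(axis=1, keepdims=True)

    leaf_states = _simulate_markov(tree, root, site_rates, pmat, 20, rng)
    taxa = tree.leaf_labels
    letters = np.array(list(AA_LETTERS))
    rows = ["".join(letters[leaf_states[t]]) for t in taxa]
    return Alignment(list(taxa), rows), site_rates, cats


def simulate_gap_mask(tree: PhyloTree, n_sites: int,
                      seed: int | np.random.Generator = 0,
                      loss_rate: float = 0.05, gain_rate: float = 0.45,
                      root_present: float = 0.95) -> np.ndarray:
    """Phylogenetically autocorrelated indel mask: residue presence (1) /
    absence (0) evolves as an asymmetric two-state process down the tree,
    so gaps cluster by clade as in real alignments.

    Returns a boolean (n_taxa, n_sites) array, True where a residue is
    present, rows ordered by ``tree.leaf_labels``.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    total = loss_rate + gain_rate

    def pmat(rate: float, t: float) -> np.ndarray:
        e = math.exp(-total * t)
        pi1 = gain_rate / total  # stationary presence probability
        return np.array([
            [1 - pi1 * (1 - e), pi1 * (1 - e)],
            [(1 - pi1) * (1 - e), pi1 + (1 - pi1) * e]])

    root = (rng.random(n_sites) < root_present).astype(np.int64)
    leaf_states = _simulate_markov(tree, root, np.ones(n_sites), pmat, 2,
                                   rng)
    return np.stack([leaf_states[t] for t in tree.leaf_labels]).astype(bool)


# ---------------------------------------------------------------------------
# predictor-like tracks
# ---------------------------------------------------------------------------


def _draw_side(rng: np.random.Generator, above: np.ndarray,
               cutoff: float) -> np.ndarray:
    """Uniform draws on the requested side of the cutoff: above -> value
    in [cutoff, 1], below -> value in [0, cutoff)."""
    u = rng.random(above.shape)
    return np.where(above, cutoff + u * (1.0 - cutoff), u * cutoff)


def simulate_propensity_tracks(truth: BinaryPhyleticMatrix,
                               alignment: Alignment, epsilon: float,
                               seed: int | np.random.Generator = 0,
                               cutoff: float = 0.4,
                               kind: str | None = None) -> ResidueTrackSet:
    """Continuous per-residue scores consistent with a binary truth.

    With probability 1 - epsilon the score falls on the truth's side of
    the cutoff, with probability epsilon on the wrong side; gap positions
    produce no value.  For phospho truth, non-S/T/Y residues always score
    below the cutoff (they are non-phosphorylatable by construction).
    """
    if not 0 <= epsilon < 0.5:
        raise ValidationError("epsilon must be in [0, 0.5)")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    kind = kind or truth.kind
    tracks: dict[str, np.ndarray] = {}
    for taxon, row in zip(alignment.labels, alignment.rows):
        i = truth.taxa.index(taxon)
        cols = np.array([c for c, ch in enumerate(row) if ch != GAP])
        states = truth.data[i, cols]
        if (states == MISSING).any():
            raise ValidationError(
                f"truth matrix missing at residue positions of {taxon!r}")
        flip = rng.random(len(cols)) < epsilon
        above = (states == 1) ^ flip
        if kind == "phospho":
            residues = np.array(list(row))[cols]
            sty = np.isin(residues, sorted(PHOSPHO_RESIDUES))
            above &= sty
        tracks[taxon] = _draw_side(rng, above, cutoff)
    return ResidueTrackSet(kind if kind != "ss" else "disorder", tracks)


def simulate_ss_tracks(truth: BinaryPhyleticMatrix, alignment: Alignment,
                       epsilon: float,
                       seed: int | np.random.Generator = 0
                       ) -> ResidueTrackSet:
    """Three-state secondary-structure labels consistent with a binary
    structured/loop truth: state 1 becomes H or E (equally likely), state
    0 becomes C; labels flip sides with probability epsilon."""
    if not 0 <= epsilon < 0.5:
        raise ValidationError("epsilon must be in [0, 0.5)")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    tracks: dict[str, np.ndarray] = {}
    for taxon, row in zip(alignment.labels, alignment.rows):
        i = truth.taxa.index(taxon)
        cols = np.array([c for c, ch in enumerate(row) if ch != GAP])
        states = truth.data[i, cols]
        flip = rng.random(len(cols)) < epsilon
        structured = (states == 1) ^ flip
        helix = rng.random(len(cols)) < 0.5
        labels = np.where(structured, np.where(helix, "H", "E"), "C")
        tracks[taxon] = labels.astype("<U1")
    return ResidueTrackSet("ss", tracks)


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------


@dataclass
class SyntheticBundle:
    """A complete, internally consistent synthetic dataset."""

    tree: PhyloTree
    alignment: Alignment
    tracks: dict[str, ResidueTrackSet]
    binary_truth: dict[str, BinaryPhyleticMatrix]
    true_site_rates: dict[str, np.ndarray]
    true_categories: dict[str, np.ndarray]
    true_alpha: dict[str, float]
    clades: CladeAssignment
    regions: RegionAnnotation
    seed: int

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree": out / "tree.nwk",
            "alignment": out / "alignment.fasta",
            "regions": out / "regions.tsv",
            "clades": out / "clades.tsv",
        }
        io_core.write_newick(self.tree, paths["tree"])
        io_core.write_fasta_alignment(self.alignment, paths["alignment"])
        io_core.write_regions(self.regions, paths["regions"])
        io_core.write_clade_map(self.clades, paths["clades"])
        for kind, trackset in self.tracks.items():
            paths[kind] = out / f"{kind}.tsv"
            io_core.write_track_tsv(trackset, paths[kind])
        with open(out / "true_rates.tsv", "w") as fh:
            fh.write("column0\t" + "\t".join(
                f"{t}_rate\t{t}_category" for t in self.true_site_rates)
                + "\n")
            for c in range(self.alignment.n_columns):
                cells = []
                for t in self.true_site_rates:
                    cells.append(f"{self.true_site_rates[t][c]:.6f}")
                    cells.append(str(int(self.true_categories[t][c])))
                fh.write(f"{c}\t" + "\t".join(cells) + "\n")
        paths["true_rates"] = out / "true_rates.tsv"
        return paths


#: conditions the generator emulates: clade sizes as in the vertebrate
#: p53/p63/p73 study set (101/102/98 sequences), ~900 alignment columns
#: with TAD/DBD/OD/SAM domains separated by linkers
PRESETS = {
    "tiny": dict(clade_sizes={"A": 4, "B": 4}, n_columns=60,
                 domains=[("D1", 10, 30), ("D2", 40, 55)]),
    "paper-shaped": dict(
        clade_sizes={"p53": 101, "p63": 102, "p73": 98}, n_columns=900,
        domains=[("TAD", 20, 110), ("DBD", 170, 400),
                 ("OD", 460, 540), ("SAM", 600, 670)]),
}

#: trait-process defaults: gamma shapes per trait and the predictor noise
DEFAULT_ALPHAS = {"disorder": 0.7, "ss": 0.7, "phospho": 0.7, "seq": 1.0}
DEFAULT_EPSILON = 0.05


def build_fixture_bundle(preset: str = "tiny", seed: int = 0,
                         out_dir: str | Path | None = None,
                         alphas: dict[str, float] | None = None,
                         epsilon: float = DEFAULT_EPSILON,
                         with_gaps: bool = True) -> SyntheticBundle:
    """Generate a complete bundle for a named preset.

    'tiny' is 8 taxa x 60 columns in 2 clades; 'paper-shaped' mirrors the
    study's dataset shape: 3 clades of 101/102/98 taxa and 900 columns
    with 4 domains (TAD/DBD/OD/SAM) separated by auto-labeled linkers.
    """
    if preset not in PRESETS:
        raise ValidationError(
            f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    params = PRESETS[preset]
    alphas = {**DEFAULT_ALPHAS, **(alphas or {})}
    rng = np.random.default_rng(seed)
    n_cols = params["n_columns"]

    subtrees = {}
    for clade, size in params["clade_sizes"].items():
        subtrees[clade] = simulate_yule_tree(
            size, seed=rng, depth=0.6, label_prefix=f"{clade}_")
    tree, clades = join_clades(subtrees)
    taxa = tree.leaf_labels

    aln_nogap, seq_rates_true, seq_cats = simulate_aa_alignment(
        tree, n_cols, alphas["seq"], seed=rng)

    if with_gaps:
        present = simulate_gap_mask(tree, n_cols, seed=rng)
        # a column absent everywhere would be unalignable; re-anchor it
        dead = ~present.any(axis=0)
        present[:, dead] = True
    else:
        present = np.ones((len(taxa), n_cols), dtype=bool)
    rows = []
    for i, label in enumerate(taxa):
        chars = np.array(list(aln_nogap.row(label)))
        chars[~present[i]] = GAP
        rows.append("".join(chars))
    alignment = Alignment(list(taxa), rows)

    binary_truth: dict[str, BinaryPhyleticMatrix] = {}
    true_rates = {"seq": seq_rates_true}
    true_cats = {"seq": seq_cats}
    for kind in ("disorder", "ss", "phospho"):
        mat, site_rates, cats = simulate_binary_trait_matrix(
            tree, n_cols, alphas[kind], seed=rng, kind=kind)
        if kind == "phospho":
            # phosphosites only exist on Ser/Thr/Tyr residues
            chars = alignment.char_matrix()
            sty = np.isin(chars, sorted(PHOSPHO_RESIDUES))
            mat.data[~sty & (mat.data == 1)] = 0
        binary_truth[kind] = mat
        true_rates[kind] = site_rates
        true_cats[kind] = cats

    tracks = {
        "disorder": simulate_propensity_tracks(
            binary_truth["disorder"], alignment, epsilon, seed=rng,
            cutoff=0.4, kind="disorder"),
        "ss": simulate_ss_tracks(binary_truth["ss"], alignment, epsilon,
                                 seed=rng),
        "phospho": simulate_propensity_tracks(
            binary_truth["phospho"], alignment, epsilon, seed=rng,
            cutoff=0.75, kind="phospho"),
    }
    # gap positions become missing in the truth matrices, as they would be
    # after projecting real predictor tracks onto the alignment
    gapped = alignment.gap_matrix()
    for mat in binary_truth.values():
        mat.data[gapped] = MISSING

    regions = RegionAnnotation(list(params["domains"]), n_cols)
    bundle = SyntheticBundle(
        tree=tree, alignment=alignment, tracks=tracks,
        binary_truth=binary_truth, true_site_rates=true_rates,
        true_categories=true_cats, true_alpha=dict(alphas),
        clades=clades, regions=regions, seed=seed)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
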