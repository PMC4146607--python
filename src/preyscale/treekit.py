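"""Dated-phylogeny handling: Newick I/O, pruning, polytomy resolution.

Trees are wrapped thinly around :mod:`dendropy`; all operations treat the
tree as rooted and dated (ultrametric within a relative tolerance), with
node *ages* measured back from the tips (tips at age ~0).

Polytomies are resolved stochastically by sequential random joins: within
each polytomy, two of its current children are picked uniformly at random
and joined at an age drawn uniformly between the older child's age and the
polytomy node's age.  Repeating over seeds yields an ensemble of binary
dated trees that agree with the input everywhere outside the polytomies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import ParameterError, UsageError, ValidationError
from .data_io import normalize_species_name

__all__ = [
    "Phylogeny",
    "TreeEnsemble",
    "read_newick",
    "read_ensemble",
    "prune",
    "find_polytomies",
    "resolve_polytomies",
]

#: default relative ultrametricity tolerance (fraction of tree height)
DEFAULT_REL_TOL = 1e-6


class Phylogeny:
    """A rooted dated tree with unique tip labels.

    Thin wrapper over ``dendropy.Tree``; construction validates rooting
    and label uniqueness and caches root-to-tip geometry.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._tree.is_rooted = True
        seed = self._tree.seed_node
        if seed is None:
            raise ValidationError("empty tree")
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError("duplicate tip labels", problems=dupes)
        self._refresh()

    def _refresh(self):
        for nd in self._tree.preorder_node_iter():
            parent = nd.parent_node
            bl = nd.edge.length or 0.0
            nd._root_distance = (parent._root_distance if parent else 0.0) + (
                bl if parent else 0.0
            )
        self._height = max(
            (lf._root_distance for lf in self._tree.leaf_node_iter()), default=0.0
        )

    # -- factories -------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as err:  # dendropy raises several reader errors
            raise ValidationError(f"could not parse Newick: {err}") from None
        return cls(tree)

    def clone(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    # -- geometry --------------------------------------------------------
    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    @property
    def height(self) -> float:
        """Maximum root-to-tip path length."""
        return self._height

    def node_age(self, node) -> float:
        """Age of a node: tree height minus its root distance."""
        return self._height - node._root_distance

    def root_distances(self) -> dict[str, float]:
        return {
            lf.taxon.label: lf._root_distance for lf in self._tree.leaf_node_iter()
        }

    def is_binary(self) -> bool:
        return all(
            len(nd.child_nodes()) == 2 for nd in self._tree.preorder_internal_node_iter()
        )

    def is_ultrametric(self, rel_tol: float = DEFAULT_REL_TOL) -> bool:
        dists = [lf._root_distance for lf in self._tree.leaf_node_iter()]
        if not dists:
            return True
        tol = rel_tol * self._height if self._height > 0 else rel_tol
        return max(dists) - min(dists) <= tol

    def zero_length_terminals(self) -> list[str]:
        """Tip labels whose terminal branch has zero length (reported, permitted)."""
        return [
            lf.taxon.label
            for lf in self._tree.leaf_node_iter()
            if not (lf.edge.length or 0.0) > 0.0
        ]

    # -- serialization ---------------------------------------------------
    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".10g",
        )
        return s.strip()

    def write_newick(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick() + "\n")

    def __repr__(self):
        return f"<Phylogeny n_tips={self.n_tips} height={self.height:.4g}>"


@dataclass
class TreeEnsemble:
    """Ordered collection of binary dated trees sharing one tip set."""

    trees: list[Phylogeny]
    seeds: list[int] = field(default_factory=list)

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    def validate(self, rel_tol: float = DEFAULT_REL_TOL) -> None:
        if not self.trees:
            raise ValidationError("empty ensemble")
        tips0 = set(self.trees[0].tip_labels)
        for i, t in enumerate(self.trees):
            if set(t.tip_labels) != tips0:
                raise ValidationError(f"tree {i} has a different tip set")
            if not t.is_binary():
                raise ValidationError(f"tree {i} is not binary")
            if not t.is_ultrametric(rel_tol):
                raise ValidationError(f"tree {i} is not ultrametric")

    def write(self, path) -> None:
        """One Newick per line; seeds recorded in a leading comment line."""
        with open(path, "w", encoding="utf-8") as fh:
            if self.seeds:
                fh.write("[&preyscale seeds=" + ",".join(map(str, self.seeds)) + "]\n")
            for t in self.trees:
                fh.write(t.to_newick() + "\n")


def read_newick(path) -> Phylogeny:
    """Read the first tree from a Newick file."""
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("[&preyscale"):
                return Phylogeny.from_newick(line)
    raise ValidationError(f"no tree found in {path}")


def read_ensemble(path) -> TreeEnsemble:
    """Read a one-tree-per-line Newick file into a TreeEnsemble."""
    trees, seeds = [], []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("[&preyscale"):
                inner = line.strip("[]").split("seeds=")
                if len(inner) == 2 and inner[1]:
                    seeds = [int(s) for s in inner[1].split(",") if s]
                continue
            trees.append(Phylogeny.from_newick(line))
    if not trees:
        raise ValidationError(f"no trees found in {path}")
    return TreeEnsemble(trees=trees, seeds=seeds)


def prune(phylo: Phylogeny, keep: set[str]) -> Phylogeny:
    """Prune to exactly the tips in ``keep``.

    Degree-2 nodes created by pruning are suppressed with branch lengths
    summed, so the root-to-tip depth of every retained tip is unchanged.
    Tip matching normalizes whitespace/underscores.
    """
    by_norm = {}
    for lab in phylo.tip_labels:
        by_norm.setdefault(normalize_species_name(lab), lab)
    keep_norm = {normalize_species_name(k) for k in keep}
    missing = sorted(keep_norm - set(by_norm))
    if missing:
        raise ValidationError(
            f"{len(missing)} species not found in tree", problems=missing
        )
    labels = [by_norm[k] for k in keep_norm]
    tree = phylo.dendropy_tree.clone(depth=1)
    tree.migrate_taxon_namespace(dendropy.TaxonNamespace())
    taxa = [t for t in tree.taxon_namespace if t.label in set(labels)]
    tree.retain_taxa(taxa)
    tree.purge_taxon_namespace()
    return Phylogeny(tree)


def find_polytomies(phylo: Phylogeny) -> list[tuple[object, int]]:
    """Every internal node with more than two children, with its child count."""
    return [
        (nd, len(nd.child_nodes()))
        for nd in phylo.dendropy_tree.preorder_internal_node_iter()
        if len(nd.child_nodes()) > 2
    ]


def _resolve_one(phylo: Phylogeny, rng: np.random.Generator) -> Phylogeny:
    out = phylo.clone()
    tree = out.dendropy_tree
    for node, _deg in find_polytomies(out):
        node_age = out.node_age(node)
        children = list(node.child_nodes())
        ages = {id(ch): node_age - (ch.edge.length or 0.0) for ch in children}
        while len(children) > 2:
            i, j = sorted(rng.choice(len(children), size=2, replace=False))
            ci, cj = children[i], children[j]
            lo = max(ages[id(ci)], ages[id(cj)])
            new_age = float(rng.uniform(lo, node_age))
            for ch in (ci, cj):
                node.remove_child(ch)
            joined = dendropy.Node()
            joined.add_child(ci)
            joined.add_child(cj)
            ci.edge.length = new_age - ages[id(ci)]
            cj.edge.length = new_age - ages[id(cj)]
            node.add_child(joined)
            joined.edge.length = node_age - new_age
            ages[id(joined)] = new_age
            children = [ch for k, ch in enumerate(children) if k not in (i, j)]
            children.append(joined)
    return Phylogeny(tree)


def resolve_polytomies(
    phylo: Phylogeny,
    n_trees: int,
    seed: int,
    rel_tol: float = DEFAULT_REL_TOL,
) -> TreeEnsemble:
    """Resolve all polytomies into an ensemble of ``n_trees`` binary dated trees.

    Each member randomizes both the join order (topology) and the new
    internal-node ages within every polytomy; the tip set and the ages of
    all pre-existing nodes are preserved.  Reproducible given ``seed``.
    """
    if n_trees < 1:
        raise ParameterError(f"n_trees must be >= 1, got {n_trees}")
    if not phylo.is_ultrametric(rel_tol):
        raise ValidationError(
            "input tree is not ultrametric within tolerance; cannot date resolutions"
        )
    child_seqs = np.random.SeedSequence(seed).spawn(n_trees)
    trees, seeds = [], []
    for seq in child_seqs:
        rng = np.random.default_rng(seq)
        trees.append(_resolve_one(phylo, rng))
        seeds.append(int(seq.generate_state(1)[0]))
    ensemble = TreeEnsemble(trees=trees, seeds=seeds)
    ensemble.validate(rel_tol=max(rel_tol, DEFAULT_REL_TOL))
    return ensemble
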