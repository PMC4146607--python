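"""Synthetic trees and trait tables with the structure the analysis assumes.

Trees come from a birth-death process conditioned on the number of
surviving tips; a configurable fraction of internal edges is then
collapsed to create soft polytomies.  Traits follow the generative model
the PGLS fits:

    y = b0 + b_mass * m + b_env * e + b_int * m * e
        + taxonomic effects + MVN(0, sigma2 * V(lambda_true))

with log10 predator mass ``m`` drawn i.i.d. normal and environment ``e``
assigned either to whole clades (the default — aquatic lineages are
phylogenetically clustered in the real data, which is exactly the
confound lambda addresses) or at random.  Taxonomy labels are derived by
slicing the tree at fixed relative depths so taxonomic and phylogenetic
structure agree; per-level random intercepts with configurable SDs
provide taxonomic variance structure.  Prey maximum is prey minimum plus
a positive kg offset whose log10 has its own regression on mass, so
``prey_max > prey_min`` always holds.
"""

from __future__ import annotations

import random as _pyrandom
import zlib
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
import scipy.linalg as sla
from dendropy.model import birthdeath

from .data_io import TraitTable
from .errors import ParameterError, ValidationError
from .phylo_gls import apply_lambda, phylo_covariance
from .treekit import Phylogeny, resolve_polytomies

__all__ = ["SimulationConfig", "simulate_tree", "simulate_traits", "simulate_dataset"]

_MAX_TREE_RETRIES = 25


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for tree and trait generation (see module docstring)."""

    n_species: int = 108
    birth_rate: float = 1.0
    death_rate: float = 0.2
    polytomy_fraction: float = 0.0
    # taxonomy: tree is cut at these ages (as fractions of height), deepest
    # first -> order / family / genus; per-level effect SDs add taxonomic
    # variance to the response.
    taxonomy_cut_fractions: tuple[float, float, float] = (0.75, 0.5, 0.25)
    taxonomy_level_sds: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # generative regression
    beta0: float = -1.0
    beta_mass: float = 1.0
    beta_env: float = 0.0
    beta_interaction: float = 0.0
    lambda_true: float = 1.0
    sigma2: float = 0.25
    # environment assignment
    env_mode: str = "clade"  # or "random"
    aquatic_fraction: float = 0.5
    # predator mass distribution (log10 kg)
    log_mass_mean: float = 1.0
    log_mass_sd: float = 1.0
    # prey_max = prey_min + 10**(gap0 + gap_mass * m + N(0, gap_sd^2))
    gap_intercept: float = -0.3
    gap_mass_slope: float = 0.5
    gap_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ParameterError("n_species must be >= 2")
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ParameterError("birth and death rates must be >= 0")
        if not 0.0 <= self.polytomy_fraction <= 1.0:
            raise ParameterError("polytomy_fraction must be in [0, 1]")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ParameterError("lambda_true must be in [0, 1]")
        if self.sigma2 <= 0:
            raise ParameterError("sigma2 must be > 0")
        if self.env_mode not in ("clade", "random"):
            raise ParameterError(f"unknown env_mode {self.env_mode!r}")
        fr = self.taxonomy_cut_fractions
        if not (0 < fr[2] < fr[1] < fr[0] < 1):
            raise ParameterError(
                "taxonomy_cut_fractions must be strictly decreasing in (0, 1)"
            )


def _seed_for(config: SimulationConfig, stage: str) -> np.random.SeedSequence:
    # stable (non-salted) stage hash so identical configs reproduce exactly
    stage_key = zlib.crc32(stage.encode("utf-8"))
    return np.random.SeedSequence((config.seed, stage_key))


def simulate_tree(config: SimulationConfig) -> Phylogeny:
    """Birth-death tree on ``n_species`` extant tips, optionally with polytomies.

    Total extinction triggers a bounded retry with an incremented seed.
    ``polytomy_fraction`` of the internal (non-root) edges are collapsed,
    children reattached to the grandparent with summed branch lengths, so
    the tree stays ultrametric.
    """
    seq = _seed_for(config, "tree")
    base = int(seq.generate_state(1)[0])
    tree = None
    for attempt in range(_MAX_TREE_RETRIES):
        rng = _pyrandom.Random(base + attempt)
        try:
            tree = birthdeath.birth_death_tree(
                birth_rate=config.birth_rate,
                death_rate=config.death_rate,
                num_extant_tips=config.n_species,
                rng=rng,
            )
            break
        except birthdeath.TreeSimTotalExtinctionException:
            continue
    if tree is None:
        raise ValidationError(
            f"birth-death simulation went extinct {_MAX_TREE_RETRIES} times"
        )
    # The simulator stops exactly at the n-th speciation, leaving a
    # zero-length cherry (singular covariance).  Extend every terminal
    # branch by the waiting time to the next event, drawn once, which
    # keeps the tree ultrametric and the process exact.
    rate = config.n_species * (config.birth_rate + config.death_rate)
    hold = _pyrandom.Random(base - 1).expovariate(rate) if rate > 0 else 0.0
    for i, lf in enumerate(tree.leaf_node_iter()):
        lf.taxon.label = f"tip{i:04d}"
        lf.edge.length = (lf.edge.length or 0.0) + hold
    phylo = Phylogeny(tree)

    if config.polytomy_fraction > 0:
        rng_np = np.random.default_rng(_seed_for(config, "collapse"))
        internal = [
            nd
            for nd in tree.preorder_internal_node_iter()
            if nd.parent_node is not None
        ]
        n_collapse = int(round(config.polytomy_fraction * len(internal)))
        if n_collapse:
            chosen = rng_np.choice(len(internal), size=n_collapse, replace=False)
            for idx in sorted(chosen):
                nd = internal[idx]
                # may already have been absorbed by a parent collapse
                if nd.parent_node is not None and not nd.is_leaf():
                    nd.edge.collapse(adjust_collapsed_head_children_edge_lengths=True)
        phylo = Phylogeny(tree)
    return phylo


def _taxonomy_groups(phylo: Phylogeny, fraction: float) -> dict[str, int]:
    """Partition tips by the branch crossing age ``fraction * height``.

    Each tip's group is its most ancient ancestor strictly younger than
    the cut age (the child end of the crossing edge).
    """
    cut_age = fraction * phylo.height
    tree = phylo.dendropy_tree
    group_of = {}
    counter = 0
    ids = {}
    for nd in tree.preorder_node_iter():
        parent = nd.parent_node
        age = phylo.node_age(nd)
        parent_age = phylo.node_age(parent) if parent is not None else np.inf
        if age <= cut_age < parent_age:
            ids[nd] = counter
            counter += 1
    for lf in tree.leaf_node_iter():
        nd = lf
        while nd is not None and nd not in ids:
            nd = nd.parent_node
        group_of[lf.taxon.label] = ids[nd] if nd is not None else 0
    return group_of


def _assign_environment(phylo: Phylogeny, config: SimulationConfig, rng) -> dict[str, str]:
    labels = phylo.tip_labels
    n = len(labels)
    target = config.aquatic_fraction * n
    if config.env_mode == "random":
        aquatic = set(
            rng.choice(labels, size=int(round(target)), replace=False).tolist()
        ) if target >= 1 else set()
    else:
        # greedy: add non-overlapping clades, largest first, while they
        # improve the distance to the target aquatic count
        clades = []
        for nd in phylo.dendropy_tree.preorder_internal_node_iter():
            if nd.parent_node is None:
                continue
            tips = [lf.taxon.label for lf in nd.leaf_iter()]
            if len(tips) < n:
                clades.append(tips)
        aquatic: set[str] = set()
        while True:
            remaining = target - len(aquatic)
            if remaining <= 0:
                break
            candidates = [c for c in clades if not aquatic.intersection(c)]
            if not candidates:
                break
            best = min(candidates, key=lambda c: abs(len(c) - remaining))
            # accept only if it brings the aquatic count closer to target
            if abs(len(best) - remaining) >= abs(remaining):
                break
            aquatic.update(best)
    return {lab: ("aquatic" if lab in aquatic else "terrestrial") for lab in labels}


def simulate_traits(
    phylo: Phylogeny, config: SimulationConfig, return_details: bool = False
):
    """Generate a TraitTable on a tree under the lambda-Brownian model.

    A polytomous input is first resolved once at random (the generative
    covariance needs a binary dated tree).  With ``return_details=True``
    the generative internals (design, residuals, coefficients) are also
    returned for calibration tests.
    """
    if not phylo.is_binary():
        phylo = resolve_polytomies(
            phylo, 1, seed=int(_seed_for(config, "resolve").generate_state(1)[0])
        )[0]
    rng = np.random.default_rng(_seed_for(config, "traits"))
    labels = phylo.tip_labels
    n = len(labels)

    order_of = _taxonomy_groups(phylo, config.taxonomy_cut_fractions[0])
    family_of = _taxonomy_groups(phylo, config.taxonomy_cut_fractions[1])
    genus_of = _taxonomy_groups(phylo, config.taxonomy_cut_fractions[2])
    env_of = _assign_environment(phylo, config, rng)

    m = rng.normal(config.log_mass_mean, config.log_mass_sd, size=n)
    e = np.array([1.0 if env_of[lab] == "terrestrial" else 0.0 for lab in labels])
    X = np.column_stack([np.ones(n), m, e, m * e])
    beta = np.array(
        [config.beta0, config.beta_mass, config.beta_env, config.beta_interaction]
    )

    u = np.zeros(n)
    for groups, sd in zip(
        (order_of, family_of, genus_of), config.taxonomy_level_sds
    ):
        if sd > 0:
            ids = sorted(set(groups.values()))
            effects = rng.normal(0.0, sd, size=len(ids))
            lookup = dict(zip(ids, effects))
            u += np.array([lookup[groups[lab]] for lab in labels])

    V = apply_lambda(phylo_covariance(phylo, labels), config.lambda_true)
    L = sla.cholesky(config.sigma2 * V, lower=True)
    eps = L @ rng.standard_normal(n)
    y = X @ beta + u + eps

    gap_log = (
        config.gap_intercept
        + config.gap_mass_slope * m
        + rng.normal(0.0, config.gap_sd, size=n)
    )
    prey_min = 10.0 ** y
    prey_max = prey_min + 10.0 ** gap_log

    genus_names = [f"G{genus_of[lab]:03d}" for lab in labels]
    df = pd.DataFrame(
        {
            "species": [f"{g}_{lab}" for g, lab in zip(genus_names, labels)],
            "order": [f"O{order_of[lab]:02d}" for lab in labels],
            "family": [f"F{family_of[lab]:03d}" for lab in labels],
            "genus": genus_names,
            "environment": [env_of[lab] for lab in labels],
            "predator_mass": 10.0 ** m,
            "prey_min": prey_min,
            "prey_max": prey_max,
        }
    )
    table = TraitTable.from_frame(df)
    if return_details:
        details = {
            "tree": phylo,
            "tip_labels": labels,
            "y": y,
            "X": X,
            "beta": beta,
            "taxonomic_effects": u,
            "residuals": eps,
            "V_lambda": V,
            "species": df["species"].tolist(),
        }
        return table, details
    return table


def simulate_dataset(config: SimulationConfig, return_details: bool = False):
    """Convenience: simulate a tree and matching traits in one call.

    Returns ``(table, phylo)`` — the phylogeny's tips are renamed to the
    trait table's species names so the pair feeds the analysis directly.
    With ``polytomy_fraction > 0`` the returned tree keeps its polytomies
    (the realistic pipeline input); the traits were generated on a random
    resolution of it, retrievable via ``return_details=True``.
    """
    phylo = simulate_tree(config)
    out = simulate_traits(phylo, config, return_details=return_details)
    table = out[0] if return_details else out
    resolved = out[1]["tree"] if return_details else phylo
    # rename tips to the generated binomials (Genus_tipNNNN)
    renamed = resolved.clone()
    name_of = dict(zip(
        [s.split("_", 1)[1] for s in table.species], table.species
    ))
    for lf in renamed.dendropy_tree.leaf_node_iter():
        lf.taxon.label = name_of[lf.taxon.label]
    if return_details:
        out[1]["tree"] = renamed
        return table, renamed, out[1]
    return table, renamed
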