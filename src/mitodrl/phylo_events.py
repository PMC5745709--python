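"""Map a gene-order character onto a fixed species tree by parsimony.

The gene order observed in each individual is treated as an unordered
multistate character at the tips of a rooted binary tree; the minimum
number of state changes (each rearrangement event = one change) and one
most-parsimonious edge placement of those changes are computed.  Trees are
read from Newick via dendropy; branch lengths are ignored.

Within-species gene-order polymorphism is handled by expanding polymorphic
species into one tip per individual
(:func:`polymorphic_species_expand`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import dendropy

__all__ = [
    "PhyloTree",
    "FitchResult",
    "Placement",
    "load_tree",
    "fitch_min_changes",
    "polymorphic_species_expand",
]


@dataclass(frozen=True)
class Placement:
    """One inferred change on the edge parent -> child."""

    edge: tuple[str, str]
    from_state: str
    to_state: str


@dataclass(frozen=True)
class FitchResult:
    min_changes: int
    placements: tuple[Placement, ...]
    ancestral_sets: dict[str, frozenset[str]]
    n_mprs: int


class PhyloTree:
    """Rooted binary tree over named tips (thin wrapper around dendropy)."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._name_internal_nodes()
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(tips) != len(set(tips)):
            raise ValueError("tip names must be unique")
        self.tip_names = tuple(tips)
        for node in tree.preorder_node_iter():
            if not node.is_leaf() and len(node.child_nodes()) not in (2,) and node is not tree.seed_node:
                raise ValueError("tree must be binary (after rooting)")

    def _name_internal_nodes(self) -> None:
        counter = 0
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                node._mdrl_name = node.taxon.label
            else:
                node._mdrl_name = f"node{counter}"
                counter += 1

    @classmethod
    def from_newick(cls, newick: str, outgroup: str | None = None) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls._prepare(tree, outgroup)

    @classmethod
    def from_file(cls, path, outgroup: str | None = None) -> "PhyloTree":
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
        return cls._prepare(tree, outgroup)

    @classmethod
    def _prepare(cls, tree: dendropy.Tree, outgroup: str | None) -> "PhyloTree":
        if outgroup is not None:
            og = tree.find_node_with_taxon_label(outgroup)
            if og is None:
                raise ValueError(f"outgroup tip {outgroup!r} not in tree")
            tree.to_outgroup_position(og, update_bipartitions=False)
        _binarize(tree)
        return cls(tree)

    @property
    def root(self):
        return self._tree.seed_node


def _binarize(tree: dendropy.Tree) -> None:
    """Resolve polytomies (including a basal trifurcation from unrooted
    input) arbitrarily but deterministically; Fitch counts are unaffected."""
    tree.suppress_unifurcations()
    tree.resolve_polytomies(update_bipartitions=False)


def load_tree(path, outgroup: str | None = None) -> PhyloTree:
    return PhyloTree.from_file(path, outgroup=outgroup)


def polymorphic_species_expand(
    states_by_individual: Mapping[str, str],
    species_map: Mapping[str, str],
) -> dict[str, str]:
    """Turn per-individual states into a tip state map.

    Species whose individuals all share one state contribute a single tip
    named after the species; species observed in multiple states contribute
    one tip per individual (named after the individual), so within-species
    polymorphism is representable on the tree.
    """
    by_species: dict[str, dict[str, str]] = {}
    for indiv, state in states_by_individual.items():
        if indiv not in species_map:
            raise ValueError(f"individual {indiv!r} has no species assignment")
        by_species.setdefault(species_map[indiv], {})[indiv] = state
    tip_states: dict[str, str] = {}
    for species, members in by_species.items():
        states = set(members.values())
        if len(states) == 1:
            tip_states[species] = states.pop()
        else:
            for indiv, state in members.items():
                tip_states[indiv] = state
    return tip_states


def fitch_min_changes(tree: PhyloTree, states: Mapping[str, str]) -> FitchResult:
    """Minimum number of unordered state changes on the tree, with one
    most-parsimonious reconstruction.

    The bottom-up pass is classic Fitch (set intersection/union); the
    returned reconstruction and the count of most-parsimonious
    reconstructions come from a unit-cost dynamic program over states.
    Ties in the top-down pass are broken by preferring the parent's state.
    """
    missing = [t for t in tree.tip_names if t not in states]
    if missing:
        raise ValueError(f"tips missing from state map: {missing}")
    state_space = sorted(set(states[t] for t in tree.tip_names))

    # --- Fitch bottom-up sets (reported as ancestral_sets)
    fitch_sets: dict[str, frozenset[str]] = {}
    union_count = 0
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            fitch_sets[node._mdrl_name] = frozenset({states[node._mdrl_name]})
        else:
            children = node.child_nodes()
            acc = fitch_sets[children[0]._mdrl_name]
            for child in children[1:]:
                nxt = acc & fitch_sets[child._mdrl_name]
                if not nxt:
                    nxt = acc | fitch_sets[child._mdrl_name]
                    union_count += 1
                acc = nxt
            fitch_sets[node._mdrl_name] = acc

    # --- unit-cost Sankoff DP: exact min changes and MPR count
    INF = float("inf")
    cost: dict[str, dict[str, float]] = {}
    ways: dict[str, dict[str, int]] = {}
    for node in tree._tree.postorder_node_iter():
        name = node._mdrl_name
        if node.is_leaf():
            cost[name] = {s: (0 if s == states[name] else INF) for s in state_space}
            ways[name] = {s: (1 if s == states[name] else 0) for s in state_space}
        else:
            cost[name] = {}
            ways[name] = {}
            for s in state_space:
                total, combos = 0.0, 1
                for child in node.child_nodes():
                    cname = child._mdrl_name
                    best = min(
                        cost[cname][t] + (0 if t == s else 1) for t in state_space
                    )
                    nways = sum(
                        ways[cname][t]
                        for t in state_space
                        if cost[cname][t] + (0 if t == s else 1) == best
                    )
                    total += best
                    combos *= nways
                cost[name][s] = total
                ways[name][s] = combos
    root = tree.root._mdrl_name
    min_changes = min(cost[root].values())
    n_mprs = sum(ways[root][s] for s in state_space if cost[root][s] == min_changes)

    # --- one MPR, top-down, preferring the parent's state on ties
    assignment: dict[str, str] = {}
    placements: list[Placement] = []
    for node in tree._tree.preorder_node_iter():
        name = node._mdrl_name
        parent = node.parent_node
        if parent is None:
            best = min(cost[name].values())
            assignment[name] = next(
                s for s in state_space if cost[name][s] == best
            )
        else:
            pstate = assignment[parent._mdrl_name]
            best = min(
                cost[name][t] + (0 if t == pstate else 1) for t in state_space
            )
            if cost[name][pstate] == best:
                chosen = pstate  # tie-break: keep the parent's state
            else:
                chosen = next(
                    t
                    for t in state_space
                    if cost[name][t] + (0 if t == pstate else 1) == best
                )
            assignment[name] = chosen
            if chosen != pstate:
                placements.append(
                    Placement(
                        edge=(parent._mdrl_name, name),
                        from_state=pstate,
                        to_state=chosen,
                    )
                )
    assert len(placements) == int(min_changes), "reconstruction/count mismatch"
    return FitchResult(
        min_changes=int(min_changes),
        placements=tuple(placements),
        ancestral_sets=fitch_sets,
        n_mprs=int(n_mprs),
    )
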