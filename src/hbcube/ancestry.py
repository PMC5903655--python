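"""Parsimony polarization of amino-acid substitutions on a rooted tree.

Implements equal-cost (Fitch) parsimony for single amino-acid sites.
State sets per internal node are the exact most-parsimonious-
reconstruction (MPR) sets, obtained with a unit-cost dynamic program
(up pass + down pass), which generalizes the classic Fitch
intersection/union passes to multifurcating trees and yields the exact
minimum change count in all cases.  Branch substitution assignment
distinguishes certain, ambiguous-state and ambiguous-placement changes
rather than picking arbitrarily.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import pandas as pd

from .errors import (
    InvalidParameterError,
    MissingTaxonError,
    UnresolvedStateError,
)
from .landscape import AMINO_ACIDS, Genotype, SiteDef

__all__ = [
    "PhyloTree",
    "SiteStateMatrix",
    "AncestralReconstruction",
    "BranchEvent",
    "fitch_parsimony",
    "reconstruct_all",
    "assign_branches",
    "ancestral_states",
    "ancestral_genotype",
]

_INF = math.inf


class PhyloTree:
    """A rooted tree with uniquely labelled tips and labelled internal nodes.

    Internal nodes lacking labels are auto-labelled N1, N2, ... in
    preorder so branches can be addressed stably by their child node.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(tips) != len(set(tips)):
            raise InvalidParameterError("tip labels must be unique")
        if len(tips) < 3:
            raise InvalidParameterError(">=3 tips required for polarization")
        self._label_internals()

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        tree.is_rooted = True
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=False, unquoted_underscores=True
        ).strip()

    def _label_internals(self) -> None:
        i = 0
        seen = set(self.tip_labels)
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            label = node.taxon.label if node.taxon else node.label
            if not label:
                i += 1
                while f"N{i}" in seen:
                    i += 1
                label = f"N{i}"
            node.label = label
            seen.add(label)

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def node_label(self, node: dendropy.Node) -> str:
        return node.taxon.label if node.is_leaf() else node.label

    def find_node(self, label: str) -> dendropy.Node:
        for node in self.tree.preorder_node_iter():
            if self.node_label(node) == label:
                return node
        raise MissingTaxonError(f"no node labelled {label!r}")

    def mrca(self, tip_labels: Sequence[str]) -> str:
        taxa = [self.tree.taxon_namespace.get_taxon(t) for t in tip_labels]
        if any(t is None for t in taxa):
            raise MissingTaxonError(f"unknown tip in {list(tip_labels)}")
        node = self.tree.mrca(taxa=taxa)
        return self.node_label(node)


@dataclass
class SiteStateMatrix:
    """Taxon x site one-letter amino-acid states."""

    states: dict[str, dict[str, str]]  # taxon -> site -> letter

    def __post_init__(self) -> None:
        for taxon, row in self.states.items():
            for site, letter in row.items():
                if len(letter) != 1 or letter not in AMINO_ACIDS:
                    raise InvalidParameterError(
                        f"bad state {letter!r} for taxon {taxon!r}, site {site!r}"
                    )

    @property
    def taxa(self) -> list[str]:
        return list(self.states)

    @property
    def sites(self) -> list[str]:
        seen: dict[str, None] = {}
        for row in self.states.values():
            for s in row:
                seen.setdefault(s)
        return list(seen)

    def state(self, taxon: str, site: str) -> str:
        try:
            return self.states[taxon][site]
        except KeyError:
            raise MissingTaxonError(
                f"no state for taxon {taxon!r} at site {site!r}"
            ) from None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SiteStateMatrix":
        """Rows = taxa (index or 'taxon' column), columns = sites."""
        if "taxon" in df.columns:
            df = df.set_index("taxon")
        return cls(
            {str(t): {str(s): str(df.at[t, s]) for s in df.columns} for t in df.index}
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.states, orient="index")
        df.index.name = "taxon"
        return df


@dataclass
class BranchEvent:
    """A (possible) state change on the branch above ``child_label``."""

    site: str
    child_label: str
    from_states: frozenset[str]
    to_states: frozenset[str]
    certain: bool  # a change occurs on this branch in every MPR

    @property
    def resolved(self) -> bool:
        return (
            self.certain
            and len(self.from_states) == 1
            and len(self.to_states) == 1
        )

    @property
    def substitution(self) -> tuple[str, str] | None:
        if self.resolved:
            return (next(iter(self.from_states)), next(iter(self.to_states)))
        return None


@dataclass
class AncestralReconstruction:
    """Per-site MPR state sets, minimum change counts and branch events."""

    tree: PhyloTree
    node_states: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)
    change_counts: dict[str, int] = field(default_factory=dict)
    events: dict[str, list[BranchEvent]] = field(default_factory=dict)

    @property
    def sites(self) -> list[str]:
        return list(self.change_counts)

    def states_at(self, site: str, node_label: str) -> frozenset[str]:
        return self.node_states[site][node_label]

    def merge(self, other: "AncestralReconstruction") -> "AncestralReconstruction":
        if other.tree is not self.tree:
            raise InvalidParameterError("reconstructions are on different trees")
        self.node_states.update(other.node_states)
        self.change_counts.update(other.change_counts)
        self.events.update(other.events)
        return self


def _site_dp(
    tree: PhyloTree, matrix: SiteStateMatrix, site: str
) -> tuple[list[str], dict, dict, int]:
    """Unit-cost up/down dynamic program for one site.

    Returns (alphabet, up, down, min_changes) where up[node][s] is the
    minimal change count within the subtree of ``node`` given state s at
    ``node`` and down[node][s] the minimal count outside it.
    """
    tips = tree.tip_labels
    for t in tips:
        if t not in matrix.states or site not in matrix.states[t]:
            raise MissingTaxonError(f"taxon {t!r} missing from matrix at site {site!r}")
    alphabet = sorted({matrix.state(t, site) for t in tips})

    up: dict[dendropy.Node, dict[str, float]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            obs = matrix.state(node.taxon.label, site)
            up[node] = {s: (0.0 if s == obs else _INF) for s in alphabet}
        else:
            up[node] = {
                s: sum(
                    min(up[c][t] + (s != t) for t in alphabet)
                    for c in node.child_nodes()
                )
                for s in alphabet
            }

    root = tree.tree.seed_node
    down: dict[dendropy.Node, dict[str, float]] = {root: {s: 0.0 for s in alphabet}}
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        for child in children:
            sib_cost = {
                s: sum(
                    min(up[c][t] + (s != t) for t in alphabet)
                    for c in children
                    if c is not child
                )
                for s in alphabet
            }
            down[child] = {
                t: min(
                    down[node][s] + sib_cost[s] + (s != t) for s in alphabet
                )
                for t in alphabet
            }

    min_changes = int(min(up[root].values()))
    return alphabet, up, down, min_changes


def fitch_parsimony(
    tree: PhyloTree, matrix: SiteStateMatrix, site: str
) -> AncestralReconstruction:
    """Exact minimum-change reconstruction for one site.

    Node state sets contain every state appearing at that node in at
    least one most parsimonious reconstruction.  Branch events record
    where changes are certain (every MPR) or merely possible, with the
    endpoint state sets over change-bearing MPRs; nothing is resolved
    arbitrarily.
    """
    alphabet, up, down, min_changes = _site_dp(tree, matrix, site)
    total = {
        node: {s: up[node][s] + down[node][s] for s in alphabet}
        for node in tree.tree.preorder_node_iter()
    }

    node_states: dict[str, frozenset[str]] = {}
    for node in tree.tree.preorder_node_iter():
        node_states[tree.node_label(node)] = frozenset(
            s for s in alphabet if total[node][s] == min_changes
        )

    events: list[BranchEvent] = []
    for node in tree.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        siblings = [c for c in parent.child_nodes() if c is not node]
        sib_cost = {
            s: sum(
                min(up[c][t] + (s != t) for t in alphabet) for c in siblings
            )
            for s in alphabet
        }
        # joint[s, t]: minimal total changes with parent=s and child=t
        best_change = _INF
        best_same = _INF
        from_states: set[str] = set()
        to_states: set[str] = set()
        for s in alphabet:
            base = down[parent][s] + sib_cost[s]
            for t in alphabet:
                joint = base + (s != t) + up[node][t]
                if s == t:
                    best_same = min(best_same, joint)
                else:
                    if joint < best_change:
                        best_change = joint
                        from_states, to_states = {s}, {t}
                    elif joint == best_change:
                        from_states.add(s)
                        to_states.add(t)
        change_possible = best_change == min_changes
        change_certain = change_possible and best_same > min_changes
        if change_possible:
            events.append(
                BranchEvent(
                    site=site,
                    child_label=tree.node_label(node),
                    from_states=frozenset(from_states),
                    to_states=frozenset(to_states),
                    certain=change_certain,
                )
            )

    return AncestralReconstruction(
        tree=tree,
        node_states={site: node_states},
        change_counts={site: min_changes},
        events={site: events},
    )


def reconstruct_all(
    tree: PhyloTree, matrix: SiteStateMatrix
) -> AncestralReconstruction:
    """Run :func:`fitch_parsimony` for every site in the matrix."""
    recon = AncestralReconstruction(tree=tree)
    for site in matrix.sites:
        recon.merge(fitch_parsimony(tree, matrix, site))
    return recon


def assign_branches(
    recon: AncestralReconstruction,
) -> dict[str, list[BranchEvent]]:
    """Branch label -> events, certain-and-resolved substitutions first.

    A substitution is asserted only where the change is certain and both
    endpoint state sets are singletons; everything else stays flagged as
    ambiguous via ``BranchEvent.certain``/``resolved``.
    """
    out: dict[str, list[BranchEvent]] = {}
    for site_events in recon.events.values():
        for ev in site_events:
            out.setdefault(ev.child_label, []).append(ev)
    for events in out.values():
        events.sort(key=lambda e: (not e.resolved, e.site))
    return out


def ancestral_states(
    recon: AncestralReconstruction, node_label: str, sites: Sequence[str]
) -> str:
    """Concatenated resolved states at ``node_label`` for ``sites``.

    Raises :class:`UnresolvedStateError` on any ambiguous (non-singleton)
    state set rather than picking a state.
    """
    letters = []
    for site in sites:
        states = recon.node_states[site][node_label]
        if len(states) != 1:
            raise UnresolvedStateError(
                f"node {node_label!r} is ambiguous at site {site!r}: "
                f"{sorted(states)}"
            )
        letters.append(next(iter(states)))
    return "".join(letters)


def ancestral_genotype(
    recon: AncestralReconstruction,
    node_label: str,
    sites: Sequence[SiteDef],
) -> Genotype:
    """Resolved states at a node as a landscape :class:`Genotype`."""
    code = ancestral_states(recon, node_label, [s.label for s in sites])
    return Genotype.from_code(sites, code)
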