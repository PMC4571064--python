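"""Simulation of gene genealogies within a species tree or network.

Sampled lineages start at the species tips (time 0) and move rootward.  On
each branch of the network an independent coalescent process runs with that
branch's coalescent parameter for the branch's duration; lineages that fail
to coalesce are handed intact to the parent branch (censored-coalescent
semantics).  Where branches join, lineage sets pool.  At a hybrid node each
lineage independently follows the left parent branch with the node's
inheritance probability gamma, else the right one.  Above the network root
the root branch's coalescent parameter and population size apply until the
grand most recent common ancestor is reached.

Event heights are measured from the present (tips at height 0), increasing
rootward, in coalescent units.  Each gene-tree branch records the network
branches it traversed, so it can later be rescaled to generations (and
expected mutations) piecewise across population boundaries.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .network_io import (
    BranchAttributes,
    SpeciesNetwork,
    ValidationError,
    check_ultrametric,
)
from .rates import CoalescentParameter, CoalescentState, sample_event

__all__ = [
    "GeneTreeNode",
    "GeneTree",
    "simulate_within_branch",
    "route_at_hybrid",
    "simulate_gene_tree",
    "rescale_tree",
]


@dataclass(eq=False)
class GeneTreeNode:
    """A node of a simulated genealogy.

    ``segments`` records, for the branch above this node, the network
    branches traversed as (start height, end height, BranchAttributes)
    triples covering [height, parent.height).
    """

    label: str = ""
    height: float = 0.0
    children: List["GeneTreeNode"] = field(default_factory=list)
    parent: Optional["GeneTreeNode"] = None
    segments: List[Tuple[float, float, BranchAttributes]] = field(default_factory=list)
    length_gen: Optional[float] = None
    length_mut: Optional[float] = None

    @property
    def length_coal(self) -> Optional[float]:
        if self.parent is None:
            return None
        return self.parent.height - self.height

    def preorder(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> List["GeneTreeNode"]:
        return [n for n in self.preorder() if not n.children]


@dataclass
class GeneTree:
    """A simulated gene genealogy with its sample-to-species map."""

    root: GeneTreeNode
    sample_map: Dict[str, str]
    mu: Optional[float] = None

    def preorder(self):
        return self.root.preorder()

    def tips(self) -> List[GeneTreeNode]:
        return self.root.tips()

    @property
    def num_tips(self) -> int:
        return len(self.sample_map)


def simulate_within_branch(
    lineages: Sequence[GeneTreeNode],
    duration: float,
    p: CoalescentParameter,
    rng: np.random.Generator,
    start_height: float = 0.0,
    attrs: Optional[BranchAttributes] = None,
):
    """Run one branch's coalescent on a set of lineages.

    Repeatedly draws merger events; events whose cumulative time fits within
    ``duration`` are applied (the k participants are replaced by one parent
    node at the event height).  Surviving lineages are returned for the
    parent branch.  With ``duration = inf`` the process runs until a single
    lineage remains.  ``attrs``, when given, is recorded on the traversed
    segment of every lineage for later rescaling.

    Returns ``(surviving lineages, merger events)``.
    """
    if duration < 0:
        raise ValueError(f"negative branch duration {duration}")
    active = list(lineages)
    entry = {id(l): start_height for l in active}
    t = 0.0
    events = []
    while len(active) >= 2:
        ev = sample_event(CoalescentState(active), p, rng)
        if t + ev.waiting_time > duration:
            break
        t += ev.waiting_time
        h = start_height + t
        parent = GeneTreeNode(height=h)
        for child in ev.participants:
            if attrs is not None:
                child.segments.append((entry.pop(id(child)), h, attrs))
            child.parent = parent
            parent.children.append(child)
            active.remove(child)
        active.append(parent)
        entry[id(parent)] = h
        events.append(ev)
    if math.isfinite(duration) and attrs is not None:
        for l in active:
            l.segments.append((entry[id(l)], start_height + duration, attrs))
    return active, events


def route_at_hybrid(
    lineages: Sequence[GeneTreeNode], gamma: float, rng: np.random.Generator
):
    """Partition lineages at a hybrid node.

    Each lineage independently derives from the left parental population
    with probability ``gamma``, else from the right one.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"inheritance probability must lie in [0, 1], got {gamma}")
    left, right = [], []
    draws = rng.random(len(lineages))
    for lineage, u in zip(lineages, draws):
        (left if u < gamma else right).append(lineage)
    return left, right


def _normalise_samples(net: SpeciesNetwork, samples) -> Dict[str, int]:
    tips = net.tips
    if isinstance(samples, int):
        samples = {t.label: samples for t in tips}
    elif isinstance(samples, (list, tuple)):
        if len(samples) == 1:
            samples = {t.label: int(samples[0]) for t in tips}
        elif len(samples) == len(tips):
            samples = {t.label: int(c) for t, c in zip(tips, samples)}
        else:
            raise ValueError(
                f"{len(samples)} sample counts given for {len(tips)} tip species"
            )
    missing = [t.label for t in tips if t.label not in samples]
    if missing:
        raise ValueError(f"no sample count for species {missing}")
    bad = {k: v for k, v in samples.items() if v < 1}
    if bad:
        raise ValueError(f"sample counts must be >= 1, got {bad}")
    return dict(samples)


def simulate_gene_tree(
    net: SpeciesNetwork,
    samples: Union[int, Sequence[int], Dict[str, int]],
    rng: np.random.Generator,
    check_ultra: bool = True,
) -> GeneTree:
    """Simulate one gene genealogy within a species network.

    ``samples`` gives the number of lineages sampled per tip species (a
    mapping, a list aligned with the network's tip order, or a scalar
    broadcast to every tip).  Sample tips are labelled ``<species>_<i>`` with
    1-based indices.  Branch lengths must be in coalescent units.  The
    returned tree may contain multifurcations under multiple-merger
    coalescents; under the Kingman coalescent it is strictly binary.

    Non-ultrametric networks trigger a warning (not an error) and are
    simulated on the root-consistent time axis: every tip is placed at the
    present and each branch lasts from its child node's height to its parent
    node's height.
    """
    if net.unit_tag != "coalescent":
        raise ValidationError(
            "branch lengths are in generations; call convert_units first"
        )
    counts = _normalise_samples(net, samples)
    if check_ultra and any(e.length is not None for _, _, e in net.edges()):
        for w in check_ultrametric(net):
            _warnings.warn(w, UserWarning, stacklevel=2)

    single = net.root.is_tip  # one-population (single node) network
    heights = {id(net.root): 0.0} if single else net.node_heights()
    for h in net.hybrid_nodes:
        if any(e.inheritance_prob is None for e in h.parent_edges):
            raise ValidationError(
                f"hybrid node {h.label!r} has no inheritance probability; "
                "supply one when parsing the network"
            )

    sample_map: Dict[str, str] = {}
    pool: Dict[int, List[GeneTreeNode]] = {}
    for node in net.postorder():
        lineages = pool.get(id(node), [])
        if node.is_tip:
            for i in range(counts[node.label]):
                label = f"{node.label}_{i + 1}"
                lineages.append(GeneTreeNode(label=label, height=heights[id(node)]))
                sample_map[label] = node.label
        if node is net.root:
            root_lineages = lineages
            continue
        if node.is_hybrid:
            gamma = node.parent_edges[0].inheritance_prob
            subsets = route_at_hybrid(lineages, gamma, rng)
        else:
            subsets = (lineages,)
        for subset, parent, edge in zip(subsets, node.parents, node.parent_edges):
            duration = heights[id(parent)] - heights[id(node)]
            survivors, _ = simulate_within_branch(
                subset,
                duration,
                edge.parameter,
                rng,
                start_height=heights[id(node)],
                attrs=edge,
            )
            pool.setdefault(id(parent), []).extend(survivors)

    # ancestral population above the network root
    stem = net.root_attributes
    final, _ = simulate_within_branch(
        root_lineages,
        math.inf,
        stem.parameter,
        rng,
        start_height=heights[id(net.root)],
        attrs=None,
    )
    (root,) = final
    # close the open segments of the stem: every lineage that entered the
    # ancestral population records its traversal up to its coalescence
    _close_stem_segments(root, heights[id(net.root)], stem)
    return GeneTree(root=root, sample_map=sample_map)


def _close_stem_segments(root: GeneTreeNode, stem_height: float, stem: BranchAttributes):
    for node in root.preorder():
        if node.parent is None:
            continue
        covered = sum(h1 - h0 for h0, h1, _ in node.segments)
        gap = node.length_coal - covered
        if gap > 1e-12 * max(1.0, node.length_coal):
            start = max(node.height, stem_height)
            node.segments.append((start, node.parent.height, stem))


def rescale_tree(tree: GeneTree, mu: float = 0.0) -> GeneTree:
    """Attach generations and expected-mutations branch lengths.

    Each gene-tree branch's length in generations is its coalescent length
    times the conversion factor of the network branch it traverses (N, or
    N**(alpha-1) on Beta branches), summed piecewise over the recorded
    segments.  Expected mutations are generations times the per-generation
    mutation rate ``mu``.  Modifies the tree in place and returns it.
    """
    from .network_io import _conversion_divisor

    if mu < 0:
        raise ValueError(f"mutation rate must be >= 0, got {mu}")
    for node in tree.preorder():
        if node.parent is None:
            continue
        node.length_gen = sum(
            (h1 - h0) * _conversion_divisor(attrs) for h0, h1, attrs in node.segments
        )
        node.length_mut = node.length_gen * mu
    tree.mu = mu
    return tree
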