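"""Reading, validating and writing species trees/networks and gene trees.

Species trees are given in standard Newick; species networks in extended
Newick, where a hybrid population appears under two parents as a duplicated
``name#tag`` label (Cardona-style).  Both occurrences of a hybrid label are
merged into a single node with two parent edges.  The tag after ``#`` is
either a symbolic name (e.g. ``h1#H1``, with the inheritance probability
supplied separately) or an inline number (e.g. ``h_2#.5``) which is taken as
the inheritance probability gamma of the FIRST-listed (left) parent edge; the
other parent edge receives 1 - gamma.  "Left" means first encountered in a
left-to-right scan of the input string.

Branch lengths may be in coalescent units (default) or generations; the two
are interconvertible given per-branch effective population sizes N.  On a
branch governed by a Beta(2-alpha, alpha)-coalescent the timescale is
proportional to N**(alpha - 1), so that power is used as the conversion
divisor there; Kingman and psi branches use N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

from .rates import KINGMAN, CoalescentParameter

__all__ = [
    "ParseError",
    "ValidationError",
    "BranchAttributes",
    "NetworkNode",
    "SpeciesNetwork",
    "parse_network",
    "write_newick",
    "check_ultrametric",
    "convert_units",
    "assign_branch_attributes",
]


class ParseError(ValueError):
    """Malformed (extended) Newick input; carries the offending position."""

    def __init__(self, message: str, position: Optional[int] = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class ValidationError(ValueError):
    """Structurally well-formed input that violates a network invariant."""


@dataclass
class BranchAttributes:
    """Attributes of one branch (edge from a node up to one of its parents).

    ``length`` is in the network's unit system (coalescent units or
    generations); ``pop_size`` is the effective population size N of the
    population the branch represents (relative units, default 1);
    ``parameter`` selects the coalescent family operating on the branch;
    ``inheritance_prob`` is gamma for hybrid edges, ``None`` otherwise.
    """

    length: Optional[float] = None
    pop_size: float = 1.0
    parameter: CoalescentParameter = KINGMAN
    inheritance_prob: Optional[float] = None

    def validate(self) -> None:
        if self.length is not None and self.length < 0:
            raise ValidationError(f"negative branch length {self.length}")
        if self.pop_size <= 0:
            raise ValidationError(f"population size must be > 0, got {self.pop_size}")
        if self.inheritance_prob is not None and not 0.0 <= self.inheritance_prob <= 1.0:
            raise ValidationError(
                f"inheritance probability must lie in [0, 1], got {self.inheritance_prob}"
            )


@dataclass(eq=False)
class NetworkNode:
    """A population in the species network."""

    label: str = ""
    children: List["NetworkNode"] = field(default_factory=list)
    parents: List["NetworkNode"] = field(default_factory=list)
    parent_edges: List[BranchAttributes] = field(default_factory=list)
    is_hybrid: bool = False
    hybrid_tag: Optional[str] = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def edge_to(self, parent: "NetworkNode") -> BranchAttributes:
        for p, e in zip(self.parents, self.parent_edges):
            if p is parent:
                return e
        raise KeyError(f"{parent.label!r} is not a parent of {self.label!r}")

    def __repr__(self) -> str:  # pragma: no cover
        kind = "hybrid" if self.is_hybrid else ("tip" if self.is_tip else "internal")
        return f"<NetworkNode {self.label!r} ({kind})>"


class SpeciesNetwork:
    """A rooted DAG of populations with branch attributes.

    ``root_attributes`` describes the (infinite) ancestral branch above the
    root: the coalescent process and population size that apply once all
    lineages have reached the root population.
    """

    def __init__(
        self,
        root: NetworkNode,
        nodes: List[NetworkNode],
        unit_tag: str = "coalescent",
    ):
        self.root = root
        self.nodes = nodes
        self.unit_tag = unit_tag
        self.root_attributes = BranchAttributes(length=None)

    @property
    def tips(self) -> List[NetworkNode]:
        return [n for n in self.nodes if n.is_tip]

    @property
    def hybrid_nodes(self) -> List[NetworkNode]:
        return [n for n in self.nodes if n.is_hybrid]

    def postorder(self) -> List[NetworkNode]:
        """Nodes with every child listed before its parents (deduplicated)."""
        order: List[NetworkNode] = []
        seen = set()

        def visit(node: NetworkNode) -> None:
            if id(node) in seen:
                return
            seen.add(id(node))
            for c in node.children:
                visit(c)
            order.append(node)

        visit(self.root)
        return order

    def node_heights(self) -> Dict[int, float]:
        """Height (time before present) of every node, tips at 0.

        Heights are defined bottom-up: a node's height is the maximum over
        its children of (child height + connecting branch length), which for
        ultrametric networks coincides with every path.  Requires all branch
        lengths to be set.
        """
        heights: Dict[int, float] = {}
        for node in self.postorder():
            if node.is_tip:
                heights[id(node)] = 0.0
            else:
                hs = []
                for c in node.children:
                    e = c.edge_to(node)
                    if e.length is None:
                        raise ValidationError(
                            f"branch above {c.label!r} has no length"
                        )
                    hs.append(heights[id(c)] + e.length)
                heights[id(node)] = max(hs)
        return heights

    def edges(self):
        """Iterate (child, parent, BranchAttributes) over all branches."""
        for node in self.nodes:
            for p, e in zip(node.parents, node.parent_edges):
                yield node, p, e

    def validate(self) -> None:
        # parent-count invariants
        for node in self.nodes:
            n_par = len(node.parent_edges)
            if node is self.root:
                if n_par != 0:
                    raise ValidationError(f"root {node.label!r} has a parent")
            elif node.is_hybrid:
                if n_par != 2:
                    raise ValidationError(
                        f"hybrid node {node.label!r} has {n_par} parent edge(s), expected 2"
                    )
            elif n_par != 1:
                raise ValidationError(
                    f"node {node.label!r} has {n_par} parent edges, expected 1"
                )
            for e in node.parent_edges:
                e.validate()
        # gamma pairs sum to 1
        for h in self.hybrid_nodes:
            gammas = [e.inheritance_prob for e in h.parent_edges]
            if all(g is not None for g in gammas):
                if abs(sum(gammas) - 1.0) > 1e-9:
                    raise ValidationError(
                        f"inheritance probabilities of hybrid {h.label!r} sum to "
                        f"{sum(gammas)}, expected 1"
                    )
        # acyclicity + reachability (DFS from root with a recursion stack)
        seen, stack = set(), set()

        def visit(node: NetworkNode) -> None:
            if id(node) in stack:
                raise ValidationError(
                    f"cycle detected through node {node.label!r}"
                )
            if id(node) in seen:
                return
            seen.add(id(node))
            stack.add(id(node))
            for c in node.children:
                visit(c)
            stack.discard(id(node))

        visit(self.root)
        unreachable = [n.label for n in self.nodes if id(n) not in seen]
        if unreachable:
            raise ValidationError(f"nodes unreachable from root: {unreachable}")
        # unique tip labels
        tip_labels = [t.label for t in self.tips]
        if len(set(tip_labels)) != len(tip_labels):
            dup = sorted({l for l in tip_labels if tip_labels.count(l) > 1})
            raise ValidationError(f"duplicate tip labels: {dup}")


_LABEL_TERMINATORS = set("():,;#[]\t\n\r ")
_NUMBER_CHARS = set("0123456789.eE+-")


class _Parser:
    def __init__(self, text: str, inheritance_probs: Optional[Dict[str, float]]):
        self.text = text
        self.i = 0
        self.nodes: List[NetworkNode] = []
        self.hybrids: Dict[str, NetworkNode] = {}
        self.inheritance_probs = inheritance_probs or {}

    def error(self, msg: str) -> ParseError:
        return ParseError(msg, self.i)

    def peek(self) -> str:
        self.skip_ws()
        return self.text[self.i] if self.i < len(self.text) else ""

    def skip_ws(self) -> None:
        while self.i < len(self.text) and self.text[self.i] in " \t\n\r":
            self.i += 1

    def read_label(self) -> str:
        self.skip_ws()
        start = self.i
        while self.i < len(self.text) and self.text[self.i] not in _LABEL_TERMINATORS:
            self.i += 1
        return self.text[start : self.i]

    def read_number(self) -> float:
        self.skip_ws()
        start = self.i
        while self.i < len(self.text) and self.text[self.i] in _NUMBER_CHARS:
            # '+'/'-' only valid leading or after exponent marker
            c = self.text[self.i]
            if c in "+-" and self.i > start and self.text[self.i - 1] not in "eE":
                break
            self.i += 1
        token = self.text[start : self.i]
        try:
            return float(token)
        except ValueError:
            self.i = start
            raise self.error(f"expected a number, found {token!r}")

    def parse(self) -> NetworkNode:
        root, _ = self.parse_clade()
        if self.peek() != ";":
            raise self.error("expected ';' at end of Newick string")
        self.i += 1
        self.skip_ws()
        if self.i != len(self.text):
            raise self.error("trailing characters after ';'")
        return root

    def parse_clade(self):
        """Parse one clade; returns (node, edge) where edge is the branch
        attributes connecting the node to its (not yet attached) parent."""
        children = []
        if self.peek() == "(":
            self.i += 1
            children.append(self.parse_clade())
            while self.peek() == ",":
                self.i += 1
                children.append(self.parse_clade())
            if self.peek() != ")":
                raise self.error("expected ')' or ','")
            self.i += 1
        name = self.read_label()
        hybrid_tag = None
        if self.peek() == "#":
            self.i += 1
            hybrid_tag = self.read_label()
            if not hybrid_tag:
                raise self.error("empty hybrid tag after '#'")
        length = None
        if self.peek() == ":":
            self.i += 1
            length = self.read_number()
            if length < 0:
                raise self.error(f"negative branch length {length}")
        if not children and not name and hybrid_tag is None:
            raise self.error("expected a node label")

        node = self.make_node(name, hybrid_tag, children)
        edge = BranchAttributes(length=length)
        if hybrid_tag is not None:
            # inline numeric tag -> inheritance probability of this edge;
            # symbolic tags are resolved after the full string is parsed
            try:
                gamma = float(hybrid_tag)
            except ValueError:
                gamma = None
            if gamma is not None and not 0.0 <= gamma <= 1.0:
                raise ValidationError(
                    f"inheritance probability must lie in [0, 1], got {gamma}"
                )
            edge.inheritance_prob = gamma
            # scan position of this occurrence: the hybrid's parent edges are
            # ordered left-to-right by it after parsing ("left parent" rule)
            edge._scan_order = self.i
        return node, edge

    def make_node(self, name, hybrid_tag, children):
        if hybrid_tag is not None:
            key = name or hybrid_tag
            node = self.hybrids.get(key)
            if node is None:
                node = NetworkNode(label=key, is_hybrid=True, hybrid_tag=hybrid_tag)
                self.hybrids[key] = node
                self.nodes.append(node)
            else:
                def _numeric(tag):
                    try:
                        float(tag)
                        return True
                    except ValueError:
                        return False

                # numeric tags carry per-edge gammas and may differ between
                # occurrences (their sum is validated later); symbolic tags
                # must agree
                if node.hybrid_tag != hybrid_tag and not (
                    _numeric(node.hybrid_tag) and _numeric(hybrid_tag)
                ):
                    raise ValidationError(
                        f"hybrid node {key!r} appears with conflicting tags "
                        f"{node.hybrid_tag!r} and {hybrid_tag!r}"
                    )
            if children:
                if node.children:
                    raise ValidationError(
                        f"hybrid node {key!r} has child subtrees in more than one occurrence"
                    )
                self.attach(node, children)
            return node
        node = NetworkNode(label=name)
        self.nodes.append(node)
        self.attach(node, children)
        return node

    @staticmethod
    def attach(parent, children):
        for child, edge in children:
            parent.children.append(child)
            child.parents.append(parent)
            child.parent_edges.append(edge)


def parse_network(
    newick: str,
    inheritance_probs: Optional[Dict[str, float]] = None,
    unit_tag: str = "coalescent",
) -> SpeciesNetwork:
    """Parse an (extended) Newick string into a validated SpeciesNetwork.

    Parameters
    ----------
    newick
        A Newick or extended Newick string terminated by ``';'``.  The two
        occurrences of a hybrid label (``name#tag``) resolve to one node.
    inheritance_probs
        Mapping from hybrid node name (or symbolic tag) to the inheritance
        probability gamma of its left (first-listed) parent edge.  Required
        only for symbolic hybrid tags; inline numeric tags (``h#.5``) carry
        gamma in the string itself.
    unit_tag
        ``"coalescent"`` (default) or ``"generations"``; declares the unit
        system of the branch lengths.
    """
    if unit_tag not in ("coalescent", "generations"):
        raise ValueError(f"unknown unit tag {unit_tag!r}")
    parser = _Parser(newick, inheritance_probs)
    root = parser.parse()
    # resolve the complementary gamma on hybrid edges
    probs = inheritance_probs or {}
    for h in parser.hybrids.values():
        if len(h.parent_edges) == 2:
            order = sorted(
                range(2), key=lambda i: getattr(h.parent_edges[i], "_scan_order", 0)
            )
            h.parent_edges = [h.parent_edges[i] for i in order]
            h.parents = [h.parents[i] for i in order]
            g = [e.inheritance_prob for e in h.parent_edges]
            if g[0] is None and g[1] is None:
                # symbolic tag: the side-supplied gamma binds to the left
                # (first-encountered) parent edge
                gamma = probs.get(h.label, probs.get(h.hybrid_tag))
                if gamma is not None:
                    if not 0.0 <= gamma <= 1.0:
                        raise ValidationError(
                            f"inheritance probability must lie in [0, 1], got {gamma}"
                        )
                    h.parent_edges[0].inheritance_prob = gamma
                    h.parent_edges[1].inheritance_prob = 1.0 - gamma
            elif g[0] is None and g[1] is not None:
                h.parent_edges[0].inheritance_prob = 1.0 - g[1]
            elif g[1] is None and g[0] is not None:
                h.parent_edges[1].inheritance_prob = 1.0 - g[0]
        elif len(h.parent_edges) > 2:
            raise ValidationError(
                f"hybrid label {h.label!r} occurs {len(h.parent_edges)} times, expected 2"
            )
    net = SpeciesNetwork(root, parser.nodes, unit_tag=unit_tag)
    net.validate()
    return net


def check_ultrametric(net: SpeciesNetwork, tolerance: float = 1e-6) -> List[str]:
    """Warn about root-to-tip paths that deviate from the maximum path length.

    ``tolerance`` is relative to the tree height.  Returns one warning string
    per deviating path (possibly several per tip when the tip is below a
    hybrid node); an empty list means the network is ultrametric.  This is a
    diagnostic only: simulation proceeds regardless.
    """
    paths: List[tuple] = []  # (tip label, total length)

    def walk(node: NetworkNode, acc: float) -> None:
        if node.is_tip:
            paths.append((node.label, acc))
            return
        for c in node.children:
            e = c.edge_to(node)
            if e.length is None:
                raise ValidationError(f"branch above {c.label!r} has no length")
            walk(c, acc + e.length)

    walk(net.root, 0.0)
    height = max(total for _, total in paths)
    threshold = tolerance * height if height > 0 else tolerance
    warnings = []
    for tip, total in paths:
        if height - total > threshold:
            warnings.append(
                f"root-to-tip path to {tip!r} has length {total:g}, "
                f"{height - total:g} short of the tree height {height:g}: "
                "network is not ultrametric"
            )
    return warnings


def _conversion_divisor(e: BranchAttributes) -> float:
    """Generations-per-coalescent-unit factor for one branch.

    N for Kingman/psi branches; N**(alpha-1) on Beta branches, whose
    coalescent timescale is proportional to that power of the population
    size.
    """
    from .rates import Family

    if e.parameter.family == Family.BETA:
        return e.pop_size ** (e.parameter.value - 1.0)
    return e.pop_size


def convert_units(
    net: SpeciesNetwork,
    pop_sizes: Union[None, float, str] = None,
    to: str = "coalescent",
) -> SpeciesNetwork:
    """Convert branch lengths between generations and coalescent units.

    Converts in place and returns the network.  ``pop_sizes`` (scalar or
    (extended) Newick spec) optionally assigns per-branch effective
    population sizes first; otherwise the sizes already stored on the
    branches are used.  ``to="coalescent"`` divides each branch length by its
    conversion divisor (requires lengths in generations); ``to="generations"``
    multiplies (requires coalescent units).
    """
    if to not in ("coalescent", "generations"):
        raise ValueError(f"unknown unit tag {to!r}")
    if pop_sizes is not None:
        assign_branch_attributes(net, pop_sizes, attribute="pop_size")
    if net.unit_tag == to:
        raise ValueError(f"branch lengths are already in {to} units")
    for _, _, e in net.edges():
        if e.length is None:
            continue
        d = _conversion_divisor(e)
        e.length = e.length / d if to == "coalescent" else e.length * d
    net.unit_tag = to
    return net


def _node_key(node: NetworkNode):
    """Matching key for topology alignment: the set of descendant tips."""
    if node.is_tip:
        return frozenset([node.label])
    out = frozenset()
    for c in node.children:
        out |= _node_key(c)
    return out


def assign_branch_attributes(
    net: SpeciesNetwork,
    spec: Union[float, int, str],
    attribute: str = "coalescent_parameter",
) -> SpeciesNetwork:
    """Assign per-branch coalescent parameters or population sizes.

    ``spec`` is either a scalar, applied to every branch (including the
    ancestral branch above the root), or an (extended) Newick string whose
    topology matches the network and whose branch lengths carry the values.
    Scalar coalescent parameters are dispatched to a family by value (see
    :meth:`CoalescentParameter.from_value`); population sizes must be > 0.
    """
    if attribute not in ("coalescent_parameter", "pop_size"):
        raise ValueError(f"unknown attribute {attribute!r}")

    def apply(e: BranchAttributes, value: float) -> None:
        if attribute == "coalescent_parameter":
            e.parameter = CoalescentParameter.from_value(value)
        else:
            if value <= 0:
                raise ValidationError(f"population size must be > 0, got {value}")
            e.pop_size = float(value)

    if isinstance(spec, (int, float)):
        for _, _, e in net.edges():
            apply(e, spec)
        apply(net.root_attributes, spec)
        return net

    spec_net = parse_network(spec)

    def edge_map(n: SpeciesNetwork):
        out = {}
        for child, parent, e in n.edges():
            key = (_node_key(child), _node_key(parent))
            if key in out:
                raise ValidationError(
                    f"ambiguous branch match for node {child.label!r}"
                )
            out[key] = e
        return out

    spec_edges = edge_map(spec_net)
    for child, parent, e in net.edges():
        key = (_node_key(child), _node_key(parent))
        se = spec_edges.pop(key, None)
        if se is None:
            raise ValidationError(
                f"attribute spec topology does not match: no branch above "
                f"{child.label or sorted(_node_key(child))!r}"
            )
        if se.length is None:
            raise ValidationError(
                f"attribute spec carries no value on the branch above "
                f"{child.label or sorted(_node_key(child))!r}"
            )
        apply(e, se.length)
    if spec_edges:
        (key, _), = list(spec_edges.items())[:1]
        raise ValidationError(
            f"attribute spec has an extra branch above {sorted(key[0])}"
        )
    return net


_SCALINGS = ("coalescent", "generations", "expected_mutations", "topology")


def write_newick(tree, scaling: str = "coalescent", precision: int = 6) -> str:
    """Serialise a gene tree to Newick with the requested branch scaling.

    ``scaling`` selects branch lengths in coalescent units, generations, or
    expected mutations (the latter two require :func:`rescale_tree` to have
    been applied), or ``"topology"`` for a lengthless string.  Multiple
    mergers appear as polytomies; interior nodes are unlabelled.  Lengths are
    printed with ``precision`` significant digits.
    """
    if scaling not in _SCALINGS:
        raise ValueError(f"unknown scaling {scaling!r}; expected one of {_SCALINGS}")
    root = tree.root if hasattr(tree, "root") else tree

    def branch_length(node) -> Optional[float]:
        if scaling == "topology" or node.parent is None:
            return None
        if scaling == "coalescent":
            return node.parent.height - node.height
        value = node.length_gen if scaling == "generations" else node.length_mut
        if value is None:
            raise ValueError(
                f"{scaling} branch lengths are not set; call rescale_tree first"
            )
        return value

    def serialise(node) -> str:
        if node.children:
            inner = ",".join(serialise(c) for c in node.children)
            s = f"({inner})"
        else:
            s = node.label
        length = branch_length(node)
        if length is not None:
            s += f":{length:.{precision}g}"
        return s

    return serialise(root) + ";"
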