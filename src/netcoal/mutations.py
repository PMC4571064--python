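"""Infinite-sites mutations on simulated genealogies.

Under the infinitely-many-sites model every mutation hits a previously
unmutated site, so each mutation becomes one binary segregating site: the
samples descending from the mutated branch carry the derived allele 1,
everyone else the ancestral 0.  Mutations fall on each branch as independent
Poisson counts with mean mu times the branch length in generations.
Mutations above the grand MRCA are not simulated (they would not segregate
in the sample); 0 always denotes the ancestral state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .genealogy_sim import GeneTree, GeneTreeNode

__all__ = [
    "MutationPlacement",
    "HaplotypeMatrix",
    "place_mutations",
    "haplotypes",
    "label_tree_with_mutations",
]

logger = logging.getLogger(__name__)


@dataclass
class MutationPlacement:
    """Per-branch mutation counts; a branch is keyed by its child node."""

    counts: Dict[int, int]  # id(GeneTreeNode) -> count
    mu: float
    nodes: Dict[int, GeneTreeNode] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def count_for(self, node: GeneTreeNode) -> int:
        return self.counts.get(id(node), 0)


@dataclass
class HaplotypeMatrix:
    """0/1 haplotype data: one row per sample, one column per mutation.

    ``pop_assignment`` maps sample labels to populations (species of
    origin).  Column order is mutation age order, oldest first (age taken as
    the top height of the carrying branch; ties broken by preorder branch
    traversal order), so the serialisation is deterministic.
    """

    data: np.ndarray  # (n_samples, n_sites) of {0, 1}
    row_labels: List[str]
    pop_assignment: Dict[str, str]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def samples_per_pop(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for label in self.row_labels:
            pop = self.pop_assignment[label]
            out[pop] = out.get(pop, 0) + 1
        return out

    def to_text(self, name: str = "1") -> str:
        """Serialise one replicate block: a ``//`` header line naming the
        replicate, then one ``label 0 1 ...`` row per sample."""
        lines = [f"//replicate {name} segsites {self.n_sites}"]
        for label, row in zip(self.row_labels, self.data):
            lines.append(label + " " + " ".join(str(int(v)) for v in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(
        cls, text: str, pop_assignment: Optional[Dict[str, str]] = None
    ) -> List["HaplotypeMatrix"]:
        """Parse one or more replicate blocks written by :meth:`to_text`.

        When ``pop_assignment`` is omitted, each sample's population is
        inferred from its label prefix (everything before the last ``_``).
        """
        raw_blocks: List[List[str]] = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("//"):
                raw_blocks.append([])
            elif raw_blocks:
                raw_blocks[-1].append(line)
        blocks: List[HaplotypeMatrix] = []
        for block in raw_blocks:
            labels = [l.split()[0] for l in block]
            rows = [[int(v) for v in l.split()[1:]] for l in block]
            n_sites = len(rows[0]) if rows else 0
            data = (
                np.array(rows, dtype=np.uint8)
                if n_sites
                else np.zeros((len(labels), 0), dtype=np.uint8)
            )
            pops = pop_assignment or {l: l.rsplit("_", 1)[0] for l in labels}
            blocks.append(cls(data=data, row_labels=labels, pop_assignment=pops))
        return blocks


def place_mutations(
    tree: GeneTree, mu: float, rng: np.random.Generator
) -> MutationPlacement:
    """Drop Poisson(mu * branch length in generations) mutations per branch.

    Branches are visited in preorder so placement is reproducible for a
    given seed.  Requires generations branch lengths (see ``rescale_tree``).
    """
    if mu < 0:
        raise ValueError(f"mutation rate must be >= 0, got {mu}")
    counts: Dict[int, int] = {}
    nodes: Dict[int, GeneTreeNode] = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        if node.length_gen is None:
            raise ValueError(
                "tree has no generations branch lengths; call rescale_tree first"
            )
        counts[id(node)] = int(rng.poisson(mu * node.length_gen))
        nodes[id(node)] = node
    return MutationPlacement(counts=counts, mu=mu, nodes=nodes)


def haplotypes(tree: GeneTree, placement: MutationPlacement) -> HaplotypeMatrix:
    """Convert a mutation placement into a 0/1 haplotype matrix.

    Every mutation becomes one column whose 1-entries are exactly the
    samples below the mutated branch, so the matrix is a perfect phylogeny
    by construction.  A mutation whose branch subtends every sample would
    not segregate; such columns are excluded with a logged note (they cannot
    arise below the grand MRCA of the full sample, but the guard keeps the
    invariant explicit).
    """
    tip_nodes = tree.tips()
    # canonical row order: sample-map insertion order (species in network tip
    # order, then sample index), so rows align across replicates
    order = {label: i for i, label in enumerate(tree.sample_map)}
    if all(t.label in order for t in tip_nodes):
        tip_nodes = sorted(tip_nodes, key=lambda t: order[t.label])
    tip_index = {id(t): i for i, t in enumerate(tip_nodes)}
    row_labels = [t.label for t in tip_nodes]

    # descendant tip indices per node, bottom-up
    desc: Dict[int, List[int]] = {}

    def collect(node: GeneTreeNode) -> List[int]:
        if not node.children:
            out = [tip_index[id(node)]]
        else:
            out = []
            for c in node.children:
                out.extend(collect(c))
        desc[id(node)] = out
        return out

    collect(tree.root)

    # oldest mutations first: sort carrying branches by top height descending
    carriers = []
    for order, node in enumerate(tree.preorder()):
        if node.parent is None:
            continue
        c = placement.count_for(node)
        if c > 0:
            carriers.append((-node.parent.height, order, node, c))
    carriers.sort(key=lambda t: (t[0], t[1]))

    columns = []
    n = len(tip_nodes)
    dropped = 0
    for _, _, node, count in carriers:
        rows = desc[id(node)]
        if len(rows) == n:
            dropped += count
            continue
        col = np.zeros(n, dtype=np.uint8)
        col[rows] = 1
        columns.extend([col] * count)
    if dropped:
        logger.info("excluded %d non-segregating mutation(s)", dropped)
    data = (
        np.column_stack(columns) if columns else np.zeros((n, 0), dtype=np.uint8)
    )
    return HaplotypeMatrix(
        data=data, row_labels=row_labels, pop_assignment=dict(tree.sample_map)
    )


def label_tree_with_mutations(tree: GeneTree, placement: MutationPlacement) -> str:
    """Newick string with per-branch mutation counts as branch annotations.

    The integer count replaces the branch length, matching the classic
    mutation-labelled genealogy output.
    """

    def serialise(node: GeneTreeNode) -> str:
        if node.children:
            s = "(" + ",".join(serialise(c) for c in node.children) + ")"
        else:
            s = node.label
        if node.parent is not None:
            s += f":{placement.count_for(node)}"
        return s

    return serialise(tree.root) + ";"
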