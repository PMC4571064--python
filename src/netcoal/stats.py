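"""Summary statistics: F_ST (analytic and estimated), topology frequencies,
and monophyly classification for two-population samples.

Analytic split model
--------------------
Two populations A and B diverged tau coalescent units ago from an ancestral
population AB.  With pairwise coalescence rate ``lambda_A`` within each
daughter population and ``lambda_AB`` in the ancestral population, the
expected pairwise coalescence times are

    E[T_w] = (1 - exp(-lambda_A tau)) / lambda_A
             + exp(-lambda_A tau) (tau + 1/lambda_AB)
    E[T_b] = tau + 1/lambda_AB

and Slatkin's low-mutation limit of F_ST is

    F_ST = 1 - E[T_w]/E[T_b]
         = (1 - exp(-lambda_A tau)) (1 - 1/((tau + 1/lambda_AB) lambda_A)).

For the Beta(2-alpha, alpha)-coalescent ``lambda_A = 1`` on the coalescent
timescale; for the psi point-mass process the pairwise rate is supplied by
the caller (the literature is not consistent about its normalisation, so it
is kept as a free input here).

Estimation from haplotypes
--------------------------
With n sequences per population, H_w is the average number of pairwise
differences within populations (H_w = (H_w1 + H_w2)/2) and H_b the average
over all between-population pairs.  The corrected estimator

    F_hat = 1 - (n/(n-1)) * H_w / H_b

follows the published formula with H_w averaged over distinct within pairs;
``corrected=False`` gives the plain ratio estimator 1 - H_w/H_b, which is
the one whose pooled (multi-locus) form converges to the analytic limit
above.  See the package methods note for the discussion of the n/(n-1)
factor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .genealogy_sim import GeneTree, GeneTreeNode
from .mutations import HaplotypeMatrix

__all__ = [
    "SplitModel",
    "FstResult",
    "MonophylyClass",
    "expected_times",
    "expected_fst",
    "estimate_fst",
    "topology_table",
    "canonical_topology",
    "classify_monophyly",
    "monophyly_table",
    "fst_replicate_table",
    "simulate_split_fst",
    "pooled_fst_bootstrap",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitModel:
    """Two-population split model: divergence time tau (coalescent units),
    pairwise rate lambda_A within each daughter population and lambda_AB in
    the ancestral population."""

    tau: float
    lambda_A: float = 1.0
    lambda_AB: float = 1.0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if self.lambda_A <= 0 or self.lambda_AB <= 0:
            raise ValueError("coalescence rates must be > 0")


def expected_times(m: SplitModel) -> Tuple[float, float]:
    """Expected pairwise coalescence times (E[T_w], E[T_b])."""
    decay = math.exp(-m.lambda_A * m.tau)
    e_tb = m.tau + 1.0 / m.lambda_AB
    e_tw = (1.0 - decay) / m.lambda_A + decay * e_tb
    return e_tw, e_tb


def expected_fst(m: SplitModel) -> float:
    """Low-mutation-limit F_ST of the split model.

    Equals ``1 - E[T_w]/E[T_b]``; vanishes as tau -> 0 and tends to 1 as
    tau -> infinity.
    """
    return (1.0 - math.exp(-m.lambda_A * m.tau)) * (
        1.0 - 1.0 / ((m.tau + 1.0 / m.lambda_AB) * m.lambda_A)
    )


@dataclass
class FstResult:
    """Pairwise-difference summaries and the resulting F_ST estimate.

    ``fst_hat`` is NaN when H_b = 0 (no between-population variation), in
    which case ``defined`` is False.
    """

    H_w1: float
    H_w2: float
    H_w: float
    H_b: float
    n: float
    fst_hat: float
    corrected: bool = True

    @property
    def defined(self) -> bool:
        return not math.isnan(self.fst_hat)


def _as_matrix_list(h) -> List[HaplotypeMatrix]:
    if isinstance(h, HaplotypeMatrix):
        return [h]
    return list(h)


def _pair_diff_matrix(mats: Sequence[HaplotypeMatrix]) -> Tuple[np.ndarray, List[str]]:
    """Total pairwise difference counts summed across loci (replicates)."""
    labels = mats[0].row_labels
    n = len(labels)
    D = np.zeros((n, n))
    for m in mats:
        if m.row_labels != labels:
            raise ValueError("haplotype matrices have mismatched sample labels")
        if m.n_sites == 0:
            continue
        x = m.data.astype(np.int16)
        D += (x[:, None, :] != x[None, :, :]).sum(axis=2)
    return D, labels

def estimate_fst(
    h: Union[HaplotypeMatrix, Sequence[HaplotypeMatrix]], corrected: bool = True
) -> FstResult:
    """Estimate F_ST from one haplotype matrix or a multi-locus collection.

    Multi-locus input is pooled: pairwise differences are summed across loci
    per pair before averaging (ratio-of-sums), the standard low-variance
    choice.  Requires exactly two populations; the corrected estimator
    additionally requires at least two samples per population.  With unequal
    sample sizes H_b averages over all n1*n2 between pairs and the n/(n-1)
    correction uses n = (n1+n2)/2 with a logged warning.
    """
    mats = _as_matrix_list(h)
    D, labels = _pair_diff_matrix(mats)
    pops_of = mats[0].pop_assignment
    pop_names = sorted(set(pops_of[l] for l in labels))
    if len(pop_names) != 2:
        raise ValueError(f"F_ST needs exactly 2 populations, got {pop_names}")
    idx = {p: [i for i, l in enumerate(labels) if pops_of[l] == p] for p in pop_names}
    n1, n2 = len(idx[pop_names[0]]), len(idx[pop_names[1]])

    def within_mean(rows: List[int]) -> float:
        if len(rows) < 2:
            return float("nan")
        sub = D[np.ix_(rows, rows)]
        k = len(rows)
        return float(sub.sum() / (k * (k - 1)))  # mean over distinct pairs

    H_w1 = within_mean(idx[pop_names[0]])
    H_w2 = within_mean(idx[pop_names[1]])
    H_b = float(D[np.ix_(idx[pop_names[0]], idx[pop_names[1]])].mean())

    if corrected and (n1 < 2 or n2 < 2):
        raise ValueError(
            "the corrected estimator needs >= 2 samples per population; "
            "use corrected=False for single-sample populations"
        )
    if n1 != n2:
        n = (n1 + n2) / 2.0
        logger.warning(
            "unequal sample sizes (%d, %d); using n = %.1f in the correction", n1, n2, n
        )
    else:
        n = float(n1)
    if corrected:
        H_w = (H_w1 + H_w2) / 2.0
    else:
        # uncorrected mode tolerates single-sample populations: populations
        # without a within pair contribute nothing to H_w
        available = [x for x in (H_w1, H_w2) if not math.isnan(x)]
        if available:
            H_w = float(np.mean(available))
        else:
            H_w = 0.0
            logger.info("no within-population pairs; H_w taken as 0")
    if H_b == 0.0:
        fst = float("nan")
    elif corrected:
        fst = 1.0 - (n / (n - 1.0)) * H_w / H_b
    else:
        fst = 1.0 - H_w / H_b
    return FstResult(
        H_w1=H_w1, H_w2=H_w2, H_w=float(H_w), H_b=H_b, n=n, fst_hat=fst,
        corrected=corrected,
    )


def canonical_topology(tree: Union[GeneTree, GeneTreeNode]) -> str:
    """Canonical lengthless Newick-like topology string.

    Children are sorted by their smallest descendant tip label, so trees
    differing only in child order map to the same string.
    """
    root = tree.root if isinstance(tree, GeneTree) else tree

    def render(node: GeneTreeNode) -> Tuple[str, str]:
        if not node.children:
            return node.label, node.label
        parts = sorted(render(c) for c in node.children)
        min_label = parts[0][0]
        return min_label, "(" + ",".join(p[1] for p in parts) + ")"

    return render(root)[1]


def topology_table(trees: Sequence[Union[GeneTree, GeneTreeNode]]) -> pd.DataFrame:
    """Frequency table of canonical gene-tree topologies.

    Returns a DataFrame with columns ``topology``, ``count`` and
    ``frequency`` (summing to 1), sorted by decreasing count.
    """
    if not trees:
        raise ValueError("need at least one tree")
    counts: Dict[str, int] = {}
    for t in trees:
        key = canonical_topology(t)
        counts[key] = counts.get(key, 0) + 1
    df = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["topology", "count"],
    )
    df["frequency"] = df["count"] / df["count"].sum()
    return df


class MonophylyClass(str, Enum):
    """Mutually exclusive two-population gene-tree classes."""

    RECIPROCAL_MONOPHYLY = "reciprocal_monophyly"
    PARAPHYLY = "paraphyly"
    POLYPHYLY = "polyphyly"


def classify_monophyly(
    tree: GeneTree, pops: Optional[Dict[str, str]] = None
) -> MonophylyClass:
    """Classify a two-population gene tree.

    Reciprocal monophyly if each population's samples form a clade,
    paraphyly if exactly one does, polyphyly if neither.  ``pops`` maps tip
    labels to populations and defaults to the tree's sample-to-species map.
    """
    if pops is None:
        pops = tree.sample_map
    tip_labels = {t.label for t in tree.tips()}
    missing = tip_labels - set(pops)
    if missing:
        raise ValueError(f"tips without population assignment: {sorted(missing)}")
    pop_names = sorted(set(pops[l] for l in tip_labels))
    if len(pop_names) != 2:
        raise ValueError(f"monophyly classification needs 2 populations, got {pop_names}")

    clades = set()

    def collect(node: GeneTreeNode) -> frozenset:
        if not node.children:
            s = frozenset([node.label])
        else:
            s = frozenset().union(*(collect(c) for c in node.children))
        clades.add(s)
        return s

    collect(tree.root)
    n_mono = sum(
        frozenset(l for l in tip_labels if pops[l] == p) in clades for p in pop_names
    )
    if n_mono == 2:
        return MonophylyClass.RECIPROCAL_MONOPHYLY
    if n_mono == 1:
        return MonophylyClass.PARAPHYLY
    return MonophylyClass.POLYPHYLY


def monophyly_table(
    trees: Sequence[GeneTree], pops: Optional[Dict[str, str]] = None
) -> pd.DataFrame:
    """Relative frequencies of the three monophyly classes over replicates."""
    counts = {c: 0 for c in MonophylyClass}
    for t in trees:
        counts[classify_monophyly(t, pops)] += 1
    df = pd.DataFrame(
        [(c.value, counts[c]) for c in MonophylyClass], columns=["class", "count"]
    )
    df["frequency"] = df["count"] / max(len(trees), 1)
    return df


def fst_replicate_table(
    matrices: Sequence[HaplotypeMatrix], corrected: bool = True
) -> Tuple[pd.DataFrame, FstResult, int]:
    """Per-replicate F_ST plus the pooled multi-locus estimate.

    Returns ``(table, pooled, n_undefined)``; replicates with H_b = 0 are
    NaN in the table and excluded from the reported mean.
    """
    rows = []
    n_undef = 0
    for i, m in enumerate(matrices, start=1):
        r = estimate_fst(m, corrected=corrected)
        if not r.defined:
            n_undef += 1
        rows.append((i, r.H_w, r.H_b, r.fst_hat))
    df = pd.DataFrame(rows, columns=["replicate", "H_w", "H_b", "fst_hat"])
    pooled = estimate_fst(matrices, corrected=corrected)
    if n_undef:
        logger.info("%d replicate(s) with H_b = 0 excluded from the mean", n_undef)
    return df, pooled, n_undef


def simulate_split_fst(
    tau_generations: float,
    coalescent_param: float,
    pop_size: float,
    mu: float,
    n_per_pop: int,
    num_replicates: int,
    rng: np.random.Generator,
    corrected: bool = False,
) -> Tuple[FstResult, List[HaplotypeMatrix]]:
    """Simulate the two-population split model and estimate pooled F_ST.

    Builds the split network ``(A:tau,B:tau);`` with branch lengths in
    generations, converts to coalescent units using ``pop_size`` (on Beta
    branches the timescale N**(alpha-1) applies), simulates
    ``num_replicates`` genealogies with ``n_per_pop`` samples per
    population, drops infinite-sites mutations at per-generation rate
    ``mu``, and returns the pooled multi-locus F_ST estimate together with
    the per-replicate haplotype matrices.
    """
    from .genealogy_sim import rescale_tree, simulate_gene_tree
    from .mutations import haplotypes, place_mutations
    from .network_io import assign_branch_attributes, convert_units, parse_network

    net = parse_network(
        f"(A:{tau_generations!r},B:{tau_generations!r});", unit_tag="generations"
    )
    assign_branch_attributes(net, coalescent_param, "coalescent_parameter")
    convert_units(net, pop_sizes=pop_size, to="coalescent")
    matrices = []
    for _ in range(num_replicates):
        tree = simulate_gene_tree(net, n_per_pop, rng, check_ultra=False)
        rescale_tree(tree, mu)
        matrices.append(haplotypes(tree, place_mutations(tree, mu, rng)))
    return estimate_fst(matrices, corrected=corrected), matrices


def pooled_fst_bootstrap(
    matrices: Sequence[HaplotypeMatrix],
    rng: np.random.Generator,
    n_boot: int = 200,
    corrected: bool = False,
) -> np.ndarray:
    """Bootstrap the pooled F_ST over loci (replicates).

    Resamples whole replicates with replacement and recomputes the pooled
    estimate; returns the bootstrap sample (NaN where a resample has
    H_b = 0).
    """
    mats = list(matrices)
    L = len(mats)
    out = np.empty(n_boot)
    for i in range(n_boot):
        pick = rng.integers(0, L, size=L)
        out[i] = estimate_fst([mats[j] for j in pick], corrected=corrected).fst_hat
    return out
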