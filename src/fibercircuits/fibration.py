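"""Fibration symmetries: fibers, input trees, branching ratios, base graphs.

Two genes are symmetric under a graph fibration when their *input trees* —
the rooted trees of all reversed signed paths into them — are isomorphic;
such genes receive identical histories of regulation and therefore
synchronize under any admissible dynamics.  The equivalence classes are
called *fibers* and are computed here as the coarsest *balanced coloring*:
the coarsest partition in which any two same-color genes see identical
multisets of (regulator color, edge sign) among their in-neighbors.

The input tree of a gene has layer sizes Q_1 = 1, Q_2, Q_3, ... (the number
of tree nodes per layer); the asymptotic branching ratio n = lim Q_{t+1}/Q_t
measures the divergence of regulatory histories and classifies fiber
complexity: a plain autoregulation loop has Q = 1, 1, 1, ... (n = 1); a
loop with feedback to its regulator yields the Fibonacci recurrence
Q_t = Q_{t-1} + Q_{t-2} (n = golden ratio); two coupled autoregulators give
Q_t = 2 Q_{t-1} (n = 2); the general family follows
Q_t = n Q_{t-1} + m Q_{t-d} for m loops of length d.

Collapsing every fiber to one node gives the *base* graph, the minimal
circuit carrying the same dynamics.  Frustration counting (whether any
high/low state satisfies all signed interactions) separates the
fixed-point (SAT) from the oscillating (UNSAT) circuits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product as _iproduct
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .graph_core import NetworkIntegrityError, RegulatoryNetwork, Sign

__all__ = [
    "FiberPartition",
    "InputTree",
    "FiberClass",
    "BaseGraph",
    "minimal_balanced_coloring",
    "input_tree",
    "input_tree_classes",
    "trees_isomorphic",
    "branching_ratio",
    "quotient_base",
    "classify_fiber",
    "frustration_count",
    "sat_classify",
    "GOLDEN_RATIO",
]

GOLDEN_RATIO = (1.0 + math.sqrt(5.0)) / 2.0


@dataclass
class FiberPartition:
    """Coarsest balanced coloring: gene -> fiber id, fiber id -> gene set."""

    coloring: Dict[str, int]
    fibers: Dict[int, Set[str]]
    rounds: int = 0  # refinement rounds until stabilization
    class_counts: List[int] = field(default_factory=list)  # per round

    def fiber_of(self, gene: str) -> Set[str]:
        return self.fibers[self.coloring[gene]]

    def nontrivial_fibers(self, network: RegulatoryNetwork) -> List[Set[str]]:
        """Fibers of size >= 2, plus singleton fibers of self-looped genes."""
        out = []
        for genes in self.fibers.values():
            if len(genes) >= 2:
                out.append(set(genes))
            else:
                (g,) = genes
                if network.has_edge(g, g):
                    out.append({g})
        return out


@dataclass
class InputTree:
    """Input tree of a gene: layers of (gene, sign-of-edge-into-child) nodes.

    ``Q[t-1]`` is the exact size of layer ``t`` (``Q[0] == 1`` for the
    root), computed by the integer counting recurrence over per-gene
    occurrence vectors, so deep layers are exact even when the explicit
    node list would be astronomically large.  ``layers`` materializes the
    node lists up to ``max_nodes`` total nodes (``truncated`` marks where
    it stopped); the root carries sign ``None``.
    """

    root: str
    depth: int
    Q: List[int]
    layers: List[List[Tuple[str, Optional[Sign]]]]
    truncated: bool = False
    _network: Optional[RegulatoryNetwork] = field(
        default=None, repr=False, compare=False
    )


def minimal_balanced_coloring(network: RegulatoryNetwork) -> FiberPartition:
    """Coarsest balanced coloring of a signed digraph (the fibers).

    Iterative refinement: start with all genes in one class and repeatedly
    split classes by the multiset of (in-neighbor class, edge sign) until
    stable.  Stabilizes in at most |genes| rounds; two genes end in the
    same class iff their (infinite) input trees are isomorphic.
    """
    genes = sorted(network.genes)
    if not genes:
        return FiberPartition(coloring={}, fibers={}, rounds=0)
    in_adj: Dict[str, List[Tuple[str, Sign]]] = {
        g: network.in_edges(g) for g in genes
    }
    color: Dict[str, int] = {g: 0 for g in genes}
    n_colors = 1
    rounds = 0
    class_counts: List[int] = []
    while True:
        rounds += 1
        sig_map: Dict[Tuple, int] = {}
        new_color: Dict[str, int] = {}
        for g in genes:
            sig = (
                color[g],
                tuple(sorted((color[src], sign.value) for src, sign in in_adj[g])),
            )
            if sig not in sig_map:
                sig_map[sig] = len(sig_map)
            new_color[g] = sig_map[sig]
        class_counts.append(len(sig_map))
        if len(sig_map) == n_colors:
            color = new_color
            break
        n_colors = len(sig_map)
        color = new_color
    # renumber fibers canonically by their smallest member gene
    members: Dict[int, List[str]] = {}
    for g in genes:
        members.setdefault(color[g], []).append(g)
    order = sorted(members.values(), key=lambda m: m[0])
    coloring = {}
    fibers = {}
    for fid, m in enumerate(order):
        fibers[fid] = set(m)
        for g in m:
            coloring[g] = fid
    return FiberPartition(
        coloring=coloring, fibers=fibers, rounds=rounds,
        class_counts=class_counts,
    )


def input_tree(
    network: RegulatoryNetwork,
    root: str,
    depth: int,
    max_nodes: int = 100_000,
) -> InputTree:
    """Build the input tree of ``root`` to exactly ``depth`` layers.

    Layer 1 is the root; layer t+1 holds, for every occurrence of gene g in
    layer t, one node per in-edge of g (labelled by the regulating gene and
    the edge sign, repeated per path).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not network.has_gene(root):
        raise KeyError(f"unknown root gene {root!r}")
    in_adj = {g: network.in_edges(g) for g in network.genes}

    # exact layer sizes via occurrence-count vectors (Python ints)
    Q: List[int] = [1]
    counts: Dict[str, int] = {root: 1}
    for _ in range(depth - 1):
        nxt: Dict[str, int] = {}
        for g, c in counts.items():
            for src, _sign in in_adj[g]:
                nxt[src] = nxt.get(src, 0) + c
        Q.append(sum(nxt.values()))
        counts = nxt

    # explicit node lists, capped
    layers: List[List[Tuple[str, Optional[Sign]]]] = [[(root, None)]]
    total = 1
    truncated = False
    for t in range(1, depth):
        if truncated or total + Q[t] > max_nodes:
            truncated = Q[t] > 0
            break
        layer: List[Tuple[str, Optional[Sign]]] = []
        for g, _ in layers[-1]:
            layer.extend(in_adj[g])
        layers.append(layer)
        total += len(layer)
    return InputTree(
        root=root, depth=depth, Q=Q, layers=layers,
        truncated=truncated, _network=network,
    )


def input_tree_classes(network: RegulatoryNetwork, depth: int) -> Dict[str, int]:
    """Partition genes by depth-limited input-tree isomorphism.

    Canonical forms are hash-consed bottom-up: two genes get the same class
    id iff their input trees truncated at ``depth`` layers are isomorphic
    as rooted trees with sign-labelled edges.  Independent of (and the
    verification oracle for) :func:`minimal_balanced_coloring`.
    """
    genes = sorted(network.genes)
    in_adj = {g: network.in_edges(g) for g in genes}
    ids: Dict[str, int] = {g: 0 for g in genes}  # depth-1 trees: all isomorphic
    for _ in range(depth - 1):
        intern: Dict[Tuple, int] = {}
        nxt: Dict[str, int] = {}
        for g in genes:
            key = tuple(sorted((sign.value, ids[src]) for src, sign in in_adj[g]))
            if key not in intern:
                intern[key] = len(intern)
            nxt[g] = intern[key]
        ids = nxt
    return ids


def trees_isomorphic(a: InputTree, b: InputTree) -> bool:
    """Order-independent isomorphism of two (equal-depth) input trees."""
    if a.depth != b.depth:
        raise ValueError("input trees must have equal depth")
    if a.Q != b.Q:
        return False
    if a._network is None or b._network is None:
        raise ValueError("input trees lack their source network")
    if a._network is b._network:
        classes = input_tree_classes(a._network, a.depth)
        return classes[a.root] == classes[b.root]
    # different networks: canonize jointly on a disjoint union
    merged = RegulatoryNetwork()
    for tag, net in (("a:", a._network), ("b:", b._network)):
        for g in net.genes:
            merged.add_gene(tag + g)
        for u, v, s in net.edges:
            merged.add_edge(tag + u, tag + v, s)
    classes = input_tree_classes(merged, a.depth)
    return classes["a:" + a.root] == classes["b:" + b.root]


def branching_ratio(
    network: RegulatoryNetwork, root: str, depth: int = 40
) -> float:
    """Finite-depth estimate Q_depth / Q_{depth-1} of the branching ratio.

    Returns 0.0 when the tree dies out (Q_{depth-1} = 0, e.g. a gene whose
    regulatory ancestry contains no cycle deep enough).  Depth 40 separates
    the canonical values 1, golden ratio and 2 to far better than 4
    decimals.
    """
    tree = input_tree(network, root, depth, max_nodes=0)
    if tree.Q[-2] == 0:
        return 0.0
    return tree.Q[-1] / tree.Q[-2]


@dataclass
class BaseGraph:
    """Quotient of a network by a balanced partition.

    One node per fiber (named by the fiber's lexicographically smallest
    member); ``multiplicity[(src_fiber, tgt_fiber, sign)]`` is the number
    of in-edges each member of the target fiber receives from the source
    fiber — well-defined exactly because the partition is balanced.
    """

    network: RegulatoryNetwork
    multiplicity: Dict[Tuple[str, str, Sign], int]
    fiber_names: Dict[int, str]


def quotient_base(
    network: RegulatoryNetwork, partition: FiberPartition
) -> BaseGraph:
    """Collapse each fiber to a single node of the base graph."""
    names = {fid: min(genes) for fid, genes in partition.fibers.items()}
    # per-gene in-edge counts grouped by (source fiber, sign)
    per_gene: Dict[str, Dict[Tuple[int, Sign], int]] = {}
    for g in network.genes:
        counts: Dict[Tuple[int, Sign], int] = {}
        for src, sign in network.in_edges(g):
            key = (partition.coloring[src], sign)
            counts[key] = counts.get(key, 0) + 1
        per_gene[g] = counts
    base = RegulatoryNetwork()
    multiplicity: Dict[Tuple[str, str, Sign], int] = {}
    for fid, genes in partition.fibers.items():
        rep, *rest = sorted(genes)
        for other in rest:
            if per_gene[other] != per_gene[rep]:
                raise NetworkIntegrityError(
                    f"partition not balanced: {rep!r} and {other!r} share a "
                    "fiber but have different signed in-edge profiles"
                )
        base.add_gene(names[fid])
        for (src_fid, sign), count in per_gene[rep].items():
            base.add_edge(names[src_fid], names[fid], sign)
            multiplicity[(names[src_fid], names[fid], sign)] = count
    return BaseGraph(network=base, multiplicity=multiplicity, fiber_names=names)


@dataclass
class FiberClass:
    """Branching-ratio classification of a fiber: the |n, l> nomenclature."""

    n: float  # branching ratio at finite depth
    ell: int  # number of distinct external-regulator fibers
    m: Optional[int] = None  # extra-loop count in Q_t = n Q_{t-1} + m Q_{t-d}
    d: Optional[int] = None  # extra-loop length
    label: str = ""


def _fit_q_recurrence(Q: Sequence[int]) -> Optional[Tuple[int, int, int]]:
    """Fit small integers (n, m, d) with Q_t = n Q_{t-1} + m Q_{t-d} exactly."""
    best = None
    for n_i, m_i, d_i in _iproduct(range(0, 4), range(0, 4), range(2, 6)):
        if len(Q) <= d_i + 2:
            continue
        if all(
            Q[t] == n_i * Q[t - 1] + m_i * Q[t - d_i]
            for t in range(d_i, len(Q))
        ):
            cand = (n_i, m_i, d_i)
            if best is None or (cand[1], cand[2]) < (best[1], best[2]):
                best = cand
    return best


def classify_fiber(
    network: RegulatoryNetwork,
    fiber_genes: Set[str],
    partition: FiberPartition,
    depth: int = 40,
    tol: float = 1e-3,
) -> FiberClass:
    """Assign the |n, l> class of a fiber from a minimal balanced coloring.

    ``n`` is the depth-``depth`` branching ratio of a representative's input
    tree (all members are isomorphic, so the choice is immaterial);
    ``ell`` counts the distinct fibers of regulators that feed the fiber
    from outside its strongly-connected loop core.
    """
    rep = min(fiber_genes)
    n = branching_ratio(network, rep, depth)
    tree = input_tree(network, rep, depth, max_nodes=0)
    fit = _fit_q_recurrence(tree.Q)

    # loop core: nontrivial SCCs (size > 1 or self-looped) of fiber members
    g = network.to_networkx()
    core: Set[str] = set()
    for comp in nx.strongly_connected_components(g):
        if comp & fiber_genes:
            if len(comp) > 1 or any(network.has_edge(x, x) for x in comp):
                core |= comp
    external_fibers = {
        partition.coloring[src]
        for gene in fiber_genes
        for src, _ in network.in_edges(gene)
        if src not in core and src not in fiber_genes
    }
    ell = len(external_fibers)

    intra_loop = bool(core & fiber_genes) or any(
        network.has_edge(x, x) for x in fiber_genes
    )
    if abs(n - 2.0) <= tol:
        label = "n = 2"
    elif abs(n - GOLDEN_RATIO) <= tol:
        label = "Fibonacci"
    elif abs(n - 1.0) <= tol and ell == 0 and intra_loop:
        label = "AR |1,0>"
    elif abs(n - 1.0) <= tol and ell == 1:
        label = "FFF |1,1>"
    elif abs(n - 1.0) <= tol:
        label = f"|1,{ell}>"
    else:
        label = f"|n={n:.4f}, l={ell}>"
    m_fit, d_fit = (None, None)
    if fit is not None:
        _, m_fit, d_fit = fit
        if m_fit == 0:
            d_fit = None
    return FiberClass(n=n, ell=ell, m=m_fit, d=d_fit, label=label)


# ---------------------------------------------------------------------------
# Frustration / SAT-UNSAT classification
# ---------------------------------------------------------------------------

def frustration_count(
    network: RegulatoryNetwork, state: Dict[str, int]
) -> int:
    """Number of signed interactions unsatisfied by a high/low assignment.

    An activator edge is satisfied iff the target's state equals the
    source's; a repressor edge iff the target's state is the opposite of
    the source's.  Unknown-sign edges are unsupported.
    """
    bad = 0
    for src, tgt, sign in network.edges:
        if sign is Sign.UNKNOWN:
            raise NetworkIntegrityError(
                f"edge {src}->{tgt} has unknown sign; frustration undefined"
            )
        s, t = bool(state[src]), bool(state[tgt])
        ok = (t == s) if sign is Sign.ACTIVATOR else (t != s)
        if not ok:
            bad += 1
    return bad


def sat_classify(network: RegulatoryNetwork, max_genes: int = 20) -> str:
    """SAT iff some high/low assignment (with external drives high)
    satisfies every signed interaction; UNSAT circuits are frustrated and
    oscillate.  Exhaustive over the free genes (circuit scale only)."""
    genes = sorted(network.genes)
    if len(genes) > max_genes:
        raise ValueError(
            f"sat_classify is exhaustive; refusing {len(genes)} > {max_genes} genes"
        )
    sources = [g for g in genes if network.in_degree(g) == 0]
    free = [g for g in genes if network.in_degree(g) > 0]
    for bits in _iproduct((1, 0), repeat=len(free)):
        state = {g: 1 for g in sources}
        state.update(dict(zip(free, bits)))
        if frustration_count(network, state) == 0:
            return "SAT"
    return "UNSAT"
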