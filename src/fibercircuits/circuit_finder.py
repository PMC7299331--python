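"""Locate symmetric fiber building blocks and broken-symmetry memory circuits.

Symmetric blocks (found via the minimal balanced coloring and classified by
branching ratio): the autoregulation (AR) fiber, the feed-forward fiber
(FFF), the Fibonacci fiber, and the n = 2 fiber.  Broken-symmetry blocks
(found by constrained subgraph search): the SR, Clocked SR and JK
flip-flops — each obtained conceptually by duplicating the corresponding
symmetric circuit into two mutually repressing replicas (a toggle switch)
and breaking the symmetry with distinct set/reset inputs.

Sign constraints follow the figures where they are fixed: the replica pair
must be mutually *repressing*; peripheral edges (inputs S/R/J/K/CLK and
the X -> Y stages, drawn with mixed or uncharacterised signs) are accepted
with any sign.  Matches are de-duplicated by the unordered replica pair
plus input assignment; overlapping matches sharing genes are all reported
(counts are instances, not disjoint sets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import networkx as nx

from .fibration import (
    FiberClass,
    classify_fiber,
    minimal_balanced_coloring,
    sat_classify,
)
from .graph_core import RegulatoryNetwork, Sign

__all__ = [
    "CIRCUIT_TYPES",
    "CircuitMatch",
    "find_fiber_blocks",
    "find_sr_flipflops",
    "find_clocked_sr_flipflops",
    "find_jk_flipflops",
    "find_circuits",
    "count_circuits",
]

#: All named circuit types, in hierarchy order.
CIRCUIT_TYPES = (
    "AR_fiber",
    "FFF",
    "Fibonacci",
    "n2_fiber",
    "SR_flipflop",
    "ClockedSR_flipflop",
    "JK_flipflop",
)

_LABEL_TO_TYPE = {
    "AR |1,0>": "AR_fiber",
    "FFF |1,1>": "FFF",
    "Fibonacci": "Fibonacci",
    "n = 2": "n2_fiber",
}


@dataclass
class CircuitMatch:
    """A located circuit instance with role assignments."""

    circuit_type: str
    roles: Dict[str, str]  # role name (X, Y, Z, S, R, ...) -> gene
    edges_used: Set[Tuple[str, str, Sign]] = field(default_factory=set)
    sat_state: str = "n/a"  # SAT | UNSAT | n/a
    fiber_class: Optional[FiberClass] = None
    wiring: str = ""  # parity | chiral for JK matches

    @property
    def genes(self) -> FrozenSet[str]:
        return frozenset(self.roles.values())

    def key(self) -> Tuple:
        """Canonical de-duplication key (replica-swap invariant)."""
        return (self.circuit_type, frozenset(self.roles.items()))


def _induced_edges(
    network: RegulatoryNetwork, genes: Set[str]
) -> Set[Tuple[str, str, Sign]]:
    return {
        (u, v, s) for u, v, s in network.edges if u in genes and v in genes
    }


def _sat_of(network: RegulatoryNetwork, genes: Set[str]) -> str:
    sub = RegulatoryNetwork(genes=genes, edges=_induced_edges(network, genes))
    if any(s is Sign.UNKNOWN for _, _, s in sub.edges):
        return "n/a"
    try:
        return sat_classify(sub)
    except ValueError:
        return "n/a"


# ---------------------------------------------------------------------------
# Symmetric fiber blocks
# ---------------------------------------------------------------------------

def find_fiber_blocks(
    network: RegulatoryNetwork,
    depth: int = 40,
    include_other: bool = False,
) -> List[CircuitMatch]:
    """One match per symmetric building block of the network.

    Runs the minimal balanced coloring, classifies every non-trivial fiber
    (size >= 2, or a self-looped singleton), then groups fibers that are
    generated by the same loop core — the union of non-trivial strongly
    connected components in the fiber's regulatory ancestry — into a single
    match, since one loop can synchronize several balanced classes (e.g.
    the Fibonacci circuit synchronizes {X, Z} while {Y} carries the loop).
    """
    partition = minimal_balanced_coloring(network)
    candidates = partition.nontrivial_fibers(network)
    if not candidates:
        return []

    g = network.to_networkx()
    nontrivial_sccs = [
        comp
        for comp in nx.strongly_connected_components(g)
        if len(comp) > 1 or any(network.has_edge(x, x) for x in comp)
    ]

    def loop_core(fiber: Set[str]) -> FrozenSet[str]:
        ancestry = set(fiber)
        for gene in fiber:
            ancestry |= nx.ancestors(g, gene)
        core: Set[str] = set()
        for comp in nontrivial_sccs:
            if comp & ancestry:
                core |= comp
        return frozenset(core)

    groups: Dict[FrozenSet[str], List[Set[str]]] = {}
    for fiber in candidates:
        key = loop_core(fiber) or frozenset(fiber)
        groups.setdefault(key, []).append(fiber)

    matches: List[CircuitMatch] = []
    for core, fibers in sorted(groups.items(), key=lambda kv: sorted(kv[0])):
        # classify using the fiber that carries the loop if there is one
        fibers = sorted(fibers, key=lambda f: (not (f & core), min(f)))
        fclass = classify_fiber(network, fibers[0], partition, depth=depth)
        ctype = _LABEL_TO_TYPE.get(fclass.label, "other")
        if ctype == "other" and not include_other:
            continue
        all_genes = set().union(*fibers) | set(core)
        external = sorted(
            {
                src
                for gene in all_genes
                for src, _ in network.in_edges(gene)
                if src not in all_genes
            }
        )
        roles = _fiber_roles(network, ctype, all_genes, core)
        i = 1
        for x in external:
            while ("X" if i == 1 else f"X{i}") in roles:
                i += 1
            roles["X" if i == 1 else f"X{i}"] = x
            i += 1
        scope = all_genes | set(external)
        matches.append(
            CircuitMatch(
                circuit_type=ctype,
                roles=roles,
                edges_used=_induced_edges(network, scope),
                sat_state=_sat_of(network, scope),
                fiber_class=fclass,
            )
        )
    return matches


def _fiber_roles(
    network: RegulatoryNetwork,
    ctype: str,
    genes: Set[str],
    core: FrozenSet[str],
) -> Dict[str, str]:
    """Name the genes of a fiber block: loop gene(s) Y (and X), targets Z."""
    roles: Dict[str, str] = {}
    core_sorted = sorted(core)
    if ctype == "Fibonacci" and len(core_sorted) == 2:
        # the self-looped core gene is Y, its feedback partner is X
        looped = [x for x in core_sorted if network.has_edge(x, x)]
        other = [x for x in core_sorted if x not in looped]
        if looped and other:
            roles["Y"], roles["X"] = looped[0], other[0]
        else:
            roles["Y"], roles["X"] = core_sorted[0], core_sorted[1]
    elif core_sorted:
        roles["Y"] = core_sorted[0]
        for i, x in enumerate(core_sorted[1:], start=2):
            roles[f"Y{i}"] = x
    rest = sorted(genes - set(roles.values()))
    for i, x in enumerate(rest, start=1):
        roles["Z" if i == 1 else f"Z{i}"] = x
    return roles


# ---------------------------------------------------------------------------
# Broken-symmetry flip-flops (constrained search anchored on toggle pairs)
# ---------------------------------------------------------------------------

def _mutual_repressor_pairs(
    network: RegulatoryNetwork,
) -> List[Tuple[str, str]]:
    pairs = []
    for u, v, s in network.edges:
        if s is Sign.REPRESSOR and u < v and network.has_edge(v, u):
            if network.sign(v, u) is Sign.REPRESSOR:
                pairs.append((u, v))
    return sorted(pairs)


def _match_edges(
    network: RegulatoryNetwork, pairs: List[Tuple[str, str]]
) -> Set[Tuple[str, str, Sign]]:
    return {(u, v, network.sign(u, v)) for u, v in pairs}


def find_sr_flipflops(network: RegulatoryNetwork) -> List[CircuitMatch]:
    """SR flip-flops: a mutually repressing pair {Y, Y'} (the toggle, i.e.
    the symmetry-broken replica of the AR loop) with two distinct external
    inputs S -> Y and R -> Y' (any sign).  Reported once per unordered
    replica pair and input assignment."""
    matches: Dict[Tuple, CircuitMatch] = {}
    for a, b in _mutual_repressor_pairs(network):
        ins_a = [s for s, _ in network.in_edges(a) if s not in (a, b)]
        ins_b = [s for s, _ in network.in_edges(b) if s not in (a, b)]
        for s in ins_a:
            for r in ins_b:
                if r == s:
                    continue
                m = CircuitMatch(
                    circuit_type="SR_flipflop",
                    roles={"Y": a, "Yp": b, "S": s, "R": r},
                    edges_used=_match_edges(
                        network, [(a, b), (b, a), (s, a), (r, b)]
                    ),
                )
                matches[frozenset({(s, a), (r, b)})] = m
    return [matches[k] for k in sorted(matches, key=sorted)]


def find_clocked_sr_flipflops(network: RegulatoryNetwork) -> List[CircuitMatch]:
    """Clocked SR flip-flops: replica-duplicated FFF with a clock.

    Toggle pair Y -| Y' -| Y; stage genes X -> Y and X' -> Y'; a clock gene
    CLK regulating both X and X'; distinct inputs S -> X and R -> X'.  All
    seven role genes distinct; peripheral signs unconstrained."""
    matches: Dict[Tuple, CircuitMatch] = {}
    for a, b in _mutual_repressor_pairs(network):
        ins_a = [x for x, _ in network.in_edges(a) if x not in (a, b)]
        ins_b = [x for x, _ in network.in_edges(b) if x not in (a, b)]
        for x in ins_a:
            in_x = {s for s, _ in network.in_edges(x)}
            for xp in ins_b:
                if xp == x:
                    continue
                in_xp = {s for s, _ in network.in_edges(xp)}
                used = {a, b, x, xp}
                for clk in sorted((in_x & in_xp) - used):
                    for s in in_x - used - {clk}:
                        for r in in_xp - used - {clk, s}:
                            key = (clk, frozenset({(s, x, a), (r, xp, b)}))
                            matches[key] = CircuitMatch(
                                circuit_type="ClockedSR_flipflop",
                                roles={
                                    "Y": a, "Yp": b, "X": x, "Xp": xp,
                                    "CLK": clk, "S": s, "R": r,
                                },
                                edges_used=_match_edges(
                                    network,
                                    [(a, b), (b, a), (x, a), (xp, b),
                                     (clk, x), (clk, xp), (s, x), (r, xp)],
                                ),
                            )
    return [matches[k] for k in sorted(matches, key=repr)]


def find_jk_flipflops(
    network: RegulatoryNetwork, chirality: str = "parity"
) -> List[CircuitMatch]:
    """JK flip-flops: replica-duplicated Fibonacci fiber with inputs J, K.

    Toggle pair Y -| Y' -| Y; stages X -> Y, X' -> Y'; the Fibonacci
    feedback loops reappear as cross ('parity', the wiring realized in
    biological circuits: Y -> X' and Y' -> X) or straight ('chiral':
    Y -> X and Y' -> X') feedback; distinct inputs J -> X and K -> X'.
    ``chirality`` selects "parity" (default), "chiral", or "both".
    """
    if chirality not in ("parity", "chiral", "both"):
        raise ValueError(f"chirality must be parity|chiral|both, got {chirality!r}")
    wirings = ("parity", "chiral") if chirality == "both" else (chirality,)
    matches: Dict[Tuple, CircuitMatch] = {}
    for a, b in _mutual_repressor_pairs(network):
        ins_a = [x for x, _ in network.in_edges(a) if x not in (a, b)]
        ins_b = [x for x, _ in network.in_edges(b) if x not in (a, b)]
        for x in ins_a:
            for xp in ins_b:
                if xp == x:
                    continue
                for wiring in wirings:
                    if wiring == "parity":
                        fb = [(a, xp), (b, x)]  # Y feeds X', Y' feeds X
                    else:
                        fb = [(a, x), (b, xp)]  # Y feeds X, Y' feeds X'
                    if not all(network.has_edge(u, v) for u, v in fb):
                        continue
                    used = {a, b, x, xp}
                    in_x = {s for s, _ in network.in_edges(x)}
                    in_xp = {s for s, _ in network.in_edges(xp)}
                    for j in in_x - used:
                        for k in in_xp - used - {j}:
                            key = (wiring, frozenset({(j, x, a), (k, xp, b)}))
                            matches[key] = CircuitMatch(
                                circuit_type="JK_flipflop",
                                roles={
                                    "Y": a, "Yp": b, "X": x, "Xp": xp,
                                    "J": j, "K": k,
                                },
                                edges_used=_match_edges(
                                    network,
                                    [(a, b), (b, a), (x, a), (xp, b)]
                                    + fb + [(j, x), (k, xp)],
                                ),
                                wiring=wiring,
                            )
    return [matches[k] for k in sorted(matches, key=repr)]


# ---------------------------------------------------------------------------
# Convenience front-ends
# ---------------------------------------------------------------------------

_FIBER_TYPES = ("AR_fiber", "FFF", "Fibonacci", "n2_fiber")


def find_circuits(
    network: RegulatoryNetwork,
    types: Tuple[str, ...] = CIRCUIT_TYPES,
    chirality: str = "parity",
) -> List[CircuitMatch]:
    """Run the requested finders and concatenate their matches."""
    unknown = set(types) - set(CIRCUIT_TYPES)
    if unknown:
        raise ValueError(f"unknown circuit types: {sorted(unknown)}")
    out: List[CircuitMatch] = []
    if set(types) & set(_FIBER_TYPES):
        out.extend(
            m for m in find_fiber_blocks(network) if m.circuit_type in types
        )
    if "SR_flipflop" in types:
        out.extend(find_sr_flipflops(network))
    if "ClockedSR_flipflop" in types:
        out.extend(find_clocked_sr_flipflops(network))
    if "JK_flipflop" in types:
        out.extend(find_jk_flipflops(network, chirality=chirality))
    return out


def count_circuits(
    network: RegulatoryNetwork,
    types: Tuple[str, ...] = CIRCUIT_TYPES,
    chirality: str = "parity",
) -> Dict[str, int]:
    """Instance counts per circuit type (the N_real column)."""
    counts = {t: 0 for t in types}
    for m in find_circuits(network, types=types, chirality=chirality):
        if m.circuit_type in counts:
            counts[m.circuit_type] += 1
    return counts
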