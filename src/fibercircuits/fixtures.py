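"""Canonical circuits and a synthetic-network generator with planted ground truth.

``make_circuit`` builds each named circuit with its textbook topology and
role-named genes; ``embed_circuits`` plants any mix of them, node-disjoint,
inside a random background network so that every finder and statistic can
be validated against known ground truth without any external database.

Background edges never add in-edges to planted genes, so planted fibers
and flip-flop patterns are guaranteed to survive embedding (the background
can only create *additional* true instances of a pattern, never destroy a
planted one).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

from .circuit_finder import CircuitMatch
from .graph_core import RegulatoryNetwork, Sign

__all__ = [
    "CANONICAL_CIRCUITS",
    "PlantedNetwork",
    "make_circuit",
    "embed_circuits",
    "RECOVERABLE_ROLES",
    "planted_recovered",
]

A, R = Sign.ACTIVATOR, Sign.REPRESSOR

#: topology per circuit kind: (source role, target role, sign)
_TOPOLOGIES: Dict[str, List[Tuple[str, str, Sign]]] = {
    # feed-forward loop: no symmetry, no synchronization
    "FFL": [("X", "Y", A), ("X", "Z", A), ("Y", "Z", A)],
    # FFL + activator autoregulation on Y: fiber {Y, Z}, SAT fixed point
    "SAT_FFF": [("X", "Y", A), ("X", "Z", A), ("Y", "Z", A), ("Y", "Y", A)],
    # repressor autoregulation version: frustrated, oscillates
    "UNSAT_FFF": [("X", "Y", A), ("X", "Z", A), ("Y", "Z", R), ("Y", "Y", R)],
    # autoregulated gene driving a synchronized target
    "AR_FIBER": [("Y", "Y", R), ("Y", "Z", R)],
    # dual-feedback loop: input tree is the Fibonacci sequence
    "FIBONACCI": [("X", "Y", R), ("Y", "Y", R), ("Y", "X", R), ("Y", "Z", R)],
    # two coupled autoregulators: branching ratio 2
    "N2_FIBER": [
        ("X", "X", A), ("Y", "Y", A), ("X", "Y", A), ("Y", "X", A),
        ("Y", "Z", A),
    ],
    # toggle switch with distinct set/reset inputs
    "SR": [("Y", "Yp", R), ("Yp", "Y", R), ("S", "Y", A), ("R", "Yp", A)],
    "CLOCKED_SR": [
        ("Y", "Yp", R), ("Yp", "Y", R),
        ("X", "Y", A), ("Xp", "Yp", A),
        ("CLK", "X", A), ("CLK", "Xp", A),
        ("S", "X", A), ("R", "Xp", A),
    ],
    # parity wiring: Y feeds X' and Y' feeds X
    "JK": [
        ("Y", "Yp", R), ("Yp", "Y", R),
        ("X", "Y", R), ("Xp", "Yp", R),
        ("Y", "Xp", R), ("Yp", "X", R),
        ("J", "X", A), ("K", "Xp", A),
    ],
}

CANONICAL_CIRCUITS = tuple(_TOPOLOGIES)

#: circuit kind -> the finder type its planted instance must register as
_KIND_TO_TYPE = {
    "SAT_FFF": "FFF",
    "UNSAT_FFF": "FFF",
    "AR_FIBER": "AR_fiber",
    "FIBONACCI": "Fibonacci",
    "N2_FIBER": "n2_fiber",
    "SR": "SR_flipflop",
    "CLOCKED_SR": "ClockedSR_flipflop",
    "JK": "JK_flipflop",
}


def make_circuit(kind: str, prefix: str = "") -> RegulatoryNetwork:
    """The canonical topology of a named circuit, with role-named genes.

    ``prefix`` is prepended to every gene name (used when planting several
    circuits in one network).
    """
    if kind not in _TOPOLOGIES:
        raise ValueError(
            f"unknown circuit kind {kind!r}; known: {sorted(_TOPOLOGIES)}"
        )
    net = RegulatoryNetwork()
    for src, tgt, sign in _TOPOLOGIES[kind]:
        net.add_edge(prefix + src, prefix + tgt, sign)
    return net


#: the roles of each planted circuit that every finder is guaranteed to
#: report (pure output genes like the Z of the n = 2 fiber are regulated by
#: the circuit but carry no symmetry of their own, so finders rightly omit
#: them)
RECOVERABLE_ROLES: Dict[str, Tuple[str, ...]] = {
    "SAT_FFF": ("X", "Y", "Z"),
    "UNSAT_FFF": ("X", "Y", "Z"),
    "AR_FIBER": ("Y", "Z"),
    "FIBONACCI": ("X", "Y", "Z"),
    "N2_FIBER": ("X", "Y"),
    "SR": ("Y", "Yp", "S", "R"),
    "CLOCKED_SR": ("Y", "Yp", "X", "Xp", "CLK", "S", "R"),
    "JK": ("Y", "Yp", "X", "Xp", "J", "K"),
}


def planted_recovered(planted: CircuitMatch, found: List[CircuitMatch]) -> bool:
    """True iff some found match of the same type covers the planted
    circuit's recoverable genes (found matches may legitimately include
    extra synchronized genes the background happened to create)."""
    return any(
        m.circuit_type == planted.circuit_type
        and planted.genes <= m.genes
        for m in found
    )


def _ground_truth(kind: str, prefix: str) -> Optional[CircuitMatch]:
    ctype = _KIND_TO_TYPE.get(kind)
    if ctype is None:  # FFL has no symmetry: nothing to recover
        return None
    roles = {role: prefix + role for role in RECOVERABLE_ROLES[kind]}
    edges = {
        (prefix + s, prefix + t, sign) for s, t, sign in _TOPOLOGIES[kind]
    }
    return CircuitMatch(circuit_type=ctype, roles=roles, edges_used=edges)


@dataclass
class PlantedNetwork:
    """A synthetic network with known planted circuits."""

    network: RegulatoryNetwork
    ground_truth: List[CircuitMatch]
    background_spec: Tuple[int, Dict[str, int], int] = field(
        default_factory=lambda: (0, {}, 0)
    )


def embed_circuits(
    counts: Mapping[str, int],
    n_background_genes: int = 200,
    edges_per_sign: Optional[Mapping[Sign, int]] = None,
    seed: int = 0,
    allow_self_loops: bool = False,
) -> PlantedNetwork:
    """Plant circuits node-disjointly in a random background network.

    ``counts`` maps circuit kinds (see :data:`CANONICAL_CIRCUITS`) to the
    number of copies to plant; each copy gets fresh genes named
    ``c<i>_<role>``.  Background genes ``g000...`` receive random directed
    edges (default 2:1 activator:repressor, a ratio typical of curated
    transcriptional networks); background edges may originate anywhere but
    only *target* background genes, so planted circuits keep their exact
    signed in-edge structure.  Deterministic given ``seed``.
    """
    for kind in counts:
        if kind not in _TOPOLOGIES:
            raise ValueError(f"unknown circuit kind {kind!r}")
    if n_background_genes < 0:
        raise ValueError("n_background_genes must be >= 0")
    if edges_per_sign is None:
        n = n_background_genes
        edges_per_sign = {A: n, R: n // 2}
    rng = random.Random(seed)
    net = RegulatoryNetwork()
    ground_truth: List[CircuitMatch] = []
    idx = 0
    for kind in sorted(counts):
        for _ in range(counts[kind]):
            prefix = f"c{idx}_"
            idx += 1
            for src, tgt, sign in _TOPOLOGIES[kind]:
                net.add_edge(prefix + src, prefix + tgt, sign)
            gt = _ground_truth(kind, prefix)
            if gt is not None:
                ground_truth.append(gt)
    circuit_genes = set(net.genes)
    bg_genes = [f"g{i:03d}" for i in range(n_background_genes)]
    for g in bg_genes:
        net.add_gene(g)
    if not bg_genes and any(edges_per_sign.values()):
        raise ValueError(
            "cannot place background edges without background genes"
        )
    all_sources = sorted(circuit_genes) + bg_genes
    existing = {(u, v) for u, v, _ in net.edges}
    for sign in sorted(edges_per_sign, key=lambda s: s.value):
        wanted = edges_per_sign[sign]
        placed = 0
        attempts = 0
        max_attempts = 100 * max(wanted, 1)
        while placed < wanted and attempts < max_attempts:
            attempts += 1
            src = rng.choice(all_sources)
            tgt = rng.choice(bg_genes)
            if src == tgt and not allow_self_loops:
                continue
            if (src, tgt) in existing:
                continue
            net.add_edge(src, tgt, sign)
            existing.add((src, tgt))
            placed += 1
        if placed < wanted:
            raise ValueError(
                f"could not place {wanted} background edges of sign "
                f"{sign.value}; network too dense"
            )
    spec = (
        n_background_genes,
        {s.value: c for s, c in edges_per_sign.items()},
        seed,
    )
    return PlantedNetwork(
        network=net, ground_truth=ground_truth, background_spec=spec
    )
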