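"""Degree- and sign-preserving randomization and circuit-count Z-scores.

Significance of a circuit count is assessed against an ensemble of
randomized networks with the same per-gene in- and out-degree sequence
*per interaction sign* as the original, generated by repeated double-edge
swaps within each sign class: two edges (a -> b) and (c -> d) of the same
sign are rewired to (a -> d) and (c -> b) unless the rewiring would create
a duplicate ordered pair or a self-loop.  Self-loops are kept fixed as
their own invariant class — autoregulation is structurally meaningful here
(it defines the AR fiber), so the null preserves each gene's
autoregulation status.

The Z-score for a circuit type is (N_real - mean(N_rand)) / sd(N_rand)
with the table conventions: "N/A" when N_real = 0, "Inf" when the
randomized counts have zero spread below N_real, and the bound form "> 3"
when the circuit never occurs in the ensemble at all.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .circuit_finder import CIRCUIT_TYPES, count_circuits
from .graph_core import RegulatoryNetwork, Sign

__all__ = ["NullStats", "randomize", "zscores"]


@dataclass
class NullStats:
    """Observed-vs-random counts for one circuit type."""

    circuit_type: str
    n_real: int
    rand_mean: float
    rand_sd: float
    z: Optional[float]  # None encodes N/A; may be +/- inf
    n_replicates: int
    seed: int

    @property
    def z_display(self) -> str:
        """The table formatting convention for the Z column."""
        if self.z is None:
            return "N/A"
        if math.isinf(self.z):
            return "Inf" if self.z > 0 else "-Inf"
        return f"{self.z:.2f}"

    @property
    def z_bound_display(self) -> str:
        """The conservative bound form: "> 3" when the circuit never occurs
        in the randomized ensemble at all (mean = sd = 0, N_real > 0)."""
        if (
            self.z is not None
            and self.rand_sd == 0.0
            and self.rand_mean == 0.0
            and self.n_real > 0
        ):
            return "> 3"
        return self.z_display


def randomize(
    network: RegulatoryNetwork,
    n_swaps: Optional[int] = None,
    seed: int = 0,
    preserve_self_loops: bool = True,
) -> RegulatoryNetwork:
    """Sign-class double-edge-swap randomization.

    ``n_swaps`` is the number of *attempted* swaps (default 10x the edge
    count, a standard mixing heuristic); rejected proposals (duplicate
    ordered pair, self-loop creation) count as attempts.  Deterministic
    given ``seed``.  Networks with too few swappable edges in every sign
    class are returned as unchanged copies.
    """
    rng = random.Random(seed)
    edge_pairs = {(u, v) for u, v, _ in network.edges}
    by_sign: Dict[Sign, List[Tuple[str, str]]] = {s: [] for s in Sign}
    fixed: List[Tuple[str, str, Sign]] = []
    for u, v, s in sorted(network.edges):
        if preserve_self_loops and u == v:
            fixed.append((u, v, s))
        else:
            by_sign[s].append((u, v))
    if n_swaps is None:
        n_swaps = 10 * network.n_edges()
    swappable = [s for s in Sign if len(by_sign[s]) >= 2]
    if swappable and n_swaps > 0:
        weights = [len(by_sign[s]) for s in swappable]
        for _ in range(n_swaps):
            sign = rng.choices(swappable, weights=weights)[0]
            pool = by_sign[sign]
            i = rng.randrange(len(pool))
            j = rng.randrange(len(pool))
            if i == j:
                continue
            a, b = pool[i]
            c, d = pool[j]
            if a == d or c == b:
                continue  # would create a self-loop
            if (a, d) in edge_pairs or (c, b) in edge_pairs:
                continue  # would create a duplicate ordered pair
            edge_pairs -= {(a, b), (c, d)}
            edge_pairs |= {(a, d), (c, b)}
            pool[i] = (a, d)
            pool[j] = (c, b)
    result = RegulatoryNetwork(genes=network.genes)
    for u, v, s in fixed:
        result.add_edge(u, v, s)
    for s in Sign:
        for u, v in by_sign[s]:
            result.add_edge(u, v, s)
    return result


def zscores(
    network: RegulatoryNetwork,
    types: Sequence[str] = CIRCUIT_TYPES,
    n_replicates: int = 1000,
    n_swaps: Optional[int] = None,
    seed: int = 0,
    chirality: str = "parity",
) -> List[NullStats]:
    """Circuit-count Z-scores against the degree/sign-preserving null.

    Runs the finders on the original network and on ``n_replicates``
    randomizations (each from a child seed derived deterministically from
    ``seed``); the SD uses the population (divide-by-n) convention.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    types = tuple(types)
    real = count_circuits(network, types=types, chirality=chirality)
    master = random.Random(seed)
    child_seeds = [master.randrange(2**31) for _ in range(n_replicates)]
    rand_counts: Dict[str, List[int]] = {t: [] for t in types}
    for child in child_seeds:
        rnd = randomize(network, n_swaps=n_swaps, seed=child)
        counts = count_circuits(rnd, types=types, chirality=chirality)
        for t in types:
            rand_counts[t].append(counts[t])
    out: List[NullStats] = []
    for t in types:
        vals = rand_counts[t]
        mean = sum(vals) / len(vals)
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / len(vals))
        n_real = real[t]
        z: Optional[float]
        if n_real == 0:
            z = None
        elif sd == 0.0:
            if n_real > mean:
                z = math.inf
            elif n_real < mean:
                z = -math.inf
            else:
                z = 0.0
        else:
            z = (n_real - mean) / sd
        out.append(
            NullStats(
                circuit_type=t,
                n_real=n_real,
                rand_mean=mean,
                rand_sd=sd,
                z=z,
                n_replicates=n_replicates,
                seed=seed,
            )
        )
    return out
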