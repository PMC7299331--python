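"""Signed directed regulatory networks: data model, edge-list I/O, validation.

A regulatory network is a directed graph over genes in which every edge
carries one of three signs: ``activator`` (positive transcriptional
regulation), ``repressor`` (negative regulation), or ``unknown`` (an
interaction whose functionality has not been characterised).  At most one
edge is allowed per ordered gene pair — a gene regulating another both
positively and negatively is rejected rather than merged, because the sign
drives both the threshold dynamics and the symmetry analysis.

Gene identifiers are opaque, case-sensitive strings; no normalisation is
attempted (naming conventions differ between species databases and belong
to the caller).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Set, Tuple

import networkx as nx

__all__ = [
    "Sign",
    "RegulatoryNetwork",
    "EdgeListError",
    "NetworkIntegrityError",
    "read_edge_list",
    "write_edge_list",
    "degree_profile",
]


class Sign(str, Enum):
    """Regulation sign of a directed interaction."""

    ACTIVATOR = "activator"
    REPRESSOR = "repressor"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Default mapping of raw edge-list tokens onto signs.  Anything not listed
#: maps to UNKNOWN (with a warning for tokens other than the canonical "?").
SIGN_TOKENS: Dict[str, Sign] = {
    "+": Sign.ACTIVATOR,
    "activator": Sign.ACTIVATOR,
    "activation": Sign.ACTIVATOR,
    "positive": Sign.ACTIVATOR,
    "-": Sign.REPRESSOR,
    "repressor": Sign.REPRESSOR,
    "repression": Sign.REPRESSOR,
    "negative": Sign.REPRESSOR,
    "?": Sign.UNKNOWN,
    "unknown": Sign.UNKNOWN,
}

#: Token used when serialising each sign.
SIGN_OUT: Dict[Sign, str] = {
    Sign.ACTIVATOR: "+",
    Sign.REPRESSOR: "-",
    Sign.UNKNOWN: "?",
}


class EdgeListError(ValueError):
    """A malformed edge-list line (reported with its line number)."""


class NetworkIntegrityError(ValueError):
    """A structural violation: conflicting duplicate edges, unknown genes, …"""


class RegulatoryNetwork:
    """A signed directed graph of genes and regulations.

    Thin wrapper around a :class:`networkx.DiGraph` whose edges carry a
    ``sign`` attribute.  Invariants enforced on construction and mutation:

    * at most one edge per ordered ``(source, target)`` pair (self-loops
      are permitted — autoregulation is structurally meaningful here);
    * every edge endpoint is a member of the gene set;
    * every sign is one of the three :class:`Sign` values.
    """

    def __init__(
        self,
        genes: Iterable[str] = (),
        edges: Iterable[Tuple[str, str, Sign | str]] = (),
    ) -> None:
        self._g = nx.DiGraph()
        for gene in genes:
            self._g.add_node(str(gene))
        for src, tgt, sign in edges:
            self.add_edge(src, tgt, sign)

    # -- construction ----------------------------------------------------
    def add_gene(self, gene: str) -> None:
        self._g.add_node(str(gene))

    def add_edge(self, source: str, target: str, sign: Sign | str) -> None:
        source, target = str(source), str(target)
        if not isinstance(sign, Sign):
            sign = SIGN_TOKENS.get(str(sign).strip().lower()) or Sign(sign)
        if self._g.has_edge(source, target):
            existing = self._g.edges[source, target]["sign"]
            if existing is not sign:
                raise NetworkIntegrityError(
                    f"conflicting signs for edge {source}->{target}: "
                    f"{existing.value} vs {sign.value}"
                )
            return  # identical duplicate collapses silently
        self._g.add_edge(source, target, sign=sign)

    # -- accessors -------------------------------------------------------
    @property
    def genes(self) -> Set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> Set[Tuple[str, str, Sign]]:
        return {(u, v, d["sign"]) for u, v, d in self._g.edges(data=True)}

    def n_genes(self) -> int:
        return self._g.number_of_nodes()

    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_gene(self, gene: str) -> bool:
        return self._g.has_node(gene)

    def has_edge(self, source: str, target: str) -> bool:
        return self._g.has_edge(source, target)

    def sign(self, source: str, target: str) -> Sign:
        return self._g.edges[source, target]["sign"]

    def in_edges(self, gene: str) -> List[Tuple[str, Sign]]:
        """Regulators of ``gene`` as ``(source, sign)`` pairs."""
        return [(u, d["sign"]) for u, _, d in self._g.in_edges(gene, data=True)]

    def out_edges(self, gene: str) -> List[Tuple[str, Sign]]:
        return [(v, d["sign"]) for _, v, d in self._g.out_edges(gene, data=True)]

    def in_degree(self, gene: str) -> int:
        return self._g.in_degree(gene)

    def to_networkx(self) -> nx.DiGraph:
        """A copy of the underlying signed digraph."""
        return self._g.copy()

    # -- comparisons -----------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return self.genes == other.genes and self.edges == other.edges

    def __hash__(self) -> int:  # pragma: no cover - not used as dict key
        return hash((frozenset(self.genes), frozenset(self.edges)))

    def __repr__(self) -> str:
        return (
            f"RegulatoryNetwork({self.n_genes()} genes, {self.n_edges()} edges)"
        )

    def copy(self) -> "RegulatoryNetwork":
        n = RegulatoryNetwork()
        n._g = self._g.copy()
        return n


def _parse_sign(token: str, lineno: int) -> Sign:
    sign = SIGN_TOKENS.get(token.strip().lower())
    if sign is None:
        warnings.warn(
            f"line {lineno}: unrecognised sign token {token!r}; treating as unknown",
            stacklevel=3,
        )
        return Sign.UNKNOWN
    return sign


def read_edge_list(
    path,
    sign_tokens: Mapping[str, Sign] | None = None,
    comment: str = "#",
) -> RegulatoryNetwork:
    """Read a whitespace/tab separated edge list into a network.

    Each non-comment, non-blank line has columns ``source target [sign]``.
    Two-column lines are accepted with sign ``unknown``.  Duplicate identical
    lines collapse to one edge; the same ordered pair with two different
    signs raises :class:`NetworkIntegrityError`.
    """
    tokens = dict(SIGN_TOKENS if sign_tokens is None else sign_tokens)
    net = RegulatoryNetwork()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(comment):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise EdgeListError(
                    f"line {lineno}: expected at least 2 fields, got {len(fields)}"
                )
            src, tgt = fields[0], fields[1]
            if len(fields) >= 3:
                tok = fields[2].strip().lower()
                sign = tokens.get(tok)
                if sign is None:
                    sign = _parse_sign(fields[2], lineno)
            else:
                sign = Sign.UNKNOWN
            net.add_edge(src, tgt, sign)
    return net


def write_edge_list(network: RegulatoryNetwork, path) -> None:
    """Write a network as a sign-annotated edge list.

    Round-trips through :func:`read_edge_list` up to gene ordering; isolated
    genes are recorded as ``# node`` comment lines so the gene set survives.
    """
    isolated = sorted(
        g for g in network.genes
        if network.in_degree(g) == 0 and not network.out_edges(g)
    )
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# source\ttarget\tsign\n")
        for src, tgt, sign in sorted(network.edges):
            fh.write(f"{src}\t{tgt}\t{SIGN_OUT[sign]}\n")
        for gene in isolated:
            fh.write(f"# node\t{gene}\n")


def read_edge_list_with_isolated(path, **kwargs) -> RegulatoryNetwork:
    """Like :func:`read_edge_list` but also recovers ``# node`` comment lines
    written by :func:`write_edge_list`, restoring isolated genes."""
    net = read_edge_list(path, **kwargs)
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            fields = line.split()
            if len(fields) == 3 and fields[0] == "#" and fields[1] == "node":
                net.add_gene(fields[2])
    return net


def degree_profile(
    network: RegulatoryNetwork,
) -> Dict[str, Dict[Sign, Tuple[int, int]]]:
    """Per-gene ``(in-degree, out-degree)`` split by edge sign.

    This is the exact invariant the degree- and sign-preserving null model
    must conserve: summing in-degrees (or out-degrees) over genes for one
    sign gives the number of edges of that sign.
    """
    indeg: Dict[str, Dict[Sign, int]] = defaultdict(lambda: defaultdict(int))
    outdeg: Dict[str, Dict[Sign, int]] = defaultdict(lambda: defaultdict(int))
    for src, tgt, sign in network.edges:
        outdeg[src][sign] += 1
        indeg[tgt][sign] += 1
    profile: Dict[str, Dict[Sign, Tuple[int, int]]] = {}
    for gene in network.genes:
        profile[gene] = {
            s: (indeg[gene].get(s, 0), outdeg[gene].get(s, 0)) for s in Sign
        }
    return profile
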