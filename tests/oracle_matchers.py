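"""Brute-force role-assignment matchers used as oracles for the anchored
circuit finders, plus a seeded random-network generator for small graphs.

Each matcher enumerates candidate role tuples with plain nested loops and
explicit edge checks — no anchoring, no shared code with the package's
finders — and returns the same de-duplication keys the finders imply, so
the two can be compared set-to-set.
"""

import random

from fibercircuits import RegulatoryNetwork, Sign


def random_network(seed, n_min=4, n_max=8, repressor_bias=0.45):
    """A small random signed digraph, biased toward repressors so that
    mutually repressing pairs (the flip-flop anchors) occur often."""
    rng = random.Random(seed)
    n = rng.randint(n_min, n_max)
    genes = [f"g{i}" for i in range(n)]
    net = RegulatoryNetwork(genes=genes)
    n_edges = rng.randint(n, min(3 * n, n * n))
    for _ in range(n_edges):
        u, v = rng.choice(genes), rng.choice(genes)
        if net.has_edge(u, v):
            continue
        p = rng.random()
        if p < repressor_bias:
            sign = Sign.REPRESSOR
        elif p < 0.9:
            sign = Sign.ACTIVATOR
        else:
            sign = Sign.UNKNOWN
        net.add_edge(u, v, sign)
    return net


def _rep(net, u, v):
    return net.has_edge(u, v) and net.sign(u, v) is Sign.REPRESSOR


def brute_sr_keys(net):
    genes = sorted(net.genes)
    keys = set()
    for y in genes:
        for yp in genes:
            if yp == y or not (_rep(net, y, yp) and _rep(net, yp, y)):
                continue
            for s in genes:
                if s in (y, yp) or not net.has_edge(s, y):
                    continue
                for r in genes:
                    if r in (y, yp, s) or not net.has_edge(r, yp):
                        continue
                    keys.add(frozenset({(s, y), (r, yp)}))
    return keys


def brute_clocked_sr_keys(net):
    genes = sorted(net.genes)
    keys = set()
    for y in genes:
        for yp in genes:
            if yp == y or not (_rep(net, y, yp) and _rep(net, yp, y)):
                continue
            for x in genes:
                if x in (y, yp) or not net.has_edge(x, y):
                    continue
                for xp in genes:
                    if xp in (y, yp, x) or not net.has_edge(xp, yp):
                        continue
                    for clk in genes:
                        if clk in (y, yp, x, xp):
                            continue
                        if not (net.has_edge(clk, x) and net.has_edge(clk, xp)):
                            continue
                        for s in genes:
                            if s in (y, yp, x, xp, clk):
                                continue
                            if not net.has_edge(s, x):
                                continue
                            for r in genes:
                                if r in (y, yp, x, xp, clk, s):
                                    continue
                                if not net.has_edge(r, xp):
                                    continue
                                keys.add(
                                    (clk, frozenset({(s, x, y), (r, xp, yp)}))
                                )
    return keys


def brute_jk_keys(net, wiring="parity"):
    genes = sorted(net.genes)
    keys = set()
    for y in genes:
        for yp in genes:
            if yp == y or not (_rep(net, y, yp) and _rep(net, yp, y)):
                continue
            for x in genes:
                if x in (y, yp) or not net.has_edge(x, y):
                    continue
                for xp in genes:
                    if xp in (y, yp, x) or not net.has_edge(xp, yp):
                        continue
                    if wiring == "parity":
                        if not (net.has_edge(y, xp) and net.has_edge(yp, x)):
                            continue
                    else:
                        if not (net.has_edge(y, x) and net.has_edge(yp, xp)):
                            continue
                    for j in genes:
                        if j in (y, yp, x, xp) or not net.has_edge(j, x):
                            continue
                        for k in genes:
                            if k in (y, yp, x, xp, j):
                                continue
                            if not net.has_edge(k, xp):
                                continue
                            keys.add(frozenset({(j, x, y), (k, xp, yp)}))
    return keys


def sr_keys(matches):
    return {
        frozenset({(m.roles["S"], m.roles["Y"]), (m.roles["R"], m.roles["Yp"])})
        for m in matches
    }


def clocked_sr_keys(matches):
    return {
        (
            m.roles["CLK"],
            frozenset(
                {
                    (m.roles["S"], m.roles["X"], m.roles["Y"]),
                    (m.roles["R"], m.roles["Xp"], m.roles["Yp"]),
                }
            ),
        )
        for m in matches
    }


def jk_keys(matches):
    return {
        frozenset(
            {
                (m.roles["J"], m.roles["X"], m.roles["Y"]),
                (m.roles["K"], m.roles["Xp"], m.roles["Yp"]),
            }
        )
        for m in matches
    }
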