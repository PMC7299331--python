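"""Discrete-time Boolean-threshold dynamics for signed regulatory circuits.

The model is the classic Glass–Kauffman style difference equation: each
gene's product decays geometrically at rate ``alpha`` per step and is
produced at a rate given by Heaviside step functions of its regulators'
levels, the Boolean-logic limit of strongly cooperative Hill input
functions.  For a gene ``g`` with regulators ``r``:

    g_{t+1} = (1 - alpha) * g_t + production_t

    production_t = GATE over regulators of  gamma_r * theta(s_r - k_r)   (activator)
                                            gamma_r * theta(k_r - s_r)   (repressor)

where ``gamma_r`` is the maximum expression rate contributed by regulator
``r``, ``k_r`` its dissociation threshold, and GATE is AND (product of the
``gamma * theta`` factors) or OR (their maximum).  Activator-only
feed-forward loops converge to distinct fixed points for genes Y and Z
(no synchronization); adding an activator autoregulation on Y (the
feed-forward fiber, FFF) synchronizes Y and Z; making the Y loop a
repressor frustrates the circuit (UNSAT-FFF) and, for a rescaled gain

    lambda = gamma_x * gamma_y / (k_y * alpha)  > 1,

drives synchronized oscillations.  The rescaled single-variable map, its
piecewise-exponential closed form, and the ``lambda = 1`` phase boundary
(equivalently ``gamma_y/k_y = (gamma_x/alpha)^{-1}``) are implemented
alongside the generic network simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .graph_core import RegulatoryNetwork, Sign

__all__ = [
    "DynamicsSpec",
    "DriveSignal",
    "Trajectory",
    "OscillationAnalysis",
    "UnsupportedDynamicsError",
    "step",
    "simulate",
    "unsat_fff_map",
    "unsat_fff_analysis",
    "unsat_fff_closed_form",
    "detect_oscillation",
    "sync_error",
    "phase_diagram",
]


class UnsupportedDynamicsError(ValueError):
    """Raised for unknown-sign edges or missing parameters in simulation."""


@dataclass
class DynamicsSpec:
    """Parameters of the threshold update map.

    ``gamma`` and ``k`` are keyed by *regulator* gene: the production term a
    regulator contributes to any of its targets is ``gamma[r] * theta(...)``
    with threshold ``k[r]``, matching the per-regulator strengths and
    dissociation constants of the printed two- and three-gene circuits.
    """

    alpha: float
    gamma: Dict[str, float] = field(default_factory=dict)
    k: Dict[str, float] = field(default_factory=dict)
    gate: str = "AND"  # AND: product of gamma*theta factors; OR: their max
    theta_at_zero: int = 1  # value of the step function at exact threshold
    undriven: str = "decay"  # in-degree-0 genes without drive: decay | hold

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.gate not in ("AND", "OR"):
            raise ValueError(f"gate must be AND or OR, got {self.gate!r}")
        if self.theta_at_zero not in (0, 1):
            raise ValueError("theta_at_zero must be 0 or 1")
        for name, val in list(self.gamma.items()):
            if val <= 0:
                raise ValueError(f"gamma[{name}] must be > 0")
        for name, val in list(self.k.items()):
            if val <= 0:
                raise ValueError(f"k[{name}] must be > 0")

    def theta(self, x: float) -> float:
        """Heaviside step with the configured convention at zero."""
        if x > 0:
            return 1.0
        if x < 0:
            return 0.0
        return float(self.theta_at_zero)


@dataclass
class DriveSignal:
    """External drive for an input gene: constant level or square wave."""

    kind: str = "constant"  # constant | square_wave
    level: float = 1.0
    high: float = 1.0
    low: float = 0.0
    period: int = 40
    duty: float = 0.5
    phase: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "square_wave"):
            raise ValueError(f"unknown drive kind {self.kind!r}")
        if self.kind == "square_wave":
            if self.high <= self.low or self.low < 0:
                raise ValueError("square wave requires high > low >= 0")
            if self.period < 2:
                raise ValueError("square wave period must be >= 2 steps")

    def value(self, t: int) -> float:
        if self.kind == "constant":
            return self.level
        pos = (t + self.phase) % self.period
        return self.high if pos < self.duty * self.period else self.low


@dataclass
class Trajectory:
    """Time-indexed expression levels for all genes."""

    times: np.ndarray
    values: Dict[str, np.ndarray]

    def __getitem__(self, gene: str) -> np.ndarray:
        return self.values[gene]

    @property
    def length(self) -> int:
        return len(self.times)

    def to_rows(self) -> List[Tuple[int, str, float]]:
        """Tidy (time, gene, level) rows for delimited-text output."""
        rows = []
        for gene in sorted(self.values):
            for t, v in zip(self.times, self.values[gene]):
                rows.append((int(t), gene, float(v)))
        return rows


@dataclass
class OscillationAnalysis:
    """Phase classification of the UNSAT-FFF map from its parameters."""

    lam: float
    beta: float
    tau: float
    phase: str  # oscillatory | fixed_point | boundary
    psi_fixed_point: Optional[float] = None  # the rescaled fixed point (= lam) when lam < 1
    switch_times: List[int] = field(default_factory=list)
    period: Optional[int] = None


# ---------------------------------------------------------------------------
# Generic network simulator
# ---------------------------------------------------------------------------

def _production(
    network: RegulatoryNetwork,
    spec: DynamicsSpec,
    gene: str,
    state: Mapping[str, float],
) -> float:
    """Gate-combined production term on ``gene`` from its regulators."""
    factors = []
    for reg, sign in network.in_edges(gene):
        if sign is Sign.UNKNOWN:
            raise UnsupportedDynamicsError(
                f"edge {reg}->{gene} has unknown sign; dynamics undefined"
            )
        try:
            gamma = spec.gamma[reg]
            k = spec.k[reg]
        except KeyError as exc:
            raise UnsupportedDynamicsError(
                f"missing gamma/k for regulator {reg!r}"
            ) from exc
        arg = state[reg] - k if sign is Sign.ACTIVATOR else k - state[reg]
        factors.append(gamma * spec.theta(arg))
    if not factors:
        return 0.0
    if spec.gate == "AND":
        prod = 1.0
        for f in factors:
            prod *= f
        return prod
    return max(factors)


def step(
    network: RegulatoryNetwork,
    spec: DynamicsSpec,
    state: Mapping[str, float],
    drive: Mapping[str, float] | None = None,
) -> Dict[str, float]:
    """One synchronous update of all gene levels.

    Genes present in ``drive`` are clamped to the drive level (they are
    external inputs, not dynamical variables).  Regulated genes follow the
    threshold update; in-degree-0 genes without drive decay geometrically
    (or hold, per ``spec.undriven``).
    """
    drive = drive or {}
    nxt: Dict[str, float] = {}
    for gene in network.genes:
        if gene in drive:
            nxt[gene] = float(drive[gene])
            continue
        if network.in_degree(gene) == 0:
            if spec.undriven == "hold":
                nxt[gene] = float(state[gene])
            else:
                nxt[gene] = (1.0 - spec.alpha) * state[gene]
            continue
        nxt[gene] = (1.0 - spec.alpha) * state[gene] + _production(
            network, spec, gene, state
        )
    return nxt


def simulate(
    network: RegulatoryNetwork,
    spec: DynamicsSpec,
    initial: Mapping[str, float],
    drives: Mapping[str, DriveSignal] | None = None,
    T: int = 100,
) -> Trajectory:
    """Iterate :func:`step` for ``T`` steps; deterministic for fixed inputs."""
    if T < 1:
        raise ValueError("T must be >= 1")
    drives = drives or {}
    genes = sorted(network.genes)
    values = {g: np.empty(T + 1) for g in genes}
    state = {g: float(initial.get(g, 0.0)) for g in genes}
    for g in drives:
        state[g] = drives[g].value(0)
    for g in genes:
        values[g][0] = state[g]
    for t in range(T):
        drive_now = {g: sig.value(t) for g, sig in drives.items()}
        state = step(network, spec, state, drive_now)
        for g in genes:
            values[g][t + 1] = state[g]
    return Trajectory(times=np.arange(T + 1), values=values)


# ---------------------------------------------------------------------------
# UNSAT-FFF rescaled map, closed form, phase classification
# ---------------------------------------------------------------------------

def unsat_fff_map(
    alpha: float,
    lam: float,
    psi0: float,
    T: int,
    theta_at_zero: int = 1,
) -> np.ndarray:
    """Iterate the rescaled frustrated-loop map for drive above threshold.

    psi_{t+1} = beta * psi_t + alpha * lam * theta(1 - psi_t),  beta = 1 - alpha.

    ``psi = y / k_y`` is the repressor gene's level in units of its own
    dissociation threshold; production is on while psi is at or below 1.
    """
    beta = 1.0 - alpha
    out = np.empty(T + 1)
    psi = float(psi0)
    out[0] = psi
    gain = alpha * lam
    for t in range(T):
        if psi < 1.0 or (psi == 1.0 and theta_at_zero):
            psi = beta * psi + gain
        else:
            psi = beta * psi
        out[t + 1] = psi
    return out


def unsat_fff_analysis(
    spec: DynamicsSpec,
    x: str = "X",
    y: str = "Y",
    psi0: float | None = None,
) -> OscillationAnalysis:
    """Classify the UNSAT-FFF phase from its parameters.

    lambda = gamma_x * gamma_y / (k_y * alpha); beta = 1 - alpha;
    tau^{-1} = -log(1 - alpha).  Oscillatory iff lambda > 1 (drive above
    the X threshold assumed); for lambda < 1 the rescaled level converges
    monotonically to the fixed point psi_inf = lambda.
    """
    alpha = spec.alpha
    lam = spec.gamma[x] * spec.gamma[y] / (spec.k[y] * alpha)
    beta = 1.0 - alpha
    tau = -1.0 / math.log(beta)
    if lam > 1.0:
        phase = "oscillatory"
    elif lam < 1.0:
        phase = "fixed_point"
    else:
        phase = "boundary"
    analysis = OscillationAnalysis(
        lam=lam,
        beta=beta,
        tau=tau,
        phase=phase,
        psi_fixed_point=lam if lam < 1.0 else None,
    )
    if psi0 is not None and lam > 1.0:
        _, switches = unsat_fff_closed_form(alpha, lam, psi0, T=5000)
        analysis.switch_times = switches[:8]
        if len(switches) >= 3:
            analysis.period = switches[2] - switches[0]
    return analysis


def unsat_fff_closed_form(
    alpha: float,
    lam: float,
    psi0: float,
    T: int,
    require_oscillatory: bool = False,
) -> Tuple[np.ndarray, List[int]]:
    """Piecewise-exponential solution of the rescaled map.

    Decay segments (psi > 1, production off):
        psi_t = psi_s * e^{-(t-s)/tau}, lasting ceil(tau * log psi_s) steps;
    rise segments (psi <= 1, production on):
        psi_t = lam + (psi_s - lam) e^{-(t-s)/tau},
        lasting ceil(tau * log((lam - psi_s)/(lam - 1))) steps for lam > 1,
        unbounded (monotone convergence to lam) for lam <= 1.

    Returns the trajectory on 0..T and the regime-switch times
    t_1, t_2, t_3, ...  Exact for the theta(0) = 1 convention: e^{-1/tau}
    equals 1 - alpha, so each segment reproduces the map's geometric
    recursion to rounding error.
    """
    if require_oscillatory and lam <= 1.0:
        raise ValueError(f"oscillatory branch requires lambda > 1, got {lam}")
    beta = 1.0 - alpha
    tau = -1.0 / math.log(beta)
    psi = np.empty(T + 1)
    psi[0] = psi0
    switches: List[int] = []
    t = 0
    cur = float(psi0)
    while t < T:
        if cur > 1.0:
            # production off: pure decay until psi <= 1
            d = max(math.ceil(tau * math.log(cur)), 1)
            n = min(d, T - t)
            for s in range(1, n + 1):
                psi[t + s] = cur * beta**s
            t += n
            cur = psi[t]
            if n == d:
                switches.append(t)
        elif lam > 1.0:
            # production on: rise toward lam until psi > 1
            d = max(math.ceil(tau * math.log((lam - cur) / (lam - 1.0))), 1)
            n = min(d, T - t)
            for s in range(1, n + 1):
                psi[t + s] = lam + (cur - lam) * beta**s
            t += n
            cur = psi[t]
            if n == d:
                switches.append(t)
        else:
            # lam <= 1: monotone convergence to lam, single unbounded segment
            for s in range(1, T - t + 1):
                psi[t + s] = lam + (cur - lam) * beta**s
            t = T
    return psi, switches


def detect_oscillation(
    series: Sequence[float] | np.ndarray,
    burn_in: int = 0,
    tol: float = 1e-9,
) -> Tuple[bool, Optional[int], float]:
    """Detect sustained periodic oscillation in a deterministic trajectory.

    After discarding ``burn_in`` steps, reports ``(oscillating, period,
    amplitude)``: oscillating iff the tail has nonzero amplitude and repeats
    with a fixed period within ``tol``.  Constant or still-converging
    monotone tails report ``(False, None, amplitude)``.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if len(arr) <= burn_in + 2:
        raise ValueError("trajectory too short for the requested burn-in")
    tail = arr[burn_in:]
    amp = float(tail.max() - tail.min())
    if amp <= tol:
        return False, None, 0.0
    half = len(tail) // 2
    for p in range(1, half + 1):
        if np.all(np.abs(tail[p:] - tail[:-p]) <= tol):
            return True, p, amp
    return False, None, amp


def trajectory_oscillation(
    traj: Trajectory,
    gene: str,
    burn_in: int,
    tol: float = 1e-9,
) -> Tuple[bool, Optional[int], float]:
    """:func:`detect_oscillation` applied to one gene of a trajectory."""
    return detect_oscillation(traj[gene], burn_in=burn_in, tol=tol)


def sync_error(
    traj: Trajectory,
    gene_a: str,
    gene_b: str,
    burn_in: int = 0,
) -> float:
    """Max absolute difference of two genes' levels over the tail.

    Zero (to machine precision) iff the genes synchronize — the dynamical
    signature of the two genes sharing a fiber.
    """
    a = traj[gene_a]
    b = traj[gene_b]
    return float(np.max(np.abs(a[burn_in:] - b[burn_in:])))


def phase_diagram(
    gx_over_alpha: Sequence[float],
    gy_over_ky: Sequence[float],
    boundary_tol: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Phase labels on a grid of (gamma_x/alpha, gamma_y/k_y).

    Returns ``(lam, labels)`` where ``lam[i, j]`` is the rescaled gain at
    grid point ``(gx_over_alpha[i], gy_over_ky[j])`` and ``labels`` holds
    ``"oscillatory"`` where ``lam > 1 + boundary_tol``, ``"fixed_point"``
    where ``lam < 1 - boundary_tol``, and ``"boundary"`` in between — the
    separatrix is the curve gamma_y/k_y = (gamma_x/alpha)^{-1}.
    """
    gx = np.asarray(gx_over_alpha, dtype=float)
    gy = np.asarray(gy_over_ky, dtype=float)
    if np.any(gx <= 0) or np.any(gy <= 0):
        raise ValueError("grids must be positive")
    lam = gx[:, None] * gy[None, :]
    labels = np.full(lam.shape, "boundary", dtype=object)
    labels[lam > 1.0 + boundary_tol] = "oscillatory"
    labels[lam < 1.0 - boundary_tol] = "fixed_point"
    return lam, labels
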