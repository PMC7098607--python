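"""Exact stochastic simulation of single cells and independent-cell ensembles.

Two interchangeable execution paths exist:

* a pure-Python reference path built from the explicit ``propensities`` /
  ``draw_next_event`` / ``apply_event`` operations, which exposes full
  molecule-level snapshots and serves as the executable definition of the
  model semantics; and
* a compiled kernel (:mod:`txnsim._kernel`) that runs the identical event
  loop on flat arrays, used for ensembles.

Per-cell random streams are derived from the master seed and the cell index
with :class:`numpy.random.SeedSequence`, so ensemble contents are identical
regardless of how many workers execute them or in what order.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .kinetics import (
    KineticParameters,
    PropensityVector,
    ProbeSpec,
    propensities,
    step_rate,
)
from .signals import SignalRecord, cell_signals

NO_EVENT = (None, math.inf)
"""Sentinel returned by :func:`draw_next_event` when no channel is active."""

ENSEMBLE_COLUMNS = (
    "cell_id",
    "time_min",
    "nascent_signal",
    "mature_signal",
    "total_signal",
)


@dataclass
class MoleculeState:
    """One transcript: intact-span step indices plus polymerase/RNase flags.

    ``five_prime``..``three_prime`` (1-based, inclusive) is the intact span;
    ``is_nascent`` means polymerase-bound at the locus (release pending when
    ``three_prime == N``); ``is_degrading`` means RNase-bound.  A molecule
    whose intact span would become empty is removed, never stored.
    """

    five_prime: int
    three_prime: int
    is_nascent: bool
    is_degrading: bool


@dataclass
class CellState:
    """System state of one cell: time, gene Boolean and molecule collection.

    Molecule order never affects any observable.  ``rnase_bound_count`` is
    derived, kept as a property to avoid redundant bookkeeping.
    """

    t: float = 0.0
    gene_on: bool = False
    molecules: list[MoleculeState] = field(default_factory=list)

    @property
    def rnase_bound_count(self) -> int:
        return sum(1 for m in self.molecules if m.is_degrading)


@dataclass(frozen=True)
class ExperimentProtocol:
    """A turn-on or turn-off experiment.

    turn-on: empty initial condition, the activation rate steps up at t=0
    (induction).  turn-off: steady-state initial condition realized by
    burn-in under the pre-step rate, activation steps down at t=0
    (repression).  ``k_on_high`` / ``k_on_pre`` may be None, meaning "use the
    k_on of the kinetic parameter set" -- the form used during inference,
    where k_on is itself a searched parameter.
    """

    kind: Literal["turn_on", "turn_off"]
    t_end: float
    sample_times: tuple[float, ...]
    k_on_high: float | None = None      # turn-on rate for t >= 0
    k_on_pre: float | None = None       # turn-off: rate during burn-in
    k_on_post: float = 0.0              # turn-off: rate for t >= 0
    burn_time: float | None = None      # turn-off: override automatic burn-in

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        st = np.asarray(self.sample_times, dtype=float)
        if st.size == 0:
            raise ValueError("at least one sample time required")
        if np.any(st < 0) or np.any(st > self.t_end):
            raise ValueError("sample_times must lie within [0, t_end]")
        if np.any(np.diff(st) <= 0):
            raise ValueError("sample_times must be strictly increasing")

    @property
    def initial_condition(self) -> str:
        return "empty" if self.kind == "turn_on" else "steady_state"

    def resolve_schedule(
        self, params: KineticParameters
    ) -> tuple[float, np.ndarray, np.ndarray]:
        """Return (t_start, boundary_times, k_on_values) for the kernel.

        For turn-off protocols the burn-in segment is placed at negative
        times so the step lands at t=0.
        """
        if self.kind == "turn_on":
            k_high = params.k_on if self.k_on_high is None else self.k_on_high
            return 0.0, np.array([0.0]), np.array([k_high])
        k_pre = params.k_on if self.k_on_pre is None else self.k_on_pre
        burn = self.burn_time if self.burn_time is not None else default_burn_time(params)
        return -burn, np.array([-burn, 0.0]), np.array([k_pre, self.k_on_post])


def default_burn_time(params: KineticParameters) -> float:
    """Burn-in long enough to realize a steady state from an empty cell.

    Ten times the slower of the degradation timescale 1/k_deg and the gene
    traversal time L/(v_el*60); conservative, and checked by the doubling
    self-consistency test.
    """
    traversal = params.L / (params.v_el * 60.0)
    return 10.0 * max(1.0 / params.k_deg, traversal)


@dataclass
class EnsembleData:
    """Per-cell, per-timepoint probe signals for a simulated population.

    ``df`` is rectangular: one row per (cell, sample time) with columns
    cell_id, time_min, nascent_signal, mature_signal, total_signal plus the
    diagnostic molecule counts n_molecules, n_degrading, n_nascent.
    ``metadata`` records everything needed to regenerate it.
    """

    df: pd.DataFrame
    metadata: dict

    @property
    def sample_times(self) -> np.ndarray:
        return np.asarray(self.metadata["sample_times"], dtype=float)

    @property
    def n_cells(self) -> int:
        return int(self.metadata["n_cells"])

    def signals_at(self, time: float, channel: str) -> np.ndarray:
        """Per-cell values of one channel at one sample time."""
        col = _channel_column(channel)
        sub = self.df[np.isclose(self.df["time_min"].to_numpy(), time)]
        if sub.empty:
            raise KeyError(f"no records at time {time}")
        return sub[col].to_numpy()

    def pivot(self, channel: str) -> pd.DataFrame:
        """Cells x sample-times matrix of one channel."""
        col = _channel_column(channel)
        return self.df.pivot(index="cell_id", columns="time_min", values=col)

    def to_csv(self, path) -> None:
        self.df.loc[:, list(ENSEMBLE_COLUMNS)].to_csv(path, index=False)


def _channel_column(channel: str) -> str:
    mapping = {
        "nascent": "nascent_signal",
        "mature": "mature_signal",
        "total": "total_signal",
        "count": "n_molecules",
        "unbound_count": "n_unbound",
    }
    if channel not in mapping:
        raise KeyError(f"unknown channel {channel!r}; expected one of {sorted(mapping)}")
    return mapping[channel]


# ---------------------------------------------------------------------------
# Reference event operations
# ---------------------------------------------------------------------------

def draw_next_event(pvec: PropensityVector, rng: np.random.Generator):
    """Sample (channel, waiting time) for the next reaction.

    The waiting time is exponential with rate equal to the total propensity;
    the channel is chosen with probability proportional to its rate.  With
    zero total propensity the ``NO_EVENT`` sentinel is returned and the
    caller advances time to the next schedule boundary or sample time.
    """
    a0 = pvec.total()
    if a0 == 0.0:
        return NO_EVENT
    dt = -math.log(1.0 - rng.random()) / a0
    u = rng.random() * a0
    acc = 0.0
    channel = None
    for ch, rate in pvec.channels():
        acc += rate
        if u < acc:
            channel = ch
            break
    if channel is None:  # guard against floating-point edge u == a0
        for ch, rate in pvec.channels():
            if rate > 0:
                channel = ch
    return channel, dt


def apply_event(cell: CellState, channel, params: KineticParameters) -> CellState:
    """Apply one reaction in place and return the cell.

    Initiation appends a molecule at span (1, 1), nascent and unbound.  An
    elongation event increments ``three_prime``, or -- when ``three_prime``
    already equals N -- releases the molecule (clears ``is_nascent``), so
    completing a transcript takes exactly N step events and the mean
    traversal time is N / step_rate = L / (v_el * 60) minutes.  A degradation
    event increments ``five_prime``, or removes the molecule (and any bound
    polymerase) once its last intact step is consumed.
    """
    kind, idx = channel
    if kind == "gene_on":
        if cell.gene_on:
            raise ValueError("gene_on applied while gene already on")
        cell.gene_on = True
    elif kind == "gene_off":
        if not cell.gene_on:
            raise ValueError("gene_off applied while gene already off")
        cell.gene_on = False
    elif kind == "initiation":
        if not cell.gene_on:
            raise ValueError("initiation applied while gene off")
        cell.molecules.append(
            MoleculeState(five_prime=1, three_prime=1, is_nascent=True, is_degrading=False)
        )
    elif kind == "elongation":
        mol = cell.molecules[idx]
        if not mol.is_nascent:
            raise ValueError("elongation applied to a released molecule")
        if mol.three_prime < params.N:
            mol.three_prime += 1
        else:
            mol.is_nascent = False
    elif kind == "rnase_binding":
        mol = cell.molecules[idx]
        if mol.is_degrading:
            raise ValueError("RNase binding applied to an already bound molecule")
        mol.is_degrading = True
    elif kind == "degradation":
        mol = cell.molecules[idx]
        if not mol.is_degrading:
            raise ValueError("degradation applied to an unbound molecule")
        if mol.five_prime < mol.three_prime:
            mol.five_prime += 1
        else:
            cell.molecules.pop(idx)
    else:
        raise ValueError(f"unknown channel {channel!r}")
    return cell


def _advance_reference(
    cell: CellState,
    params: KineticParameters,
    k_on_current: float,
    t_stop: float,
    rng: np.random.Generator,
) -> None:
    """Run the reference event loop on one schedule segment up to t_stop."""
    while True:
        pvec = propensities(cell, params, k_on_current)
        channel, dt = draw_next_event(pvec, rng)
        if channel is None or cell.t + dt > t_stop:
            cell.t = t_stop
            return
        cell.t += dt
        apply_event(cell, channel, params)


def simulate_cell_reference(
    params: KineticParameters,
    protocol: ExperimentProtocol,
    probe: ProbeSpec,
    rng: np.random.Generator,
    record_snapshots: bool = False,
) -> list[tuple[float, SignalRecord, list[MoleculeState] | None]]:
    """Exact single-cell trajectory via the explicit event operations.

    Returns one (sample_time, SignalRecord, snapshot) triple per sample time;
    snapshots are deep copies of the molecule list when requested, else None.
    Orders of magnitude slower than the kernel; intended for semantics tests,
    molecule-level visualization and cross-validation.
    """
    t0, sched_t, sched_kon = protocol.resolve_schedule(params)
    cell = CellState(t=t0, gene_on=False)
    out = []
    boundaries = list(sched_t[1:]) + [math.inf]
    seg = 0
    for ts in protocol.sample_times:
        while boundaries[seg] <= ts:
            _advance_reference(cell, params, sched_kon[seg], boundaries[seg], rng)
            seg += 1
        _advance_reference(cell, params, sched_kon[seg], ts, rng)
        rec = cell_signals(cell, probe, params.N)
        snap = (
            [MoleculeState(m.five_prime, m.three_prime, m.is_nascent, m.is_degrading)
             for m in cell.molecules]
            if record_snapshots
            else None
        )
        out.append((float(ts), rec, snap))
    return out


# ---------------------------------------------------------------------------
# Kernel-backed simulation
# ---------------------------------------------------------------------------

def _cell_rng(seed: int, cell_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(cell_index),))
    return np.random.Generator(np.random.PCG64(ss))


def _empty_molecules():
    return (
        np.empty(0, np.int64),
        np.empty(0, np.int64),
        np.empty(0, np.bool_),
        np.empty(0, np.bool_),
    )


def _cell_to_arrays(cell: CellState):
    n = len(cell.molecules)
    five = np.array([m.five_prime for m in cell.molecules], dtype=np.int64).reshape(n)
    three = np.array([m.three_prime for m in cell.molecules], dtype=np.int64).reshape(n)
    nasc = np.array([m.is_nascent for m in cell.molecules], dtype=np.bool_).reshape(n)
    degr = np.array([m.is_degrading for m in cell.molecules], dtype=np.bool_).reshape(n)
    return five, three, nasc, degr


def _run_cell_kernel(
    params: KineticParameters,
    protocol: ExperimentProtocol,
    probe: ProbeSpec,
    rng: np.random.Generator,
    sample_times: np.ndarray,
    max_events: int,
    initial: CellState | None = None,
):
    t0, sched_t, sched_kon = protocol.resolve_schedule(params)
    prefix = probe.coverage_prefix(params.N)
    if initial is None:
        five0, three0, nasc0, degr0 = _empty_molecules()
        gene0 = False
    else:
        five0, three0, nasc0, degr0 = _cell_to_arrays(initial)
        gene0 = bool(initial.gene_on)
    n_s = sample_times.size
    out_sig = np.empty((n_s, 2), dtype=np.float64)
    out_cnt = np.empty((n_s, 3), dtype=np.int64)
    result = _kernel.run_cell(
        rng,
        float(t0),
        sched_t.astype(np.float64),
        sched_kon.astype(np.float64),
        float(params.k_off),
        float(params.k_ini),
        float(params.k_deg),
        float(step_rate(params)),
        int(params.N),
        prefix,
        sample_times.astype(np.float64),
        gene0,
        five0, three0, nasc0, degr0,
        int(max_events),
        out_sig,
        out_cnt,
    )
    status = result[0]
    if status == _kernel.STATUS_EVENT_BUDGET:
        raise EventBudgetExceeded(
            f"cell exceeded the event budget of {max_events} events"
        )
    return out_sig, out_cnt, result


class EventBudgetExceeded(RuntimeError):
    """A trajectory exceeded the per-cell event budget (runaway parameters)."""


def simulate_cell(
    params: KineticParameters,
    protocol: ExperimentProtocol,
    probe: ProbeSpec,
    rng: np.random.Generator | int,
    max_events: int = 10_000_000,
) -> list[tuple[float, SignalRecord]]:
    """Single-cell trajectory on the compiled path (no snapshots)."""
    if isinstance(rng, (int, np.integer)):
        rng = _cell_rng(int(rng), 0)
    st = np.asarray(protocol.sample_times, dtype=float)
    out_sig, _, _ = _run_cell_kernel(params, protocol, probe, rng, st, max_events)
    return [
        (float(t), SignalRecord(nascent=float(s[0]), mature=float(s[1])))
        for t, s in zip(st, out_sig)
    ]


def burn_in_steady_state(
    params: KineticParameters,
    rng: np.random.Generator | int,
    burn_time: float | None = None,
    k_on: float | None = None,
) -> CellState:
    """Simulate an empty cell for ``burn_time`` and return the final state.

    Used to realize the steady-state initial condition of turn-off
    experiments; the default burn time is :func:`default_burn_time`.
    """
    if isinstance(rng, (int, np.integer)):
        rng = _cell_rng(int(rng), 0)
    if burn_time is None:
        burn_time = default_burn_time(params)
    protocol = ExperimentProtocol(
        kind="turn_on",
        t_end=burn_time,
        sample_times=(burn_time,),
        k_on_high=k_on,
    )
    st = np.array([burn_time], dtype=float)
    _, _, result = _run_cell_kernel(params, protocol, probe=ProbeSpec(0.0, 1.0),
                                    rng=rng, sample_times=st, max_events=10_000_000)
    _, gene_on, five, three, nasc, degr = result
    molecules = [
        MoleculeState(int(f), int(t), bool(a), bool(d))
        for f, t, a, d in zip(five, three, nasc, degr)
    ]
    return CellState(t=burn_time, gene_on=bool(gene_on), molecules=molecules)


def simulate_ensemble(
    params: KineticParameters,
    protocol: ExperimentProtocol,
    probe: ProbeSpec,
    n_cells: int,
    seed: int,
    workers: int = 1,
    max_events: int = 10_000_000,
) -> EnsembleData:
    """Simulate ``n_cells`` independent cells under one protocol.

    Each cell gets its own random stream derived from (seed, cell index), so
    the result is byte-identical for any ``workers`` count.  The compiled
    kernel releases the GIL, so thread workers give real parallelism.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    st = np.asarray(protocol.sample_times, dtype=float)
    n_s = st.size
    sig = np.empty((n_cells, n_s, 2), dtype=np.float64)
    cnt = np.empty((n_cells, n_s, 3), dtype=np.int64)

    def run_range(lo: int, hi: int) -> None:
        for c in range(lo, hi):
            rng = _cell_rng(seed, c)
            out_sig, out_cnt, _ = _run_cell_kernel(
                params, protocol, probe, rng, st, max_events
            )
            sig[c] = out_sig
            cnt[c] = out_cnt

    if workers <= 1 or n_cells == 1:
        run_range(0, n_cells)
    else:
        chunk = -(-n_cells // workers)
        spans = [(i, min(i + chunk, n_cells)) for i in range(0, n_cells, chunk)]
        with ThreadPoolExecutor(max_workers=workers) as pool:
            list(pool.map(lambda span: run_range(*span), spans))

    cell_ids = np.repeat(np.arange(n_cells), n_s)
    times = np.tile(st, n_cells)
    nascent = sig[:, :, 0].ravel()
    mature = sig[:, :, 1].ravel()
    df = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "time_min": times,
            "nascent_signal": nascent,
            "mature_signal": mature,
            "total_signal": nascent + mature,
            "n_molecules": cnt[:, :, 0].ravel(),
            "n_degrading": cnt[:, :, 1].ravel(),
            "n_nascent": cnt[:, :, 2].ravel(),
        }
    )
    df["n_unbound"] = df["n_molecules"] - df["n_degrading"]
    metadata = {
        "params": params,
        "protocol": protocol,
        "probe": probe,
        "seed": int(seed),
        "n_cells": int(n_cells),
        "sample_times": [float(t) for t in st],
    }
    return EnsembleData(df=df, metadata=metadata)
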