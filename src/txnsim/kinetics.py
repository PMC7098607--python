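"""Reaction network and rate parameterization for the submolecular transcription model.

The model describes a single prokaryotic gene copy.  The promoter switches
between an inactive and an active state (rates ``k_on`` / ``k_off``).  While
active, RNA polymerases initiate at rate ``k_ini``; each nascent transcript
then elongates in ``N`` discrete steps at speed ``v_el``, is released as a
mature mRNA on its final step, and -- nascent or mature -- can be bound at its
5' end by an RNase (rate ``k_deg``) that chews it up stepwise at the same
per-step speed as elongation.

All rates are handled internally in units of 1/min; the elongation speed is
supplied in nt/s (the unit in which it is usually measured) and converted
exactly once, on ingestion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .engine import CellState

PARAM_NAMES = ("k_ini", "k_on", "k_off", "k_deg", "v_el")
"""The five kinetic parameters subject to inference, in canonical order."""


@dataclass(frozen=True)
class KineticParameters:
    """Kinetic parameters of one gene copy.

    Parameters
    ----------
    k_on, k_off : float
        Promoter activation / deactivation rates (1/min).
    k_ini : float
        Transcription initiation rate while the gene is on (1/min).
    k_deg : float
        RNase-binding (degradation initiation) rate per eligible molecule
        (1/min).
    v_el : float
        Elongation speed in nt/s (converted to 1/min internally).
    L : float
        Gene length in nt.
    N : int
        Number of discrete steps to complete one transcript.  The step
        length ``L / N`` (nt) is derived, never stored.
    """

    k_on: float
    k_off: float
    k_ini: float
    k_deg: float
    v_el: float
    L: float
    N: int

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_ini", "k_deg", "v_el", "L"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 1):
            raise ValueError(f"N must be an integer >= 1, got {self.N!r}")

    @property
    def step_length_nt(self) -> float:
        return self.L / self.N

    def with_rates(self, **updates: float) -> "KineticParameters":
        """Return a copy with some of the five kinetic rates replaced."""
        unknown = set(updates) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        return replace(self, **updates)


def observed_initiation_rate(params: KineticParameters) -> float:
    """Effective (burst-averaged) initiation rate k_i^obs (1/min).

    k_i^obs = k_ini * k_on / (k_on + k_off): the initiation rate weighted by
    the stationary probability of the promoter being active.  It is a
    degeneracy axis of the inference problem -- trials sharing k_i^obs
    produce nearly identical mean total RNA when elongation is fast.
    """
    return params.k_ini * params.k_on / (params.k_on + params.k_off)


def step_rate(params: KineticParameters) -> float:
    """Per-molecule rate (1/min) of advancing one elongation or degradation step.

    Equals ``v_el * 60 * N / L``, so that the mean gene-traversal time over N
    exponential steps is ``L / (v_el * 60)`` minutes.  Degradation proceeds at
    the same per-step rate as elongation.
    """
    return params.v_el * 60.0 * params.N / params.L


@dataclass(frozen=True)
class ProbeSpec:
    """Fluorescent probe span as fractions of the gene length.

    ``p5`` and ``p3`` are the 5'-most and 3'-most edges of probe coverage in
    [0, 1].  A discrete step is considered probe-covered iff its midpoint
    lies inside [p5, p3]; the discretized interval must be non-empty.
    """

    p5: float = 0.0
    p3: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p5 < self.p3 <= 1.0):
            raise ValueError(f"require 0 <= p5 < p3 <= 1, got ({self.p5}, {self.p3})")

    def covered_steps(self, N: int) -> np.ndarray:
        """Boolean array of length N: step j (1-based) covered iff its midpoint
        (j - 0.5)/N lies within [p5, p3]."""
        mid = (np.arange(1, N + 1) - 0.5) / N
        covered = (mid >= self.p5) & (mid <= self.p3)
        if not covered.any():
            raise ValueError(
                f"probe span ({self.p5}, {self.p3}) covers no step at resolution N={N}"
            )
        return covered

    def coverage_prefix(self, N: int) -> np.ndarray:
        """Prefix sums of covered steps: prefix[k] = number of covered steps
        among steps 1..k (prefix[0] = 0).  Overlap of an intact span
        [five..three] with the probe is prefix[three] - prefix[five - 1]."""
        prefix = np.zeros(N + 1, dtype=np.int64)
        np.cumsum(self.covered_steps(N), out=prefix[1:])
        return prefix


@dataclass
class PropensityVector:
    """Reaction propensities (1/min) for one cell state.

    Per-molecule channels carry the index of the molecule in the cell's
    collection.  Channels are identified by (kind, molecule_index) pairs with
    molecule_index None for the gene/initiation channels.
    """

    gene_on: float = 0.0
    gene_off: float = 0.0
    initiation: float = 0.0
    elongation: list = field(default_factory=list)     # [(mol_idx, rate)]
    rnase_binding: list = field(default_factory=list)  # [(mol_idx, rate)]
    degradation: list = field(default_factory=list)    # [(mol_idx, rate)]

    def channels(self):
        """Yield (channel, rate) pairs; channel = (kind, mol_idx or None)."""
        yield ("gene_on", None), self.gene_on
        yield ("gene_off", None), self.gene_off
        yield ("initiation", None), self.initiation
        for kind, entries in (
            ("elongation", self.elongation),
            ("rnase_binding", self.rnase_binding),
            ("degradation", self.degradation),
        ):
            for idx, rate in entries:
                yield (kind, idx), rate

    def total(self) -> float:
        total = 0.0
        for _, rate in self.channels():
            if rate < 0 or not math.isfinite(rate):
                raise ValueError(f"invalid propensity {rate!r}")
            total += rate
        return total


def propensities(
    cell: "CellState", params: KineticParameters, k_on_current: float | None = None
) -> PropensityVector:
    """Compute the propensity vector for a cell state.

    ``k_on_current`` is the protocol-scheduled activation rate at the current
    time (defaults to ``params.k_on``).  Channel rules:

    * gene_on at ``k_on_current`` iff the gene is off; gene_off at ``k_off``
      iff on; initiation at ``k_ini`` iff on.
    * every nascent molecule contributes one elongation channel at the step
      rate (the step taken at ``three_prime == N`` is the release step);
    * every molecule without a bound RNase contributes one RNase-binding
      channel at ``k_deg`` (binding targets the 5'-most intact step, and a
      molecule holds at most one RNase);
    * every RNase-bound molecule contributes one degradation channel at the
      step rate.  A molecule that is both nascent and RNase-bound carries
      both channels (co-transcriptional degradation).
    """
    if k_on_current is None:
        k_on_current = params.k_on
    r_step = step_rate(params)
    pvec = PropensityVector(
        gene_on=0.0 if cell.gene_on else k_on_current,
        gene_off=params.k_off if cell.gene_on else 0.0,
        initiation=params.k_ini if cell.gene_on else 0.0,
    )
    for idx, mol in enumerate(cell.molecules):
        if not (1 <= mol.five_prime <= mol.three_prime <= params.N):
            raise ValueError(f"inconsistent molecule state {mol!r}")
        if mol.is_nascent:
            pvec.elongation.append((idx, r_step))
        if mol.is_degrading:
            pvec.degradation.append((idx, r_step))
        else:
            pvec.rnase_binding.append((idx, params.k_deg))
    return pvec
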