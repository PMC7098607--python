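"""Probe-overlap fluorescence readout.

Each molecule fluoresces in proportion to the overlap between its intact
span and the probe-covered steps, normalized by the fluorescence of a single
fully intact molecule, so signals are in molecule-equivalent units.  Signals
are reported in three channels: nascent (polymerase-bound molecules), mature
(released molecules), and total = nascent + mature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .kinetics import ProbeSpec

if TYPE_CHECKING:  # pragma: no cover
    from .engine import CellState, MoleculeState


@dataclass(frozen=True)
class SignalRecord:
    """Probe readout for one cell at one time, in molecule equivalents."""

    nascent: float
    mature: float

    @property
    def total(self) -> float:
        return self.nascent + self.mature


def molecule_signal(mol: "MoleculeState", probe: ProbeSpec, N: int) -> float:
    """Fraction of the probe overlapped by the molecule's intact span, in [0, 1].

    A fully intact molecule (span 1..N) scores exactly 1 for any valid probe;
    this is the normalization anchor that rescales the readout to molecule
    number.  Coverage is binary per step: partial-step fluorescence is not
    modeled (a step counts iff its midpoint lies in the probe span).
    """
    prefix = probe.coverage_prefix(N)
    overlap = prefix[mol.three_prime] - prefix[mol.five_prime - 1]
    return float(overlap) / float(prefix[N])


def cell_signals(cell: "CellState", probe: ProbeSpec, N: int) -> SignalRecord:
    """Sum per-molecule signals by class: nascent vs released molecules."""
    prefix = probe.coverage_prefix(N)
    norm = float(prefix[N])
    nascent = 0.0
    mature = 0.0
    for mol in cell.molecules:
        s = (prefix[mol.three_prime] - prefix[mol.five_prime - 1]) / norm
        if mol.is_nascent:
            nascent += s
        else:
            mature += s
    return SignalRecord(nascent=nascent, mature=mature)


def signals_from_arrays(
    five: np.ndarray,
    three: np.ndarray,
    is_nascent: np.ndarray,
    prefix: np.ndarray,
) -> tuple[float, float]:
    """Vectorized (nascent, mature) signal sums from molecule span arrays."""
    norm = float(prefix[-1])
    per_mol = (prefix[three] - prefix[five - 1]) / norm
    nascent = float(per_mol[is_nascent].sum())
    mature = float(per_mol[~is_nascent].sum())
    return nascent, mature
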