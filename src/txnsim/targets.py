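"""Experiment protocols and synthetic ground-truth target datasets.

A :class:`TargetDataset` is what the inference machinery consumes: per-cell
nascent and total probe signals at a series of timepoints, mimicking
fixed-cell smFISH histograms.  Targets are normally generated by simulating
an ensemble from known parameters, so recovery of those parameters can be
scored; the table is structurally identical to real measurements, and the
search cannot distinguish the two.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import EnsembleData, ExperimentProtocol, simulate_ensemble
from .kinetics import KineticParameters, ProbeSpec

TARGET_COLUMNS = ("cell_id", "time_min", "nascent_signal", "total_signal")

#: Ground-truth parameter set used for the synthetic validation experiments:
#: a bursty promoter (on ~9% of the time), ~8.6 effective initiations/min,
#: 2-min mRNA half-life scale, and coarse 15-step elongation resolution.
VALIDATION_GROUND_TRUTH = KineticParameters(
    k_ini=95.0, k_on=1.0, k_off=10.0, k_deg=0.5, v_el=41.5, L=5300.0, N=15
)

#: Matching induction protocol: 15 minutes sampled once per minute from t=0.
VALIDATION_SAMPLE_TIMES = tuple(float(t) for t in range(16))


def make_turn_on_protocol(
    k_on_high: float | None = None,
    t_end: float = 15.0,
    sample_times: tuple[float, ...] | None = None,
) -> ExperimentProtocol:
    """Induction experiment: empty initial state, k_on steps up at t=0.

    ``k_on_high=None`` means the activation rate of whichever parameter set
    is simulated (the form used during inference).  Default sampling is once
    per minute including t=0.
    """
    if sample_times is None:
        sample_times = tuple(float(t) for t in np.arange(0.0, t_end + 1e-9, 1.0))
    return ExperimentProtocol(
        kind="turn_on", t_end=t_end, sample_times=tuple(sample_times),
        k_on_high=k_on_high,
    )


def make_turn_off_protocol(
    k_on_pre: float | None,
    k_on_post: float,
    t_end: float,
    sample_times: tuple[float, ...] | None = None,
    burn_time: float | None = None,
) -> ExperimentProtocol:
    """Repression experiment: steady state under ``k_on_pre``, step down at t=0."""
    if k_on_pre is not None and k_on_post >= k_on_pre:
        raise ValueError("turn-off requires k_on_post < k_on_pre")
    if k_on_post < 0:
        raise ValueError("k_on_post must be >= 0")
    if sample_times is None:
        sample_times = tuple(float(t) for t in np.arange(0.0, t_end + 1e-9, 1.0))
    return ExperimentProtocol(
        kind="turn_off", t_end=t_end, sample_times=tuple(sample_times),
        k_on_pre=k_on_pre, k_on_post=k_on_post, burn_time=burn_time,
    )


@dataclass
class TargetDataset:
    """Per-cell nascent and total probe signals at a series of timepoints."""

    df: pd.DataFrame
    metadata: dict

    def __post_init__(self) -> None:
        missing = set(TARGET_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"target table missing columns {sorted(missing)}")
        df = self.df.loc[:, list(TARGET_COLUMNS)].reset_index(drop=True)
        self.df = df.astype({"cell_id": "int64", "time_min": "float64",
                             "nascent_signal": "float64",
                             "total_signal": "float64"})

    @property
    def sample_times(self) -> np.ndarray:
        return np.unique(self.df["time_min"].to_numpy(dtype=float))

    @property
    def n_cells(self) -> int:
        return int(self.df["cell_id"].nunique())

    def values_at(self, time: float, channel: str) -> np.ndarray:
        col = {"nascent": "nascent_signal", "total": "total_signal"}[channel]
        sub = self.df[np.isclose(self.df["time_min"].to_numpy(dtype=float), time)]
        if sub.empty:
            raise KeyError(f"no records at t={time}")
        return sub[col].to_numpy(dtype=float)

    def mean_trace(self, channel: str) -> pd.Series:
        col = {"nascent": "nascent_signal", "total": "total_signal"}[channel]
        return self.df.groupby("time_min")[col].mean()

    # -- serialization ------------------------------------------------------

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the table as CSV plus a JSON metadata sidecar (.json)."""
        path = Path(path)
        self.df.to_csv(path, index=False, float_format="%.17g")
        if sidecar:
            side = {k: v for k, v in self.metadata.items() if _jsonable(v)}
            path.with_suffix(".json").write_text(json.dumps(side, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TargetDataset":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(".json")
        metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(df=df, metadata=metadata)

    @classmethod
    def from_ensemble(cls, ensemble: EnsembleData) -> "TargetDataset":
        df = ensemble.df.loc[:, list(TARGET_COLUMNS)].copy()
        meta = dict(ensemble.metadata)
        params = meta.pop("params", None)
        probe = meta.pop("probe", None)
        protocol = meta.pop("protocol", None)
        if params is not None:
            meta["generating_params"] = {
                "k_ini": params.k_ini, "k_on": params.k_on, "k_off": params.k_off,
                "k_deg": params.k_deg, "v_el": params.v_el,
                "L": params.L, "N": params.N,
            }
        if probe is not None:
            meta["probe"] = {"p5": probe.p5, "p3": probe.p3}
        if protocol is not None:
            meta["protocol"] = {"kind": protocol.kind, "t_end": protocol.t_end}
        return cls(df=df, metadata=meta)


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def generate_synthetic_target(
    params: KineticParameters,
    protocol: ExperimentProtocol,
    probe: ProbeSpec,
    n_cells: int,
    seed: int,
    workers: int = 1,
) -> TargetDataset:
    """Simulate an ensemble and wrap it as an inference target.

    Deterministic given the seed: regenerating with identical settings
    yields an identical table.
    """
    ensemble = simulate_ensemble(
        params, protocol, probe, n_cells=n_cells, seed=seed, workers=workers
    )
    return TargetDataset.from_ensemble(ensemble)
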