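"""Stationary chemical-master-equation solution of the two-state telegraph model.

The telegraph model is the coarse-grained limit of the submolecular model:
when transcripts complete in a single step and degradation after RNase
binding is effectively instantaneous, the count of not-yet-bound molecules
is a birth-death process with birth rate k_ini gated by the promoter state
and death rate k_deg per molecule.  The stationary distribution is obtained
here by a truncated master-equation solve, fully independent of the
simulation path, and serves as a cross-validation oracle.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve


def stationary_pmf(
    k_on: float,
    k_off: float,
    k_ini: float,
    k_deg: float,
    m_max: int | None = None,
) -> np.ndarray:
    """Stationary molecule-count pmf of the two-state telegraph model.

    States are (gene off/on, m molecules) with transitions off->on at k_on,
    on->off at k_off, m->m+1 at k_ini while on, m->m-1 at m*k_deg.  The
    state space is truncated at ``m_max`` copies (chosen automatically to
    hold essentially all stationary mass) and the null space of the
    generator is solved for directly.  Returns the marginal pmf over m.
    """
    for name, v in (("k_on", k_on), ("k_off", k_off), ("k_ini", k_ini), ("k_deg", k_deg)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if m_max is None:
        mean_on = k_ini / k_deg  # upper bound on the conditional mean
        m_max = int(mean_on + 12.0 * np.sqrt(mean_on) + 25)
    n_m = m_max + 1
    n_states = 2 * n_m  # index = gene * n_m + m

    rows, cols, vals = [], [], []

    def add(src: int, dst: int, rate: float) -> None:
        rows.append(dst)
        cols.append(src)
        vals.append(rate)
        rows.append(src)
        cols.append(src)
        vals.append(-rate)

    for m in range(n_m):
        off_state = m
        on_state = n_m + m
        add(off_state, on_state, k_on)
        add(on_state, off_state, k_off)
        if m + 1 < n_m:
            add(on_state, n_m + m + 1, k_ini)
        if m > 0:
            add(off_state, m - 1, m * k_deg)
            add(on_state, n_m + m - 1, m * k_deg)

    gen = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_states, n_states)
    ).tolil()
    # replace one balance equation by the normalization constraint
    gen[0, :] = 1.0
    rhs = np.zeros(n_states)
    rhs[0] = 1.0
    pi = spsolve(gen.tocsr(), rhs)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    marginal = pi[:n_m] + pi[n_m:]
    if marginal[-1] > 1e-8:
        raise RuntimeError(
            f"truncation at m_max={m_max} leaves mass {marginal[-1]:.2e} at the boundary"
        )
    return marginal


def stationary_mean(k_on: float, k_off: float, k_ini: float, k_deg: float) -> float:
    """Closed-form stationary mean: k_i^obs / k_deg."""
    return k_ini * k_on / (k_on + k_off) / k_deg


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total variation distance between two pmfs (padded to a common length)."""
    n = max(len(p), len(q))
    pp = np.zeros(n)
    qq = np.zeros(n)
    pp[: len(p)] = p
    qq[: len(q)] = q
    return 0.5 * float(np.abs(pp - qq).sum())


def empirical_pmf(counts: np.ndarray, m_max: int | None = None) -> np.ndarray:
    """pmf of integer samples on 0..m_max (defaults to the sample maximum)."""
    counts = np.asarray(counts, dtype=int)
    if m_max is None:
        m_max = int(counts.max())
    pmf = np.bincount(counts, minlength=m_max + 1).astype(float)
    return pmf / pmf.sum()
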