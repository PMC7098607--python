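import numpy as np
import pytest
from scipy import stats as sps

from txnsim import (
    CellState,
    KineticParameters,
    MoleculeState,
    ProbeSpec,
    apply_event,
    burn_in_steady_state,
    cell_signals,
    draw_next_event,
    make_turn_on_protocol,
    propensities,
    simulate_cell,
    simulate_cell_reference,
    simulate_ensemble,
)
from txnsim.engine import NO_EVENT, EventBudgetExceeded, ExperimentProtocol
from txnsim.kinetics import PropensityVector


def make_params(**overrides):
    base = dict(k_on=1.0, k_off=2.0, k_ini=20.0, k_deg=0.5, v_el=41.5,
                L=5300.0, N=5)
    base.update(overrides)
    return KineticParameters(**base)


def mol(five, three, nascent=False, degrading=False):
    return MoleculeState(five, three, nascent, degrading)


class TestDrawNextEvent:
    def test_zero_propensity_returns_sentinel(self, rng):
        assert draw_next_event(PropensityVector(), rng) == NO_EVENT

    def test_waiting_time_is_exponential(self, rng):
        pvec = PropensityVector(gene_on=4.0)
        dts = np.array([draw_next_event(pvec, rng)[1] for _ in range(20000)])
        se = 0.25 / np.sqrt(len(dts))
        assert abs(dts.mean() - 0.25) < 3 * se

    def test_channel_selection_frequencies(self, rng):
        pvec = PropensityVector(gene_on=2.0, gene_off=1.0, initiation=1.0)
        counts = {"gene_on": 0, "gene_off": 0, "initiation": 0}
        n = 40000
        for _ in range(n):
            (kind, _), _ = draw_next_event(pvec, rng)
            counts[kind] += 1
        observed = [counts["gene_on"], counts["gene_off"], counts["initiation"]]
        _, p = sps.chisquare(observed, f_exp=[n / 2, n / 4, n / 4])
        assert p > 0.001

    def test_negative_propensity_is_a_model_bug(self, rng):
        with pytest.raises(ValueError):
            draw_next_event(PropensityVector(gene_on=-1.0), rng)


class TestApplyEvent:
    def test_initiation_creates_unit_span_nascent_molecule(self):
        p = make_params()
        cell = CellState(gene_on=True)
        apply_event(cell, ("initiation", None), p)
        m = cell.molecules[0]
        assert (m.five_prime, m.three_prime) == (1, 1)
        assert m.is_nascent and not m.is_degrading

    def test_elongation_then_release_takes_n_step_events(self):
        # completing a transcript takes exactly N step events: N-1 span
        # extensions plus one release event at the gene end
        p = make_params(N=3)
        cell = CellState(gene_on=True, molecules=[mol(1, 1, nascent=True)])
        apply_event(cell, ("elongation", 0), p)
        apply_event(cell, ("elongation", 0), p)
        m = cell.molecules[0]
        assert m.three_prime == 3 and m.is_nascent  # release pending
        apply_event(cell, ("elongation", 0), p)
        assert not m.is_nascent and m.three_prime == 3

    def test_degradation_consumes_and_removes(self):
        p = make_params(N=5)
        cell = CellState(molecules=[mol(4, 5, degrading=True)])
        apply_event(cell, ("degradation", 0), p)
        assert cell.molecules[0].five_prime == 5
        apply_event(cell, ("degradation", 0), p)
        assert cell.molecules == []

    def test_rnase_binding_sets_flag_and_counter(self):
        p = make_params()
        cell = CellState(molecules=[mol(1, 5)])
        apply_event(cell, ("rnase_binding", 0), p)
        assert cell.molecules[0].is_degrading
        assert cell.rnase_bound_count == 1

    @pytest.mark.parametrize("channel,state", [
        (("gene_on", None), dict(gene_on=True)),
        (("gene_off", None), dict(gene_on=False)),
        (("initiation", None), dict(gene_on=False)),
    ])
    def test_disabled_gene_channels_rejected(self, channel, state):
        with pytest.raises(ValueError):
            apply_event(CellState(**state), channel, make_params())

    def test_disabled_molecule_channels_rejected(self):
        p = make_params()
        with pytest.raises(ValueError):
            apply_event(CellState(molecules=[mol(1, 5)]), ("degradation", 0), p)
        with pytest.raises(ValueError):
            apply_event(CellState(molecules=[mol(1, 5, degrading=True)]),
                        ("rnase_binding", 0), p)


class TestSimulateCell:
    def test_turn_on_starts_from_nothing(self):
        proto = make_turn_on_protocol(t_end=5.0, sample_times=(0.0, 2.0, 5.0))
        traj = simulate_cell(make_params(), proto, ProbeSpec(), rng=3)
        t0, rec0 = traj[0]
        assert t0 == 0.0
        assert rec0.total == 0.0

    def test_silent_gene_stays_silent(self):
        p = make_params(k_ini=1e-9)
        proto = make_turn_on_protocol(t_end=10.0, sample_times=(0.0, 5.0, 10.0))
        traj = simulate_cell(p, proto, ProbeSpec(), rng=4)
        assert all(rec.total == 0.0 for _, rec in traj)

    def test_event_budget_overflow_raises(self):
        p = make_params(k_ini=500.0, k_off=0.01, k_on=50.0)
        proto = make_turn_on_protocol(t_end=15.0, sample_times=(0.0, 15.0))
        with pytest.raises(EventBudgetExceeded):
            simulate_cell(p, proto, ProbeSpec(), rng=5, max_events=500)


class TestEnsembleDeterminism:
    def test_worker_count_does_not_change_results(self, full_probe):
        p = make_params()
        proto = make_turn_on_protocol(t_end=8.0)
        a = simulate_ensemble(p, proto, full_probe, 60, seed=9, workers=1)
        b = simulate_ensemble(p, proto, full_probe, 60, seed=9, workers=4)
        assert a.df.equals(b.df)

    def test_distinct_seeds_differ(self, full_probe):
        p = make_params()
        proto = make_turn_on_protocol(t_end=8.0)
        a = simulate_ensemble(p, proto, full_probe, 40, seed=1)
        b = simulate_ensemble(p, proto, full_probe, 40, seed=2)
        assert not a.df.equals(b.df)

    def test_rectangular_table(self, full_probe):
        p = make_params()
        proto = make_turn_on_protocol(t_end=4.0, sample_times=(0.0, 2.0, 4.0))
        ens = simulate_ensemble(p, proto, full_probe, 7, seed=0)
        assert len(ens.df) == 7 * 3
        assert ens.df.groupby("cell_id").size().eq(3).all()


class TestReferenceKernelAgreement:
    """The explicit-event reference engine and the compiled kernel implement
    the same process: their signal distributions must be indistinguishable."""

    def test_total_signal_distributions_match(self, full_probe):
        p = make_params()
        proto = make_turn_on_protocol(t_end=6.0, sample_times=(3.0, 6.0))
        ref = []
        for c in range(150):
            g = np.random.default_rng(np.random.SeedSequence(500, spawn_key=(c,)))
            traj = simulate_cell_reference(p, proto, full_probe, g)
            ref.append([rec.total for _, rec, _ in traj])
        ref = np.array(ref)
        ens = simulate_ensemble(p, proto, full_probe, 1500, seed=501)
        for i, t in enumerate((3.0, 6.0)):
            ks = sps.ks_2samp(ref[:, i], ens.signals_at(t, "total"))
            assert ks.pvalue > 0.001, f"t={t}: p={ks.pvalue}"


class TestBurnIn:
    def test_doubling_burn_time_changes_nothing_statistically(self, full_probe):
        p = make_params()
        base = 10.0 / min(p.k_deg, 1.0)
        totals = {}
        for label, burn in (("1x", base), ("2x", 2 * base)):
            vals = []
            for c in range(400):
                g = np.random.default_rng(
                    np.random.SeedSequence(42 + (label == "2x"), spawn_key=(c,))
                )
                cell = burn_in_steady_state(p, g, burn_time=burn)
                vals.append(cell_signals(cell, full_probe, p.N).total)
            totals[label] = np.array(vals)
        ks = sps.ks_2samp(totals["1x"], totals["2x"])
        assert ks.pvalue > 0.01

    def test_silent_gene_burns_to_empty(self):
        p = make_params(k_ini=1e-9)
        cell = burn_in_steady_state(p, rng=7, burn_time=30.0)
        assert cell.molecules == []

    def test_turn_off_protocol_starts_at_steady_state(self, full_probe):
        # mean total just after t=0 should be near the pre-step steady level,
        # then decay under full repression
        from txnsim import make_turn_off_protocol, mean_trace

        p = make_params()
        proto = make_turn_off_protocol(k_on_pre=None, k_on_post=0.0, t_end=10.0,
                                       sample_times=(0.0, 5.0, 10.0))
        ens = simulate_ensemble(p, proto, full_probe, 400, seed=8)
        trace = mean_trace(ens, "total")
        assert trace.loc[0.0] > trace.loc[5.0] > trace.loc[10.0]
        assert trace.loc[10.0] < 0.25 * trace.loc[0.0]
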