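"""Recover the degradation-initiation rate from synthetic data.

Generates a 1,000-cell synthetic turn-on target from known parameters, then
fits k_deg alone (the other four rates clamped at truth) by minimizing the
mean squared error of the total-signal mean trace with the genetic
algorithm.  Prints the recovered value against the generating one.
"""

from txnsim import (
    VALIDATION_GROUND_TRUTH as truth,
    ProbeSpec,
    SearchDomain,
    SimSettings,
    StageConfig,
    generate_synthetic_target,
    make_turn_on_protocol,
    run_single_stage_fit,
)

probe = ProbeSpec()
protocol = make_turn_on_protocol(t_end=15.0)
target = generate_synthetic_target(truth, protocol, probe, n_cells=1000,
                                   seed=42)

domain = SearchDomain(
    bounds={"k_deg": (1e-2, 1e2)},
    fixed={"k_ini": truth.k_ini, "k_on": truth.k_on, "k_off": truth.k_off,
           "v_el": truth.v_el},
)
stage = StageConfig(stage_id=2, population=24, generations=6, n_cells=200,
                    elite_fraction=0.25)
settings = SimSettings(L=truth.L, N=truth.N)

estimate = run_single_stage_fit(target, domain, stage, settings, seed=3)

lo, hi = estimate.one_sigma_interval("k_deg")
print(f"true k_deg      : {truth.k_deg} /min")
print(f"recovered k_deg : {estimate.point['k_deg']:.3f} /min "
      f"(one-sigma {lo:.3f} .. {hi:.3f})")
print(
    "\nThe point estimate is the log-space mean of the final GA population;\n"
    "a ratio to truth within ~1.25 is typical at this data size."
)
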