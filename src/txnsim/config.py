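"""JSON run configurations: schema validation and object construction.

Every CLI workflow is driven by a JSON config so that any output can be
regenerated from the config plus the seed alone.  Unknown keys are rejected
rather than ignored -- a typo in a rate name must fail loudly, not silently
fall back to a default.
"""

from __future__ import annotations

import json
from pathlib import Path

from .engine import ExperimentProtocol
from .inference import (
    SearchDomain,
    SimSettings,
    StageConfig,
    default_stage_configs,
    reduced_stage_configs,
)
from .kinetics import KineticParameters, ProbeSpec


class ConfigError(ValueError):
    """Malformed run configuration."""


def _check_keys(d: dict, allowed: set[str], required: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    missing = required - set(d)
    if missing:
        raise ConfigError(f"missing keys in {where}: {sorted(missing)}")


def params_from_dict(d: dict) -> KineticParameters:
    _check_keys(d, {"k_on", "k_off", "k_ini", "k_deg", "v_el", "L", "N"},
                {"k_on", "k_off", "k_ini", "k_deg", "v_el", "L", "N"}, "params")
    try:
        return KineticParameters(**d)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid params: {exc}") from exc


def probe_from_dict(d: dict | None) -> ProbeSpec:
    if d is None:
        return ProbeSpec()
    _check_keys(d, {"p5", "p3"}, set(), "probe")
    try:
        return ProbeSpec(**d)
    except ValueError as exc:
        raise ConfigError(f"invalid probe: {exc}") from exc


def protocol_from_dict(d: dict) -> ExperimentProtocol:
    _check_keys(
        d,
        {"kind", "t_end", "sample_times", "k_on_high", "k_on_pre", "k_on_post",
         "burn_time"},
        {"kind", "t_end"},
        "protocol",
    )
    kind = d["kind"]
    if kind not in ("turn_on", "turn_off"):
        raise ConfigError(f"protocol kind must be turn_on or turn_off, got {kind!r}")
    from .targets import make_turn_off_protocol, make_turn_on_protocol

    sample_times = tuple(d["sample_times"]) if "sample_times" in d else None
    try:
        if kind == "turn_on":
            return make_turn_on_protocol(
                k_on_high=d.get("k_on_high"), t_end=d["t_end"],
                sample_times=sample_times,
            )
        return make_turn_off_protocol(
            k_on_pre=d.get("k_on_pre"), k_on_post=d.get("k_on_post", 0.0),
            t_end=d["t_end"], sample_times=sample_times,
            burn_time=d.get("burn_time"),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid protocol: {exc}") from exc


def domain_from_dict(d: dict | None) -> SearchDomain:
    if d is None:
        return SearchDomain()
    _check_keys(d, {"bounds", "fixed"}, set(), "domain")
    kwargs = {}
    if "bounds" in d:
        kwargs["bounds"] = {k: tuple(v) for k, v in d["bounds"].items()}
    if "fixed" in d:
        kwargs["fixed"] = dict(d["fixed"])
    try:
        return SearchDomain(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"invalid domain: {exc}") from exc


_STAGE_KEYS = {
    "stage_id", "population", "generations", "n_cells", "elite_fraction",
    "penalty_radius", "penalty_weight", "weighting", "tau", "n_early",
}


def stages_from_config(spec) -> list[StageConfig]:
    """'default', 'reduced', or an explicit list of stage dicts."""
    if spec is None or spec == "default":
        return default_stage_configs()
    if spec == "reduced":
        return reduced_stage_configs()
    if not isinstance(spec, list):
        raise ConfigError("stages must be 'default', 'reduced', or a list")
    out = []
    for i, d in enumerate(spec):
        _check_keys(d, _STAGE_KEYS, {"stage_id", "population", "generations",
                                     "n_cells"}, f"stages[{i}]")
        out.append(StageConfig(**d))
    return out


def sim_settings_from_dict(d: dict) -> SimSettings:
    _check_keys(d, {"L", "N", "probe", "bin_width", "max_events", "workers"},
                {"L", "N"}, "sim")
    d = dict(d)
    probe = probe_from_dict(d.pop("probe", None))
    return SimSettings(probe=probe, **d)


def load_config(path: str | Path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"config {path} is not valid JSON: {exc}") from exc


def dump_resolved(config: dict, path: str | Path) -> None:
    """Write the config with defaults filled so runs are reproducible from
    artifacts alone."""
    Path(path).write_text(json.dumps(config, indent=2, default=str))
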