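"""Time-series writers/readers and deterministic spike-train fixtures."""

import difflib
import json
import math
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import ALL_COLUMNS, SimConfig, SimResult, StimulusSpec
from .errors import ValidationError
from .params import ModelParameters, ModelVariants


@dataclass(frozen=True)
class SpikeTrainFixture:
    """Deterministic spike-event list for neuron-free astrocyte runs."""

    times: tuple
    rate: float
    duration: float
    seed: int

    def __post_init__(self):
        t = np.asarray(self.times)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > self.duration):
            raise ValidationError("spike times must be strictly increasing within [0, duration]")


def generate_spike_train(rate: float, duration: float, jitter: float = 0.0,
                         seed: int = 0) -> SpikeTrainFixture:
    """Regular spike train at ``rate`` Hz with optional seeded timing jitter.

    Events use the centred convention (first event at half a period), so a
    10 Hz, 1 s train has events at 0.05, 0.15, ..., 0.95 s.  ``jitter`` is
    the fractional standard deviation of the inter-spike interval, capped to
    keep the times strictly increasing; the same seed always yields the same
    train.
    """
    if rate < 0:
        raise ValidationError("rate must be >= 0")
    if duration <= 0:
        raise ValidationError("duration must be positive")
    if not (0.0 <= jitter < 0.5):
        raise ValidationError(f"jitter must be in [0, 0.5), got {jitter}")
    if rate == 0:
        return SpikeTrainFixture(times=(), rate=0.0, duration=duration, seed=seed)
    period = 1.0 / rate
    n = int(math.floor(duration * rate))
    base = (np.arange(n) + 0.5) * period
    if jitter > 0:
        rng = np.random.default_rng(seed)
        offsets = rng.normal(0.0, jitter * period, size=n)
        offsets = np.clip(offsets, -0.49 * period, 0.49 * period)
        base = base + offsets
    base = base[(base >= 0) & (base <= duration)]
    return SpikeTrainFixture(times=tuple(base), rate=rate, duration=duration,
                             seed=seed)


def write_timeseries(result: SimResult, path: str | Path) -> tuple[Path, Path]:
    """Write a run to ``<path>.csv`` (time series) and ``<path>.json`` (sidecar).

    The CSV carries one column per state/current with the unit in the
    header; the sidecar carries the configuration hash, calibration values
    and spike times.  Round-trips through :func:`read_timeseries` reproduce
    the values at the recorded precision (12 significant digits).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")
    result.data.to_csv(csv_path, index=False, float_format="%.12g")
    sidecar = dict(result.metadata)
    sidecar["spike_times_s"] = [float(t) for t in result.spike_times]
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return csv_path, json_path


def read_timeseries(path: str | Path) -> SimResult:
    """Read a run written by :func:`write_timeseries`."""
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")
    data = pd.read_csv(csv_path)
    missing = [c for c in ALL_COLUMNS if c not in data.columns]
    if missing and len(data):
        raise ValidationError(f"time series is missing columns: {missing}")
    with open(json_path) as fh:
        meta = json.load(fh)
    spikes = np.asarray(meta.pop("spike_times_s", []), dtype=float)
    return SimResult(data=data, spike_times=spikes, metadata=meta)


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_SECTIONS = ("geometry", "constants", "astrocyte", "neuron", "protocol")

_GEOMETRY_KEYS = {"r_ips", "r_eps", "l_ps", "r_p", "l_p", "r_syn", "l_syn",
                  "vol_syn", "sa_psecs_gecs"}

_CONSTANT_KEYS = {"R", "T", "F", "k_B", "Q", "eps0", "eps_r"}

_ASTRO_KEYS = {
    "v_a", "g_kir", "g_k_bg", "g_na_bg", "p_nka_max", "k_nai", "k_ke",
    "i_bar_ncx", "gamma_ncx", "j0_eaat", "tau_eaat", "g_ecs_leak",
    "phi_w", "k_pf_k", "k_pf_na", "k_pf_ca",
    "k_psc_0", "na_psc_0", "ca_psc_0", "k_psecs_0", "na_psecs_0",
    "ca_psecs", "k_gecs", "na_gecs", "ca_gecs", "k_soma", "na_soma",
    "ca_soma", "glu_ecs", "glu_psc", "h_psc", "h_psecs",
    "alpha_eaat", "beta_eaat", "r_g", "s_g",
    "background_k_in_psc", "kir_sqrt_k_out", "pf_charge_valence",
    "nernst_valence",
}

_NEURON_KEYS = {
    "c_m", "g_k_neu", "g_na_neu", "g_leak_neu", "g_k_bg_neu", "g_na_bg_neu",
    "e_k_neu", "e_na_neu", "e_leak_neu", "p_nka_max_neu", "k_nai_neu",
    "k_ke_neu", "k_syn", "na_syn", "spike_threshold_offset",
    "spike_refractory", "na_channel_h_gate",
}

_PROTOCOL_KEYS = {"dt", "t_settle", "t_stim", "t_post", "record_stride",
                  "seed", "concentration_floor", "mode", "rate", "amplitude",
                  "pulse_width", "events"}

_VARIANT_FIELDS = {f.name for f in fields(ModelVariants)}


def _check_keys(section: str, given: dict, allowed: set, errors: list):
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            msg = f"[{section}] unknown key '{key}'"
            if hint:
                msg += f"; did you mean '{hint[0]}'?"
            msg += f" (valid keys: {', '.join(sorted(allowed))})"
            errors.append(msg)


def validate_config(raw: dict | None) -> tuple[ModelParameters, "SimConfig", dict]:
    """Build parameters and a simulation config from a raw config mapping.

    Missing keys take the reference-table defaults; unknown sections or keys
    are rejected with a suggestion, and all violations are reported at once.
    Returns ``(params, sim_config, geometry_kwargs)``.
    """
    raw = dict(raw or {})
    errors: list[str] = []
    _check_keys("top level", raw, set(_SECTIONS), errors)
    geo = dict(raw.get("geometry") or {})
    con = dict(raw.get("constants") or {})
    ast = dict(raw.get("astrocyte") or {})
    neu = dict(raw.get("neuron") or {})
    pro = dict(raw.get("protocol") or {})
    _check_keys("geometry", geo, _GEOMETRY_KEYS, errors)
    _check_keys("constants", con, _CONSTANT_KEYS, errors)
    _check_keys("astrocyte", ast, _ASTRO_KEYS, errors)
    _check_keys("neuron", neu, _NEURON_KEYS, errors)
    _check_keys("protocol", pro, _PROTOCOL_KEYS, errors)
    if errors:
        raise ValidationError("invalid configuration:\n  " + "\n  ".join(errors))

    variant_kwargs = {}
    for src in (ast, neu):
        for key in list(src):
            if key in _VARIANT_FIELDS:
                variant_kwargs[key] = bool(src.pop(key))
    param_kwargs = {}
    param_kwargs.update(ast)
    param_kwargs.update(neu)
    if con:
        from .constants import PhysicalConstants
        param_kwargs["constants"] = PhysicalConstants(**con)
    if variant_kwargs:
        param_kwargs["variants"] = ModelVariants(**variant_kwargs)

    stim_kwargs = {k: pro.pop(k) for k in ("mode", "rate", "amplitude",
                                           "pulse_width", "events") if k in pro}
    if "events" in stim_kwargs:
        stim_kwargs["events"] = tuple(stim_kwargs["events"])
    try:
        params = ModelParameters(**param_kwargs)
        sim = SimConfig(stimulus=StimulusSpec(**stim_kwargs), **pro)
    except (TypeError, ValidationError) as exc:
        raise ValidationError(f"invalid configuration: {exc}") from exc
    return params, sim, geo


def load_config(path: str | Path) -> tuple[ModelParameters, "SimConfig", dict]:
    """Load and validate a YAML (or JSON) configuration file."""
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError("configuration root must be a mapping")
    return validate_config(raw)


def default_config() -> dict:
    """The full default configuration as a serialisable mapping."""
    p = ModelParameters()
    sim = SimConfig()
    geo = {"r_ips": 150e-9, "r_eps": 250e-9, "l_ps": 300e-9, "r_p": 50e-9,
           "l_p": 25e-6, "r_syn": 135e-9, "l_syn": 300e-9}
    ast = {k: getattr(p, k) for k in sorted(_ASTRO_KEYS - _VARIANT_FIELDS)}
    for k in sorted(_VARIANT_FIELDS - {"na_channel_h_gate"}):
        ast[k] = getattr(p.variants, k)
    neu = {k: getattr(p, k) for k in sorted(_NEURON_KEYS - {"na_channel_h_gate"})}
    neu["na_channel_h_gate"] = p.variants.na_channel_h_gate
    con = {k: getattr(p.constants, k) for k in sorted(_CONSTANT_KEYS)}
    pro = {"dt": sim.dt, "t_settle": sim.t_settle, "t_stim": sim.t_stim,
           "t_post": sim.t_post, "record_stride": sim.record_stride,
           "seed": sim.seed, "concentration_floor": sim.concentration_floor,
           "mode": sim.stimulus.mode, "rate": sim.stimulus.rate,
           "amplitude": sim.stimulus.amplitude,
           "pulse_width": sim.stimulus.pulse_width,
           "events": list(sim.stimulus.events)}
    return {"geometry": geo, "constants": con, "astrocyte": ast,
            "neuron": neu, "protocol": pro}
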