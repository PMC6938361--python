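"""Run configuration: defaults, YAML loading, validation and hashing."""

from __future__ import annotations

import copy
import hashlib
import json
import math
from pathlib import Path
from typing import Mapping, Optional, Tuple

import yaml

from .design import DesignParams, StimulusTiming
from .errors import ConfigurationError
from .synth import (DEFAULT_GROUP_SIZES, GroupParams, LearningModel, NoiseModel,
                    default_learning_model)


def default_config() -> dict:
    """Full default configuration (study-sized cohort; scale down for smoke runs)."""
    model = default_learning_model()
    groups_cfg = {}
    for g, gp in model.groups.items():
        groups_cfg[g] = dict(
            p_max=dict(gp.p_max), slope=gp.slope,
            inflection_session=gp.inflection_session,
            peak_latency_mean_ms=dict(gp.peak_latency_mean_ms),
            peak_latency_sd_ms=gp.peak_latency_sd_ms,
            amp_log_mean=gp.amp_log_mean, amp_log_sd=gp.amp_log_sd,
            cr_duration_ms=gp.cr_duration_ms, cr_peak_fraction=gp.cr_peak_fraction,
            ur_latency_ms=gp.ur_latency_ms, ur_amplitude_sd=gp.ur_amplitude_sd,
            ur_duration_ms=gp.ur_duration_ms, spont_rate_hz=gp.spont_rate_hz,
            spont_amp_log_mean=gp.spont_amp_log_mean,
            spont_amp_log_sd=gp.spont_amp_log_sd,
            spont_duration_ms=gp.spont_duration_ms,
            hyperactive_prob=gp.hyperactive_prob)
    return dict(
        design=dict(n_sessions=7, n_blocks=12, trials_per_block=10,
                    paired_per_block=9, iti_range_s=[25.0, 40.0],
                    cs_duration_ms=3350.0, us_onset_ms=3300.0, us_duration_ms=50.0),
        noise=dict(sigma=1.0, band_hz=[100.0, 1000.0], order=4),
        # illustrative, not fitted: qualitative orderings only
        model=dict(groups=groups_cfg, detection_sd=4.0, onset_margin_ms=60.0),
        cohort=dict(group_sizes=dict(DEFAULT_GROUP_SIZES)),
        scoring=dict(tau_ms=1.0, integrator="exponential",
                     baseline_window_ms=[-300.0, 0.0], threshold_multiplier=4.0,
                     min_duration_ms=10.0, peak_scope="epochs",
                     scope="paired_only"),
        stats=dict(measures=["cr_percent", "peak_amplitude", "start_latency",
                             "peak_latency"],
                   windows=["short", "middle", "long"], alpha=0.05,
                   gg_correction=False),
    )


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if k in out and isinstance(out[k], dict) and isinstance(v, Mapping):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: Optional[str] = None, overrides: Optional[Mapping] = None) -> dict:
    """Defaults, optionally merged with a YAML file and explicit overrides."""
    cfg = default_config()
    if path is not None:
        with open(Path(path)) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def design_from_config(cfg: Mapping) -> DesignParams:
    d = cfg["design"]
    timing = StimulusTiming(cs_duration_ms=d["cs_duration_ms"],
                            us_onset_ms=d["us_onset_ms"],
                            us_duration_ms=d["us_duration_ms"])
    return DesignParams(n_sessions=d["n_sessions"], n_blocks=d["n_blocks"],
                        trials_per_block=d["trials_per_block"],
                        paired_per_block=d["paired_per_block"],
                        iti_range_s=tuple(d["iti_range_s"]), timing=timing)


def noise_from_config(cfg: Mapping) -> NoiseModel:
    n = cfg["noise"]
    return NoiseModel(sigma=n["sigma"], band_hz=tuple(n["band_hz"]), order=n["order"])


def model_from_config(cfg: Mapping) -> LearningModel:
    m = cfg["model"]
    groups = {g: GroupParams(**gc) for g, gc in m["groups"].items()}
    return LearningModel(groups=groups, detection_sd=m["detection_sd"],
                         onset_margin_ms=m["onset_margin_ms"])


def validate_config(cfg: Mapping) -> None:
    """Schema-level validation; raises before any computation."""
    for section in ("design", "noise", "model", "cohort", "scoring", "stats"):
        if section not in cfg:
            raise ConfigurationError(f"config missing section {section!r}")
    design_from_config(cfg)       # raises on invalid design
    noise_from_config(cfg)
    model = model_from_config(cfg)
    for g, n in cfg["cohort"]["group_sizes"].items():
        model.group_params(g)
        if not isinstance(n, int) or n < 1:
            raise ConfigurationError(f"cohort group size for {g!r} must be a positive int")
    sc = cfg["scoring"]
    if sc["tau_ms"] <= 0:
        raise ConfigurationError("scoring.tau_ms must be > 0")
    if sc["threshold_multiplier"] <= 0:
        raise ConfigurationError("scoring.threshold_multiplier must be > 0")
    if sc["scope"] not in ("paired_only", "all_trials"):
        raise ConfigurationError("scoring.scope must be paired_only or all_trials")
    alpha = cfg["stats"]["alpha"]
    if not (0 < alpha < 1) or not math.isfinite(alpha):
        raise ConfigurationError("stats.alpha must be in (0, 1)")
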