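"""Configuration objects for the simulator and the analysis pipeline.

``SimConfig`` holds every tunable of the synthetic-data generator; its defaults
are the study conditions the analysis assumes (15 Hz sampling, 4-min imaged
segments, 1.5 mm push threshold, ~40 axon segments with ~10 boutons each).
``RunConfig`` holds every analysis tunable (thresholds, windows, bins, stage
boundaries) with defaults equal to the published values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

CATEGORIES = ("RM_only", "UM_only", "both", "unresponsive")


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(name, f"probability must lie in [0, 1], got {value!r}")


@dataclass
class TurnoverParams:
    """Session-to-session structural dynamics of boutons along an axon.

    ``p_form`` / ``p_elim`` are per-session-pair probabilities relative to the
    previous session's bouton count.  When ``cluster_sigma_um`` is set, newly
    formed boutons are placed around a per-axon Gaussian cluster centre with
    that standard deviation instead of uniformly along the axon.
    """

    p_form: float = 0.15
    p_elim: float = 0.15
    cluster_sigma_um: float | None = None
    axon_length_um: float = 100.0
    n_sessions: int = 2

    def validate(self) -> None:
        _check_prob("turnover.p_form", self.p_form)
        _check_prob("turnover.p_elim", self.p_elim)
        if self.axon_length_um <= 0:
            raise ConfigError("turnover.axon_length_um", "must be positive")
        if self.n_sessions < 2:
            raise ConfigError("turnover.n_sessions", "need at least 2 sessions")
        if self.cluster_sigma_um is not None and self.cluster_sigma_um <= 0:
            raise ConfigError(
                "turnover.cluster_sigma_um",
                "must be positive when clustering is enabled",
            )


@dataclass
class SimConfig:
    # population size (defaults mirror the imaged-population scale:
    # ~40 axon segments per mouse, ~10 boutons per segment)
    n_mice: int = 1
    n_axons_per_mouse: int = 40
    boutons_per_axon: int = 10

    # acquisition
    fs_hz: float = 15.0
    segment_s: float = 240.0

    # task
    n_trials: int = 30
    p_rm: float = 0.6
    task_window_s: float = 2.5
    iti_range_s: tuple[float, float] = (3.0, 6.0)
    push_threshold_mm: float = 1.5
    iti_push_rate_per_min: float = 0.0
    p_delay: float = 0.0
    p_omission: float = 0.0
    p_cue_only: float = 0.0

    # activity
    shared_event_fraction: float = 0.8
    event_rate_hz: float = 0.2
    snr: float = 8.0
    tau_rise_s: float = 0.05
    tau_decay_s: float = 0.6
    response_prob: float = 0.9
    amp_jitter: float = 0.2
    baseline_f: float = 100.0
    noise_sd: float = 1.0
    drift_frac: float = 0.1
    category_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "RM_only": 0.4,
            "UM_only": 0.2,
            "both": 0.2,
            "unresponsive": 0.2,
        }
    )
    # probability a bouton deviates from its axon's dominant category;
    # None ties it to the bouton-unique event fraction (1 - shared_event_fraction)
    category_deviation_p: float | None = None

    # structure
    turnover: TurnoverParams = field(default_factory=TurnoverParams)

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mice", "n_axons_per_mouse", "boutons_per_axon"):
            if getattr(self, name) < 1:
                raise ConfigError(name, "must be a positive count")
        if self.fs_hz <= 0:
            raise ConfigError("fs_hz", "sampling rate must be positive")
        if self.segment_s <= 0:
            raise ConfigError("segment_s", "segment duration must be positive")
        if self.n_trials < 0:
            raise ConfigError("n_trials", "must be non-negative")
        if self.snr < 0:
            raise ConfigError("snr", "must be non-negative")
        for name in ("p_rm", "shared_event_fraction", "response_prob",
                     "p_delay", "p_omission", "p_cue_only"):
            _check_prob(name, getattr(self, name))
        if self.category_deviation_p is not None:
            _check_prob("category_deviation_p", self.category_deviation_p)
        if self.p_delay + self.p_omission + self.p_cue_only > 1.0 + 1e-9:
            raise ConfigError("p_delay", "trial-variant probabilities sum above 1")
        mix = dict(self.category_mix)
        if set(mix) - set(CATEGORIES):
            raise ConfigError("category_mix", f"unknown categories {set(mix) - set(CATEGORIES)}")
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError("category_mix", f"proportions must sum to 1, got {total}")
        if any(v < 0 for v in mix.values()):
            raise ConfigError("category_mix", "proportions must be non-negative")
        self.turnover.validate()

    @property
    def deviation_p(self) -> float:
        """Per-bouton probability of deviating from the axon's dominant category."""
        if self.category_deviation_p is not None:
            return self.category_deviation_p
        return 1.0 - self.shared_event_fraction


# ---------------------------------------------------------------------------
# analysis configuration

_RUN_DEFAULTS: dict = {
    "fs_hz": 15.0,
    "behavior": {
        "merge_gap_s": 0.5,            # bouts closer than this are one movement
        "exclusion_window_s": 3.0,     # clean-baseline rule before each bout
        "push_threshold_mm": 1.5,
        "movement_threshold_mm": None,  # None -> resting median + 3*MAD
        "trajectory_window_s": [-0.5, 2.0],
        "trajectory_n_points": 64,
    },
    "baseline": {
        "window_s": 30.0,
        "percentile": 30.0,
        "align": "centered",           # centered | trailing
    },
    "events": {
        "threshold_sd": 1.0,
        "match_tol_s": 0.670,
        "label_pre_s": 0.330,
        "label_post_s": 0.670,
    },
    "alignment": {
        "pre_s": 1.0,
        "post_s": 3.0,
    },
    "classify": {
        "peak_window_s": [-0.2, 3.0],
        "criterion_sd": 0.9,
        "axon_bin_sd": 0.1,
        "axon_cap_sd": 1.0,
        "min_trials": 5,
        "delay_shift_s": 0.93,
        "delay_window_s": [1.67, 2.33],
        "omission_window_s": [0.67, 1.33],
    },
    "population": {
        "bins": [-0.2, 0.0, 0.2, 0.4, 0.6, 0.8, 1.0],
        "activation_window_s": [0.0, 3.0],
        "axon_corr_split": 0.7,
        "heterogeneity_both_policy": "dominant",  # dominant | exclude
    },
    "structure": {
        "n_shuffles": 1000,
        "match_tolerance_um": 2.0,
        "nnd_grid_um": 1.0,
        "shuffle_mode": "uniform",     # uniform | permute
    },
    "stages": {
        "early_sessions": [1, 2, 3],
        "late_min_session": 8,
    },
    "seed": 0,
}


def _merge(defaults: dict, override: Mapping, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in override:
            oval = override[key]
            if isinstance(dval, dict):
                if not isinstance(oval, Mapping):
                    raise ConfigError(path + key, "expected a mapping")
                out[key] = _merge(dval, oval, path + key + ".")
            else:
                out[key] = oval
        else:
            out[key] = dval if not isinstance(dval, dict) else _merge(dval, {}, path + key + ".")
    unknown = set(override) - set(defaults)
    if unknown:
        raise ConfigError(path + sorted(unknown)[0], "unknown configuration key")
    return out


class RunConfig:
    """Analysis configuration: a validated key tree with published defaults.

    Unknown keys are rejected so a typo cannot silently fall back to a default.
    """

    def __init__(self, overrides: Mapping | None = None):
        self._tree = _merge(_RUN_DEFAULTS, overrides or {})

    def __getitem__(self, key: str):
        node = self._tree
        for part in key.split("."):
            node = node[part]
        return node

    def to_dict(self) -> dict:
        import copy

        return copy.deepcopy(self._tree)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self._tree, fh, sort_keys=True)


def simconfig_from_mapping(data: Mapping) -> SimConfig:
    """Build a :class:`SimConfig` from a plain mapping (e.g. parsed YAML)."""
    data = dict(data)
    if "turnover" in data and isinstance(data["turnover"], Mapping):
        data["turnover"] = TurnoverParams(**data["turnover"])
    if "iti_range_s" in data:
        data["iti_range_s"] = tuple(data["iti_range_s"])
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(sorted(unknown)[0], "unknown simulation key")
    return SimConfig(**data)
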