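"""Analysis configuration: every downstream tunable in one serializable object.

All pipeline stages are pure functions of (inputs, config, seed); the config
hash recorded in result files makes any output traceable to the exact
parameter set that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

#: Envelope-spectrum frequency bands (Hz). Delta and theta-alpha carry the
#: low-frequency anesthesia signatures, beta the parkinsonian motor-STN
#: oscillation, gamma the non-motor (ventromedial) signature.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta_alpha": (4.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (31.0, 70.0),
    "high": (70.0, 150.0),
}


@dataclass
class AnalysisConfig:
    """Tunables for feature extraction, border detection, spikes and stats.

    Defaults reproduce the standard operating point of the pipeline; every
    field can be overridden from YAML (:meth:`from_yaml`).
    """

    # --- per-site spectral features -------------------------------------
    spiking_band_hz: tuple[float, float] = (300.0, 6000.0)  # multiunit band
    psd_resolution_hz: float = 1.0 / 3.0
    psd_fmax_hz: float = 200.0
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in BANDS.items()}
    )
    n_baseline_sites: int = 5  # sites used as the NRMS reference level
    n_grid: int = 100  # points of the normalized depth axis [-0.5, 1]

    # --- STN border detection -------------------------------------------
    nrms_entry_threshold: float = 1.25
    entry_min_run: int = 3
    changepoint_contrast_floor: float = 0.2  # relative contrast, unitless
    motor_fallback_fraction: float = 0.25

    # --- spike detection -------------------------------------------------
    spike_band_hz: tuple[float, float] = (300.0, 3000.0)
    spike_threshold_sd: float = 4.0
    refractory_ms: float = 1.5
    exclusion_pre_ms: float = 1.0
    exclusion_post_ms: float = 2.0
    collision_policy: str = "drop_earlier"  # or "drop_both"
    noise_sd_estimator: str = "robust"  # or "std"

    # --- spike-triggered averaging ---------------------------------------
    sta_pre_s: float = 1.0
    sta_post_s: float = 2.0
    sta_fs_hz: float = 1000.0

    # --- group statistics -------------------------------------------------
    iqr_multiplier: float = 1.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        for name, (lo, hi) in {"spiking_band_hz": self.spiking_band_hz,
                               "spike_band_hz": self.spike_band_hz,
                               **self.bands}.items():
            if not 0.0 <= lo < hi:
                raise ValueError(f"band {name} must satisfy 0 <= low < high, got ({lo}, {hi})")
        if self.collision_policy not in ("drop_earlier", "drop_both"):
            raise ValueError(f"unknown collision_policy {self.collision_policy!r}")
        if self.noise_sd_estimator not in ("robust", "std"):
            raise ValueError(f"unknown noise_sd_estimator {self.noise_sd_estimator!r}")

    # --- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spiking_band_hz"] = list(self.spiking_band_hz)
        d["spike_band_hz"] = list(self.spike_band_hz)
        d["bands"] = {k: list(v) for k, v in self.bands.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("spiking_band_hz", "spike_band_hz"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "bands" in kwargs:
            kwargs["bands"] = {k: tuple(v) for k, v in kwargs["bands"].items()}
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def hash(self) -> str:
        """Short content hash of the canonical JSON form."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
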