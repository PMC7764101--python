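"""Run configuration: YAML round-trip and content hashing.

A :class:`RunConfig` captures every knob of an end-to-end run (phantom
geometry scale, cohort composition, tracking parameters, parcellation and
stats options, master seed).  Its SHA-256 content hash is stamped into
every output so that outputs from different configurations cannot be mixed
silently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import yaml

from .phantom import CohortSpec
from .tracking import TrackingParams


@dataclass
class ParcellationOptions:
    mpm_threshold: float = 0.5
    endpoints_only: bool = False
    fa_n_streamlines: int = 10000   # FA sampling per parcel
    fa_interp: str = "trilinear"    # "trilinear" | "nearest"
    save_tractograms: bool = False
    shared_fa_tracks: bool = False  # one FA track geometry per cohort


@dataclass
class StatsOptions:
    ss_type: int = 3
    alpha: float = 0.05


@dataclass
class PhantomOptions:
    """Knobs of the canonical phantom geometry (see phantom module)."""

    grid_shape: tuple = (64, 64, 64)
    voxel_size: float = 1.0
    crossing_fraction: float = 0.0
    angular_noise_deg: float = 0.0


@dataclass
class RunConfig:
    phantom: PhantomOptions = dc_field(default_factory=PhantomOptions)
    cohort: CohortSpec = dc_field(default_factory=CohortSpec)
    tracking: TrackingParams = dc_field(default_factory=TrackingParams)
    parcellation: ParcellationOptions = dc_field(
        default_factory=ParcellationOptions)
    stats: StatsOptions = dc_field(default_factory=StatsOptions)
    out_dir: str = "midparc_out"
    master_seed: int = 0

    def to_dict(self):
        d = asdict(self)
        d["phantom"]["grid_shape"] = list(self.phantom.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        ph = dict(d.get("phantom", {}))
        if "grid_shape" in ph:
            ph["grid_shape"] = tuple(ph["grid_shape"])
        return cls(
            phantom=PhantomOptions(**ph),
            cohort=CohortSpec(**d.get("cohort", {})),
            tracking=TrackingParams(**d.get("tracking", {})),
            parcellation=ParcellationOptions(**d.get("parcellation", {})),
            stats=StatsOptions(**d.get("stats", {})),
            out_dir=d.get("out_dir", "midparc_out"),
            master_seed=int(d.get("master_seed", 0)),
        )

    def to_yaml(self, path=None):
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source):
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))

    @property
    def hash(self):
        """SHA-256 of the canonical JSON serialization (first 16 hex chars)."""
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def check_config_hash(meta: dict, expected: str, source=""):
    """Raise when an output file carries a different config hash."""
    found = meta.get("config_hash", "")
    if found and expected and found != expected:
        raise ValueError(
            f"{source}: config hash mismatch (output {found}, "
            f"current configuration {expected}); outputs from different "
            "configurations cannot be mixed")
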