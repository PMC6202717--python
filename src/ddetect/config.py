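"""Flat run configuration with YAML round-trip and strict key checking."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Every tunable of a detector run, with documented defaults.

    bandwidth_increment : scan step for the critical-bandwidth search
        (log10 grams).
    h_max_fraction_of_range : scan cap as a fraction of the data range.
    grid_points : density evaluation grid size.
    resamples : number of null resamples (B).
    threshold : acceptance percentile; a gap is a discontinuity when its
        percentile strictly exceeds this.
    sampling_mode : "centers" (component-level without replacement) or
        "iid" (standard KDE draw).
    support_lower_bound : optional truncation of the density support on
        the log10 axis (off by default; body masses below 1 g are
        legitimate, so the log axis is unbounded).
    seed : master seed; all replicate streams derive from it.
    """

    bandwidth_increment: float = 0.001
    h_max_fraction_of_range: float = 0.5
    grid_points: int = 2048
    resamples: int = 5000
    threshold: float = 0.90
    sampling_mode: str = "centers"
    support_lower_bound: float | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
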