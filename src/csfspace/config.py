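"""Pipeline configuration: every stage parameter in one declarative object
with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All tunable stage parameters.

    Defaults are the package's documented choices; see docs/methods.md for
    the rationale behind each.
    """

    # bias correction
    bias_degree: int = 3
    bias_rounds: int = 2
    # tissue classification
    classify_init_percentiles: tuple[float, float, float] = (2.0, 50.0, 98.0)
    pve_interface_only: bool = True
    pve_pure_sigma_k: float = 2.0
    # graph cut
    graphcut_lambda: float = 0.5
    graphcut_sigma: float | None = None  # None: median absolute neighbor difference
    graphcut_connectivity: int = 6
    seeds_erode_r: int = 1
    seeds_dilate_r: int = 2
    seeds_support_threshold: float = 0.01
    post_open_r: int = 0  # seeded component filtering always applies; see docs
    # volumetry
    volumetry_mode: str = "fraction"  # or "hard"
    grid_erode_r: int = 1
    # statistics
    stats_posthoc: str = "dunn"  # or "tukey_ranks"
    stats_normality_alpha: float = 0.05
    # reproducibility
    seed: int = 0
    version: str = "0.1.0"

    def __post_init__(self) -> None:
        if not 1 <= self.bias_degree <= 4:
            raise ConfigError(f"bias_degree must be in [1, 4], got {self.bias_degree}")
        if self.graphcut_lambda < 0:
            raise ConfigError("graphcut_lambda must be >= 0")
        if self.graphcut_sigma is not None and self.graphcut_sigma <= 0:
            raise ConfigError("graphcut_sigma must be > 0 (or null for automatic)")
        if self.graphcut_connectivity != 6:
            raise ConfigError("only 6-connectivity is supported")
        if self.volumetry_mode not in ("fraction", "hard"):
            raise ConfigError(f"volumetry_mode must be 'fraction' or 'hard', got {self.volumetry_mode!r}")
        if self.stats_posthoc not in ("dunn", "tukey_ranks"):
            raise ConfigError(f"stats_posthoc must be 'dunn' or 'tukey_ranks', got {self.stats_posthoc!r}")
        if not 0 < self.stats_normality_alpha < 1:
            raise ConfigError("stats_normality_alpha must be in (0, 1)")
        if any(r < 0 for r in (self.seeds_erode_r, self.seeds_dilate_r, self.post_open_r, self.grid_erode_r)):
            raise ConfigError("radii must be non-negative")
        self.classify_init_percentiles = tuple(float(p) for p in self.classify_init_percentiles)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source.read())
        else:
            text = str(source)
            if "\n" not in text and text.endswith((".yml", ".yaml")):
                with open(text) as fh:
                    payload = yaml.safe_load(fh)
            else:
                payload = yaml.safe_load(text)
        if not isinstance(payload, dict):
            raise ConfigError("config file does not contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)
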