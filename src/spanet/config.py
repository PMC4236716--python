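"""Pipeline configuration: every statistical threshold in one validated record.

Defaults reproduce the published analysis settings: tuning at the 99.99%
confidence level (alpha 1e-4) against 100 degree-preserving random networks,
MCODE with degree threshold 2 / node score threshold 0.2 / K-core 2 / max depth
100 / haircut on / fluff off, enrichment at alpha 1e-4 on modules of >= 5
members, and a raw 0.05 threshold for reporter TFs.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path


class ConfigError(ValueError):
    """Invalid or unknown configuration value."""


@dataclass
class PipelineConfig:
    alpha_tuning: float = 0.0001
    n_random: int = 100
    mcode_degree_threshold: int = 2
    mcode_node_score_threshold: float = 0.2
    mcode_kcore: int = 2
    mcode_max_depth: int = 100
    mcode_haircut: bool = True
    mcode_fluff: bool = False
    enrichment_alpha: float = 0.0001
    min_module_size: int = 5
    reporter_alpha: float = 0.05
    reporter_background_samples: int = 10000
    seed: int = 0
    swap_multiplier: int = 10

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("alpha_tuning", "enrichment_alpha", "reporter_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must lie in (0, 1), got {v!r}")
        if not (0.0 <= self.mcode_node_score_threshold <= 1.0):
            raise ConfigError(
                "mcode_node_score_threshold must lie in [0, 1], got "
                f"{self.mcode_node_score_threshold!r}"
            )
        for name in (
            "n_random",
            "mcode_degree_threshold",
            "mcode_kcore",
            "mcode_max_depth",
            "min_module_size",
            "swap_multiplier",
            "reporter_background_samples",
        ):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 1):
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        if not isinstance(self.seed, int):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key = value`` text file; unknown keys are errors."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise ConfigError(f"{path}:{lineno}: unknown configuration key {key!r}")
            kwargs[key] = _coerce(key, value, lineno, path)
        return cls(**kwargs)


_BOOL_KEYS = {"mcode_haircut", "mcode_fluff"}
_FLOAT_KEYS = {
    "alpha_tuning",
    "mcode_node_score_threshold",
    "enrichment_alpha",
    "reporter_alpha",
}


def _coerce(key: str, value: str, lineno: int, path) -> object:
    try:
        if key in _BOOL_KEYS:
            low = value.lower()
            if low in ("on", "true", "1", "yes"):
                return True
            if low in ("off", "false", "0", "no"):
                return False
            raise ValueError(value)
        if key in _FLOAT_KEYS:
            return float(value)
        return int(value)
    except ValueError as exc:
        raise ConfigError(f"{path}:{lineno}: bad value for {key}: {value!r}") from exc
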