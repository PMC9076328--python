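"""Pipeline configuration: defaults, YAML loading, strict key validation.

Defaults reproduce the printed analysis settings: 200 Hz sampling, 20-s
segments split into 1-s epochs, an order-8 Butterworth low-pass at 50 Hz,
fuzzy entropy with m=2, n=2, r = 0.2*SD, and an 11-point lambda grid
0, 0.1, ..., 1.  Unknown configuration keys are rejected.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .features import FuzzyEnParams
from .laterality import DEFAULT_LAMBDA_GRID
from .preprocess import BAND_EDGES_HZ


@dataclass
class FilterConfig:
    cutoff_hz: float = 50.0
    order: int = 8


@dataclass
class WaveletConfig:
    backend: str = "wpt"  # "wpt" or "fir"
    family: str = "dmey"


@dataclass
class StatsConfig:
    alpha: float = 0.05
    holm: bool = False


@dataclass
class PipelineConfig:
    fs: float = 200.0
    segment_s: float = 20.0
    epoch_s: float = 1.0
    filter: FilterConfig = field(default_factory=FilterConfig)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    fuzzyen: FuzzyEnParams = field(default_factory=FuzzyEnParams)
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BAND_EDGES_HZ)
    )
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


_SECTION_TYPES = {
    "filter": FilterConfig,
    "wavelet": WaveletConfig,
    "fuzzyen": FuzzyEnParams,
    "stats": StatsConfig,
}


def _build_section(cls, mapping: Mapping[str, Any]):
    allowed = {f.name for f in fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {cls.__name__}: {sorted(unknown)}")
    return cls(**mapping)


def config_from_mapping(mapping: Mapping[str, Any] | None) -> PipelineConfig:
    """Build a PipelineConfig from a (possibly nested) mapping, strictly."""
    if mapping is None:
        return PipelineConfig()
    allowed = {f.name for f in fields(PipelineConfig)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in mapping.items():
        if key in _SECTION_TYPES:
            kwargs[key] = _build_section(_SECTION_TYPES[key], value or {})
        elif key == "bands":
            kwargs[key] = {name: tuple(map(float, edges)) for name, edges in value.items()}
        elif key == "lambda_grid":
            kwargs[key] = parse_grid(value) if isinstance(value, str) else tuple(
                float(v) for v in value
            )
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file; ``None`` yields the defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        return config_from_mapping(yaml.safe_load(fh))


def parse_grid(text: str) -> tuple[float, ...]:
    """Parse a lambda grid: ``start:step:stop`` (inclusive) or comma list."""
    if ":" in text:
        parts = [float(p) for p in text.split(":")]
        if len(parts) != 3:
            raise ValueError(f"invalid weight grid: {text!r}")
        start, step, stop = parts
        if step <= 0:
            raise ValueError(f"invalid weight grid: step must be positive")
        k = int(round((stop - start) / step))
        grid = tuple(round(start + i * step, 12) for i in range(k + 1))
        if grid and grid[-1] > stop + 1e-12:
            grid = grid[:-1]
        return grid
    return tuple(float(p) for p in text.split(","))


def parse_synth_spec(path: str | Path, seed: int | None = None):
    """Load a SynthSpec from YAML.

    Recognized keys: n_subjects, fs, segment_s, broadband_noise_sd,
    amplitude_jitter_sd, seed, and per-band tables ``amplitude`` /
    ``complexity_mix`` given either flat (band -> value) or nested
    (condition -> band -> channel -> value).
    """
    from .synthdata import SynthSpec, _full_table

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = {
        "n_subjects", "fs", "segment_s", "broadband_noise_sd",
        "amplitude_jitter_sd", "seed", "amplitude", "complexity_mix",
    }
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in synth spec: {sorted(unknown)}")

    def _table(value, default):
        if value is None:
            return default
        if all(not isinstance(v, dict) for v in value.values()):
            return _full_table({k: float(v) for k, v in value.items()})
        table = dict(default)
        for cond, bands in value.items():
            for band, chans in bands.items():
                for ch, v in chans.items():
                    table[(cond, band, ch)] = float(v)
        return table

    base = SynthSpec()
    spec = SynthSpec(
        n_subjects=raw.get("n_subjects", base.n_subjects),
        fs=raw.get("fs", base.fs),
        segment_s=raw.get("segment_s", base.segment_s),
        amplitude=_table(raw.get("amplitude"), base.amplitude),
        complexity_mix=_table(raw.get("complexity_mix"), base.complexity_mix),
        broadband_noise_sd=raw.get("broadband_noise_sd", base.broadband_noise_sd),
        amplitude_jitter_sd=raw.get("amplitude_jitter_sd", base.amplitude_jitter_sd),
        seed=raw.get("seed", base.seed) if seed is None else seed,
    )
    return spec
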