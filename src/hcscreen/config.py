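"""Run configuration: a single YAML file driving the end-to-end pipeline.

Defaults encode the screen's standard analysis settings — PM ring width
2 px, perinuclear ring width 5 px, 9 fields per well, hit threshold
k = 3 SD — plus the package's own choices (viability floor 0.1, Otsu
"auto" thresholds).  Unknown keys and
invalid values are rejected at load time with one error message listing
every offending field, and a loaded config round-trips through
:func:`save_config` unchanged.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields as dc_fields, is_dataclass
from pathlib import Path

import yaml

from .errors import ConfigError

_METRICS = ("chebyshev", "manhattan")


def _threshold(value):
    if value == "auto":
        return "auto"
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError("must be a number or 'auto'") from None


@dataclass
class AnalysisConfig:
    """Analysis-stage parameters shared by both arms."""

    nuclear_threshold: float | str = "auto"
    cyto_threshold: float | str = "auto"
    pm_width: int = 2
    perinuclear_width: int = 5
    min_nucleus_area: int = 10
    metric: str = "chebyshev"
    fields_per_well: int = 9
    viability_floor: float = 0.1
    k: float = 3.0

    def validate(self, errors: list[str], prefix: str = "analysis") -> None:
        for name in ("nuclear_threshold", "cyto_threshold"):
            try:
                setattr(self, name, _threshold(getattr(self, name)))
            except ValueError as exc:
                errors.append(f"{prefix}.{name}: {exc}")
        for name in ("pm_width", "perinuclear_width", "min_nucleus_area", "fields_per_well"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                errors.append(f"{prefix}.{name}: must be a positive integer, got {v!r}")
        if self.metric not in _METRICS:
            errors.append(f"{prefix}.metric: must be one of {_METRICS}, got {self.metric!r}")
        if not isinstance(self.viability_floor, (int, float)) or self.viability_floor < 0:
            errors.append(f"{prefix}.viability_floor: must be >= 0, got {self.viability_floor!r}")
        if not isinstance(self.k, (int, float)) or self.k <= 0:
            errors.append(f"{prefix}.k: must be > 0, got {self.k!r}")


@dataclass
class PlateSimConfig:
    """Plate-arm simulation block (the default pipeline input source)."""

    enabled: bool = True
    n_plates: int = 2
    plate_format: int = 384
    mu_cell_control: float = 2.0e5
    mu_positive: float = 6.0e5
    mu_viability_control: float = 4.0e5
    mu_viable: float = 4.0e6
    stain_dead_fraction: float = 0.1
    cv: float = 0.05
    hits: dict = field(default_factory=dict)

    def validate(self, errors: list[str], prefix: str = "plate_sim") -> None:
        if not isinstance(self.n_plates, int) or self.n_plates < 1:
            errors.append(f"{prefix}.n_plates: must be a positive integer, got {self.n_plates!r}")
        if self.plate_format not in (96, 384):
            errors.append(f"{prefix}.plate_format: must be 96 or 384, got {self.plate_format!r}")
        if not isinstance(self.cv, (int, float)) or self.cv < 0:
            errors.append(f"{prefix}.cv: must be >= 0, got {self.cv!r}")
        for name in ("mu_cell_control", "mu_positive", "mu_viability_control", "mu_viable"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or v <= 0:
                errors.append(f"{prefix}.{name}: must be > 0, got {v!r}")
        if not isinstance(self.hits, dict):
            errors.append(f"{prefix}.hits: must be a mapping compound_id -> multiplier")
        else:
            for cid, m in self.hits.items():
                if not isinstance(m, (int, float)) or m <= 0:
                    errors.append(f"{prefix}.hits[{cid}]: multiplier must be > 0, got {m!r}")


@dataclass
class ImageSimConfig:
    """Imaging-arm simulation block (off by default; a desk-scale demo)."""

    enabled: bool = False
    n_wells: int = 24
    field_shape: tuple[int, int] = (128, 128)
    n_cells: int = 8
    nucleus_radius: float = 4.0
    cell_radius: float = 12.0
    noise_sd: float = 10.0
    positive_multiplier: float = 3.0
    hits: dict = field(default_factory=dict)
    write_tiffs: bool = False

    def validate(self, errors: list[str], prefix: str = "image_sim") -> None:
        if not isinstance(self.n_wells, int) or self.n_wells < 1:
            errors.append(f"{prefix}.n_wells: must be a positive integer, got {self.n_wells!r}")
        shape = tuple(self.field_shape) if isinstance(self.field_shape, (list, tuple)) else None
        if shape is None or len(shape) != 2 or any(not isinstance(s, int) or s < 16 for s in shape):
            errors.append(f"{prefix}.field_shape: must be two integers >= 16, got "
                          f"{self.field_shape!r}")
        else:
            self.field_shape = shape
        if not isinstance(self.n_cells, int) or self.n_cells < 1:
            errors.append(f"{prefix}.n_cells: must be a positive integer, got {self.n_cells!r}")
        if self.cell_radius <= self.nucleus_radius or self.nucleus_radius <= 0:
            errors.append(f"{prefix}: need cell_radius > nucleus_radius > 0")
        if not isinstance(self.noise_sd, (int, float)) or self.noise_sd < 0:
            errors.append(f"{prefix}.noise_sd: must be >= 0, got {self.noise_sd!r}")
        if not isinstance(self.positive_multiplier, (int, float)) or self.positive_multiplier <= 0:
            errors.append(f"{prefix}.positive_multiplier: must be > 0")
        if isinstance(self.hits, dict):
            for cid, m in self.hits.items():
                if not isinstance(m, (int, float)) or m <= 0:
                    errors.append(f"{prefix}.hits[{cid}]: multiplier must be > 0, got {m!r}")
        else:
            errors.append(f"{prefix}.hits: must be a mapping compound_id -> multiplier")


@dataclass
class RunConfig:
    """Top-level pipeline configuration."""

    seed: int = 0
    out_dir: str = "hcscreen_run"
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    plate_sim: PlateSimConfig = field(default_factory=PlateSimConfig)
    image_sim: ImageSimConfig = field(default_factory=ImageSimConfig)

    def validate(self) -> None:
        errors: list[str] = []
        if not isinstance(self.seed, int):
            errors.append(f"seed: must be an integer, got {self.seed!r}")
        self.analysis.validate(errors)
        self.plate_sim.validate(errors)
        self.image_sim.validate(errors)
        if errors:
            raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))

    def to_dict(self) -> dict:
        def conv(obj):
            if is_dataclass(obj):
                return {f.name: conv(getattr(obj, f.name)) for f in dc_fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return conv(self)

    def config_hash(self) -> str:
        """Stable hash of the normalized configuration, logged for reproducibility."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


_SECTIONS = {"analysis": AnalysisConfig, "plate_sim": PlateSimConfig, "image_sim": ImageSimConfig}


def _build_section(cls, data: dict, prefix: str, errors: list[str]):
    known = {f.name for f in dc_fields(cls)}
    unknown = set(data) - known
    if unknown:
        errors.append(f"{prefix}: unknown keys {sorted(unknown)}")
    return cls(**{k: v for k, v in data.items() if k in known})


def config_from_dict(data: dict | None) -> RunConfig:
    """Build and validate a RunConfig from a plain mapping (parsed YAML)."""
    data = dict(data or {})
    errors: list[str] = []
    kwargs: dict = {}
    top_known = {"seed", "out_dir"} | set(_SECTIONS)
    unknown = set(data) - top_known
    if unknown:
        errors.append(f"top level: unknown keys {sorted(unknown)}")
    for key in ("seed", "out_dir"):
        if key in data:
            kwargs[key] = data[key]
    for key, cls in _SECTIONS.items():
        section = data.get(key, {})
        if section is None:
            section = {}
        if not isinstance(section, dict):
            errors.append(f"{key}: must be a mapping")
            section = {}
        kwargs[key] = _build_section(cls, section, key, errors)
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields all defaults.  Unknown keys or invalid values
    raise :class:`ConfigError` listing each offending field.
    """
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    data = yaml.safe_load(p.read_text())
    if data is not None and not isinstance(data, dict):
        raise ConfigError(f"{p}: top level must be a mapping")
    return config_from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config as YAML; ``load_config`` of the result is identical."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
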