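"""Structured run configuration with validation and documented defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "SimulateConfig", "PreprocessConfig", "SearchConfig",
           "AnnotateConfig", "AnalyzeConfig", "validate_config", "load_config",
           "ConfigError"]


class ConfigError(ValueError):
    """Raised with the full list of configuration violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


@dataclass
class SimulateConfig:
    n_compounds: int = 100
    n_pathways: int = 10
    cross_link_prob: float = 0.15
    decoy_fraction: float = 0.0
    xenobiotic_fraction: float = 0.05
    rho: float = 0.6
    affected_set: str | None = None
    effect_multiplier: float = 0.5
    n_noise_peaks: int = 9000
    fragment_fraction: float = 0.1
    fragment_multiple: float = 0.5
    calibration_ppm: float = 0.0


@dataclass
class PreprocessConfig:
    reference_mz: float = 423.169
    recal_window: float = 0.05
    window: float = 50.0
    rank: int = 150
    tolerance: float = 0.005
    min_samples: int = 9


@dataclass
class SearchConfig:
    tolerance: float = 0.005


@dataclass
class AnnotateConfig:
    k: int = 30
    derivative_r: float = 0.85
    n_rand: int = 300
    iterations: int = 6
    accept_q: float = 0.95
    z_cut: float = -1.64
    min_pairs: int = 9
    count_mode: str = "cumulative"
    null_mode: str = "features"
    dedup_context: bool = True
    exclude: list[str] = field(default_factory=list)  # currency-metabolite ids


@dataclass
class AnalyzeConfig:
    alpha: float = 0.01
    control_group: str = "normal"
    adjust: str = "fdr_bh"


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "run"
    manifest: str | None = None   # existing cohort to load instead of simulating
    compounds: str | None = None
    reactions: str | None = None
    sets: str | None = None
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)
    analyze: AnalyzeConfig = field(default_factory=AnalyzeConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {"simulate": SimulateConfig, "preprocess": PreprocessConfig,
             "search": SearchConfig, "annotate": AnnotateConfig,
             "analyze": AnalyzeConfig}


def validate_config(raw: dict | RunConfig) -> RunConfig:
    """Build a validated RunConfig; omitted fields take the documented defaults.

    All violations are reported at once via :class:`ConfigError`.
    """
    errors: list[str] = []
    if isinstance(raw, RunConfig):
        cfg = raw
    else:
        raw = dict(raw or {})
        kwargs = {}
        top_fields = {f.name for f in fields(RunConfig)}
        for key in raw:
            if key not in top_fields:
                errors.append(f"unknown configuration key: {key}")
        for name, cls in _SECTIONS.items():
            section = dict(raw.get(name) or {})
            known = {f.name for f in fields(cls)}
            for key in section:
                if key not in known:
                    errors.append(f"{name}: unknown key {key}")
            kwargs[name] = cls(**{k: v for k, v in section.items() if k in known})
        for key in ("seed", "outdir", "manifest", "compounds", "reactions", "sets"):
            if key in raw:
                kwargs[key] = raw[key]
        cfg = RunConfig(**kwargs)

    s, p, q, a, z = cfg.simulate, cfg.preprocess, cfg.search, cfg.annotate, cfg.analyze
    checks = [
        (s.n_compounds >= 2 * s.n_pathways, "simulate: n_compounds must be >= 2*n_pathways"),
        (0 <= s.decoy_fraction < 1, "simulate: decoy_fraction must be in [0, 1)"),
        (0 <= s.xenobiotic_fraction <= 1, "simulate: xenobiotic_fraction must be in [0, 1]"),
        (0 <= s.rho < 1, "simulate: rho must be in [0, 1)"),
        (0 < s.effect_multiplier <= 1, "simulate: effect_multiplier must be in (0, 1]"),
        (s.n_noise_peaks >= 0, "simulate: n_noise_peaks must be >= 0"),
        (p.tolerance > 0, "preprocess: tolerance must be > 0"),
        (p.window > 0, "preprocess: window must be > 0"),
        (p.rank >= 1, "preprocess: rank must be >= 1"),
        (p.recal_window > 0, "preprocess: recal_window must be > 0"),
        (p.min_samples >= 0, "preprocess: min_samples must be >= 0"),
        (q.tolerance > 0, "search: tolerance must be > 0"),
        (a.k >= 1, "annotate: k must be >= 1"),
        (0 < a.derivative_r <= 1, "annotate: derivative_r must be in (0, 1]"),
        (a.n_rand >= 1, "annotate: n_rand must be >= 1"),
        (a.iterations >= 1, "annotate: iterations must be >= 1"),
        (0 < a.accept_q < 1, "annotate: accept_q must be in (0, 1)"),
        (a.z_cut < 0, "annotate: z_cut must be negative"),
        (a.min_pairs >= 2, "annotate: min_pairs must be >= 2"),
        (a.count_mode in ("cumulative", "exact"),
         "annotate: count_mode must be 'cumulative' or 'exact'"),
        (a.null_mode in ("features", "compounds"),
         "annotate: null_mode must be 'features' or 'compounds'"),
        (0 < z.alpha < 1, "analyze: alpha must be in (0, 1)"),
        (z.adjust in ("fdr_bh", "holm"), "analyze: adjust must be 'fdr_bh' or 'holm'"),
    ]
    errors.extend(msg for ok, msg in checks if not ok)
    if errors:
        raise ConfigError(errors)
    return cfg


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(raw)
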