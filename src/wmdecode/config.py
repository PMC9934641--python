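"""TOML run configuration.

One structured file controls a full pipeline run; sections mirror the
module configs::

    [session]    -> wmdecode.synth.SessionConfig
    [signal]     -> wmdecode.synth.SignalModel
    [cohort]     n_subjects, seed, age_effect, age_range_months
    [preprocess] -> wmdecode.preprocess.PreprocConfig
    [decode]     -> wmdecode.decode.CvScheme (+ bin_width_ms, windows)
    [stats]      n_permutations, permutation_cv_iterations, correction

Unknown keys and invalid values raise ConfigurationError naming the
offending key path.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .decode import CvScheme
from .exceptions import ConfigurationError
from .preprocess import PreprocConfig
from .synth import SessionConfig, SignalModel

__all__ = ["RunConfig", "load_config", "smoke_config_path"]


def smoke_config_path() -> Path:
    """Path of the bundled minimal smoke-run configuration."""
    return Path(__file__).parent / "configs" / "smoke.toml"


@dataclass
class RunConfig:
    session: SessionConfig = field(default_factory=SessionConfig)
    signal: SignalModel = field(default_factory=SignalModel)
    preprocess: PreprocConfig = field(default_factory=PreprocConfig)
    cv: CvScheme = field(default_factory=CvScheme)
    n_subjects: int = 20
    seed: int = 0
    age_effect: float = 0.0
    age_range_months: tuple[int, int] = (84, 152)
    bin_width_ms: float = 50.0
    run_tempgen: bool = False
    n_permutations: int = 0
    permutation_cv_iterations: int = 10
    correction: str = "bonferroni"


def _build(cls, section: dict, path: str):
    """Instantiate a (frozen) dataclass from a TOML table with key checking."""
    names = {f.name for f in dataclasses.fields(cls)}
    clean = {}
    for key, value in section.items():
        if key not in names:
            raise ConfigurationError(f"[{path}] {key}: unknown key")
        if isinstance(value, list):
            value = tuple(value)
        clean[key] = value
    try:
        return cls(**clean)
    except ConfigurationError as err:
        raise ConfigurationError(f"[{path}] {err}") from err
    except (TypeError, ValueError) as err:
        raise ConfigurationError(f"[{path}] invalid value: {err}") from err


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run configuration."""
    raw = tomllib.loads(Path(path).read_text())
    known = {"session", "signal", "preprocess", "decode", "cohort", "stats"}
    for key in raw:
        if key not in known:
            raise ConfigurationError(f"[{key}]: unknown section")

    cfg = RunConfig()
    if "session" in raw:
        cfg.session = _build(SessionConfig, raw["session"], "session")
    if "signal" in raw:
        cfg.signal = _build(SignalModel, raw["signal"], "signal")
    if "preprocess" in raw:
        cfg.preprocess = _build(PreprocConfig, raw["preprocess"], "preprocess")

    decode_sec = dict(raw.get("decode", {}))
    cfg.bin_width_ms = float(decode_sec.pop("bin_width_ms", cfg.bin_width_ms))
    cfg.run_tempgen = bool(decode_sec.pop("run_tempgen", cfg.run_tempgen))
    cfg.cv = _build(CvScheme, decode_sec, "decode")

    cohort = raw.get("cohort", {})
    for key in cohort:
        if key not in {"n_subjects", "seed", "age_effect", "age_range_months"}:
            raise ConfigurationError(f"[cohort] {key}: unknown key")
    cfg.n_subjects = int(cohort.get("n_subjects", cfg.n_subjects))
    if cfg.n_subjects < 1:
        raise ConfigurationError("[cohort] n_subjects: must be >= 1")
    cfg.seed = int(cohort.get("seed", cfg.seed))
    cfg.age_effect = float(cohort.get("age_effect", cfg.age_effect))
    cfg.age_range_months = tuple(cohort.get("age_range_months", cfg.age_range_months))

    stats_sec = raw.get("stats", {})
    for key in stats_sec:
        if key not in {"n_permutations", "permutation_cv_iterations", "correction"}:
            raise ConfigurationError(f"[stats] {key}: unknown key")
    cfg.n_permutations = int(stats_sec.get("n_permutations", cfg.n_permutations))
    cfg.permutation_cv_iterations = int(
        stats_sec.get("permutation_cv_iterations", cfg.permutation_cv_iterations)
    )
    cfg.correction = str(stats_sec.get("correction", cfg.correction))
    if cfg.correction not in {"bonferroni", "none"}:
        raise ConfigurationError("[stats] correction: must be 'bonferroni' or 'none'")
    return cfg
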