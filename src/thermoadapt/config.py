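"""Run configuration and reproducible random-number substreams.

A run is controlled by a single :class:`RunConfig` (usually loaded from a
YAML file).  Each analysis stage owns a parameter block with defaults, so an
empty file is a valid configuration.  Unknown keys anywhere in the file are
rejected with a :class:`~thermoadapt.errors.ConfigError` naming the key.

Randomness policy: one global ``seed``; every stage derives its own
independent substream deterministically from ``(seed, stage_name)`` via
:func:`substream`, so stages are reproducible in isolation and reordering
stages never changes their draws.
"""

from __future__ import annotations

import logging
import zlib
from enum import Enum
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError

log = logging.getLogger("thermoadapt")


class Verbosity(str, Enum):
    quiet = "quiet"
    info = "info"
    debug = "debug"


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SurvivalSimParams(_Block):
    """Parameters of the synthetic survival-experiment generator."""

    baseline_logit: float = 1.0
    sigma_family: float = Field(0.5, ge=0)
    sigma_obs: float = Field(0.3, ge=0)


class MitoSimParams(_Block):
    """Parameters of the synthetic mitochondrial pool-seq generator."""

    mean_coverage_pool: int = Field(3000, ge=1)
    mean_coverage_individual: int = Field(200, ge=1)
    error_rate: float = Field(0.001, ge=0, le=0.01)


class GLMMParams(_Block):
    """Binomial mixed-model fitting options."""

    dispersion_threshold: float = Field(1.4, gt=0)
    gh_points: int = Field(25, ge=5)


class MetaParams(_Block):
    """Multilevel meta-analysis options."""

    tau_tol: float = Field(1e-10, gt=0)


class DominanceParams(_Block):
    """Dominance-estimation options."""

    n_boot: int = Field(10_000, ge=100)
    weighted_slopes: bool = True


class SweepParams(_Block):
    """Selection-sweep simulation options."""

    s: float = Field(0.3, ge=0)
    h: float = Field(0.1, ge=0, le=1)
    N: int = Field(1_000_000, ge=1)
    generations: int = Field(100, ge=0)
    target_freq: float = Field(0.5, gt=0, le=1)
    n_replicates: int = Field(100, ge=1)


class MitotypeParams(_Block):
    """SNP-calling and mitotype-definition thresholds."""

    min_alt_fraction: float = Field(0.8, gt=0.5, le=1)
    min_coverage: int = Field(20, ge=1)
    per_year_envelope: bool = True


class RunConfig(_Block):
    seed: int = Field(0, ge=0)
    output_dir: Path = Path("thermoadapt_out")
    verbosity: Verbosity = Verbosity.info

    survival_sim: SurvivalSimParams = SurvivalSimParams()
    mito_sim: MitoSimParams = MitoSimParams()
    glmm: GLMMParams = GLMMParams()
    meta: MetaParams = MetaParams()
    dominance: DominanceParams = DominanceParams()
    sweep: SweepParams = SweepParams()
    mitotypes: MitotypeParams = MitotypeParams()


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def substream(seed: int, stage: str) -> np.random.Generator:
    """Independent, deterministic random stream for one stage.

    The stage name is hashed with CRC-32 so the pair ``(seed, stage)`` maps
    to a distinct :class:`numpy.random.SeedSequence` regardless of call
    order.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode("utf-8"))])
    )


def configure_logging(verbosity: Verbosity = Verbosity.info) -> None:
    level = {
        Verbosity.quiet: logging.WARNING,
        Verbosity.info: logging.INFO,
        Verbosity.debug: logging.DEBUG,
    }[verbosity]
    logging.basicConfig(level=level, format="%(message)s")
    log.setLevel(level)


def log_kv(event: str, **fields) -> None:
    """Emit one machine-parsable ``key=value`` log line."""
    parts = [f"event={event}"] + [
        f"{k}={v:.6g}" if isinstance(v, float) else f"{k}={v}" for k, v in fields.items()
    ]
    log.info(" ".join(parts))
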