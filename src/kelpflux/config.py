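"""Plain-text configuration for pipeline runs.

The configuration file is dotted ``key = value`` lines; ``#`` starts a
comment.  Keys are grouped by prefix into the stage they configure::

    run.total_particles = 20000
    run.seed            = 7
    scenario.pulse_speed = 0.15
    tracker.dt           = 1800
    decay.k              = 0.075
    carbon.fw_to_dw      = 0.20

Every field of :class:`~kelpflux.scenario.ShelfScenarioConfig`,
:class:`~kelpflux.tracker.TrackerOptions`,
:class:`~kelpflux.dswt.DSWTConstants`,
:class:`~kelpflux.export.DecayModel` and
:class:`~kelpflux.carbon.CarbonParams` can be overridden this way.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

from .carbon import CarbonParams
from .dswt import DSWTConstants
from .export import DecayModel
from .scenario import ShelfScenarioConfig
from .tracker import TrackerOptions

__all__ = ["RunConfig", "parse_config_file"]


def _parse_value(raw: str):
    raw = raw.strip()
    try:
        return ast.literal_eval(raw)
    except (ValueError, SyntaxError):
        return raw


def parse_config_file(path) -> dict[str, object]:
    """Read dotted key/value pairs; raises on malformed lines."""
    out: dict[str, object] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, raw = line.partition("=")
        out[key.strip()] = _parse_value(raw)
    return out


def _build(cls, prefix: str, flat: dict[str, object]):
    names = {f.name for f in dc_fields(cls)}
    kwargs = {}
    for key, value in flat.items():
        if not key.startswith(prefix + "."):
            continue
        name = key[len(prefix) + 1:]
        if name not in names:
            raise ValueError(f"unknown option {key!r}")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


@dataclass
class RunConfig:
    """Everything a full pipeline run needs."""

    scenario: ShelfScenarioConfig = field(default_factory=ShelfScenarioConfig)
    # the synthetic scenario is an idealised alongshore channel, so the
    # default tracker wraps the alongshore axis
    tracker: TrackerOptions = field(
        default_factory=lambda: TrackerOptions(periodic_y=True))
    constants: DSWTConstants = field(default_factory=DSWTConstants)
    decay: DecayModel = field(default_factory=DecayModel)
    carbon: CarbonParams = field(default_factory=CarbonParams)
    fields_path: str | None = None   # load forcing instead of generating it
    total_particles: int = 10_000
    seed: int = 0
    year: int = 2017
    levels: tuple[float, ...] = (200.0, 400.0, 600.0, 800.0, 1000.0)
    write_fields: bool = False
    write_trajectories: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        flat = parse_config_file(path)
        flat.update(overrides)
        run_fields = {"fields_path", "total_particles", "seed", "year",
                      "levels", "write_fields", "write_trajectories",
                      "log_level"}
        kwargs = {}
        for key, value in flat.items():
            if key.startswith("run."):
                name = key[4:]
                if name not in run_fields:
                    raise ValueError(f"unknown option {key!r}")
                kwargs[name] = tuple(value) if isinstance(value, list) else value
        for key in flat:
            head = key.split(".", 1)[0]
            if head not in {"run", "scenario", "tracker", "dswt", "decay", "carbon"}:
                raise ValueError(f"unknown configuration section {head!r}")
        return cls(
            scenario=_build(ShelfScenarioConfig, "scenario", flat),
            tracker=_build(TrackerOptions, "tracker", flat),
            constants=_build(DSWTConstants, "dswt", flat),
            decay=_build(DecayModel, "decay", flat),
            carbon=_build(CarbonParams, "carbon", flat),
            **kwargs,
        )
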