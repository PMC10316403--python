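"""Flat key-value run configuration files.

Dialect: one ``key = value`` pair per line; ``#`` starts a comment; blank
lines ignored.  Keys are the fields of :class:`hydropore.engine.RunConfig`
plus the model parameters of :class:`hydropore.energetics.ModelParams`
(prefixed forms are not needed: all key names are globally unique).  Unknown
keys are rejected with an error naming the key; missing keys take the
documented defaults, which reproduce the standard setup (L = 40, N_R = 36,
J = 0.3, J_sigma = 0.05, v_HB = 0.5, dJ_phi/J = 0.83, q = 6, 10^6 steps,
10^4 equilibration, sampling every 100).
"""

from __future__ import annotations

import dataclasses

from .energetics import ModelParams
from .engine import RunConfig

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}

_RUN_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}
_MODEL_FIELDS = {f.name: f for f in dataclasses.fields(ModelParams)}


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _convert(key: str, raw: str, typ):
    raw = raw.strip()
    try:
        if typ is bool:
            if raw.lower() not in _BOOL:
                raise ValueError
            return _BOOL[raw.lower()]
        if typ is int:
            return int(raw)
        if typ is float:
            return float(raw)
        if typ is str:
            return raw
        if typ is tuple:
            return tuple(float(v) for v in raw.replace(",", " ").split())
    except ValueError as exc:
        raise ConfigError(f"config key {key!r}: cannot parse {raw!r} as {typ.__name__}") from exc
    return raw


def parse_config(text: str) -> tuple[RunConfig, ModelParams]:
    """Parse flat key-value text into a validated (RunConfig, ModelParams) pair."""
    run_kwargs = {}
    model_kwargs = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, raw = (part.strip() for part in line.split("=", 1))
        if key in _RUN_FIELDS:
            f = _RUN_FIELDS[key]
            typ = type(f.default) if f.default is not dataclasses.MISSING else str
            run_kwargs[key] = _convert(key, raw, typ)
        elif key in _MODEL_FIELDS:
            f = _MODEL_FIELDS[key]
            typ = type(f.default)
            model_kwargs[key] = _convert(key, raw, typ)
        else:
            raise ConfigError(f"line {lineno}: unknown config key {key!r}")
    try:
        run = RunConfig(**run_kwargs)
        model = ModelParams(**model_kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return run, model


def load_config(path) -> tuple[RunConfig, ModelParams]:
    """Load and validate a config file; missing keys take the standard defaults."""
    with open(path) as fh:
        return parse_config(fh.read())


def format_config(run: RunConfig, model: ModelParams) -> str:
    """Serialize a configuration back to the flat dialect (round-trips)."""
    lines = []
    for f in dataclasses.fields(RunConfig):
        v = getattr(run, f.name)
        if isinstance(v, tuple):
            v = " ".join(repr(x) for x in v)
        lines.append(f"{f.name} = {v}")
    for f in dataclasses.fields(ModelParams):
        lines.append(f"{f.name} = {getattr(model, f.name)}")
    return "\n".join(lines) + "\n"
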