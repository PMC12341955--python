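"""Run configuration and reproducibility manifests.

A run is declared in a small YAML (or JSON) file with optional sections;
every omitted field falls back to the package default (nominal parameters,
W12/C12 37±1.5 degC, 200 cells, seed 0).  Validation is strict: unknown keys
are rejected by name, and every problem found is reported, not just the
first.

A manifest records the canonical configuration, its hash, the seed and the
output files with their hashes, so a finished run can be replayed and checked
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError
from .params import PARAM_NAMES, ModelParameters
from .population import IndividualSpec, PopulationSpec
from .schedules import Schedule, TemperaturePattern, ass_protocol, validation_protocol

__all__ = ["RunConfig", "load_config", "write_manifest", "check_manifest"]

_SCHEDULE_KINDS = ("rhythmic", "constant", "validation", "ass", "blocks")


@dataclass
class RunConfig:
    """Validated configuration for any experiment run."""

    params: dict = field(default_factory=dict)        # overrides of Table-1 names
    schedule: dict = field(default_factory=dict)      # see build_schedule
    population: dict = field(default_factory=dict)    # PopulationSpec fields
    individuals: dict = field(default_factory=dict)   # IndividualSpec fields
    solver: dict = field(default_factory=dict)        # dt, record_every, rtol, atol
    metrics: dict = field(default_factory=dict)       # burn_in, window_h, reference
    seed: int = 0
    out_dir: str = "runs"

    # -- builders ----------------------------------------------------------
    def model_parameters(self) -> ModelParameters:
        return ModelParameters().replace(**{k: float(v)
                                            for k, v in self.params.items()})

    def population_spec(self) -> PopulationSpec:
        d = dict(self.population)
        d.setdefault("seed", self.seed)
        if "varied" in d:
            d["varied"] = tuple(d["varied"])
        return PopulationSpec(**d)

    def individual_spec(self) -> IndividualSpec:
        d = dict(self.individuals)
        d.setdefault("seed", self.seed)
        if "fold_range" in d:
            d["fold_range"] = tuple(d["fold_range"])
        return IndividualSpec(**d)

    def build_schedule(self) -> Schedule:
        d = dict(self.schedule) or {"kind": "rhythmic"}
        kind = d.pop("kind", "rhythmic")
        if kind == "rhythmic":
            pat = TemperaturePattern(
                mean=d.pop("mean", 37.0), amplitude=d.pop("amplitude", 3.0),
                period=d.pop("period", 24.0),
                reversed_=d.pop("orientation", "normal") == "reversed")
            return Schedule.rhythmic(pat, t_end=d.pop("days", 70.0) * 24.0)
        if kind == "constant":
            return Schedule.constant(d.pop("temperature", 37.0),
                                     d.pop("days", 70.0) * 24.0)
        if kind == "validation":
            return validation_protocol(
                amplitude=d.pop("amplitude", 3.0), mean=d.pop("mean", 37.0),
                reversed_=d.pop("orientation", "normal") == "reversed",
                const_until_day=d.pop("const_until_day", 10.0),
                rhythmic_until_day=d.pop("rhythmic_until_day", 65.0),
                end_day=d.pop("end_day", 90.0))
        if kind == "ass":
            rev_amp = d.pop("reversed_amplitude", None)
            pat = TemperaturePattern(mean=d.pop("mean", 37.0),
                                     amplitude=d.pop("amplitude", 3.0))
            rev = (TemperaturePattern(mean=pat.mean, amplitude=rev_amp,
                                      reversed_=True)
                   if rev_amp is not None else None)
            return ass_protocol(d.pop("spec"), pre_days=d.pop("pre_days", 50.0),
                                post_days=d.pop("post_days", 100.0),
                                pattern=pat, reversed_pattern=rev)
        if kind == "blocks":
            return Schedule.from_list(d.pop("blocks"))
        raise ConfigError([f"unknown schedule kind {kind!r}; expected one of "
                           f"{_SCHEDULE_KINDS}"])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTION_KEYS = {
    "population": {"n_cells", "varied", "rel_width", "seed"},
    "individuals": {"n_subjects", "fold_range", "seed"},
    "solver": {"dt", "record_every", "rtol", "atol", "dt_out"},
    "metrics": {"burn_in", "window_h", "step_h", "reference",
                "prominence_frac"},
    "schedule": {"kind", "mean", "amplitude", "period", "orientation", "days",
                 "temperature", "const_until_day", "rhythmic_until_day",
                 "end_day", "spec", "pre_days", "post_days",
                 "reversed_amplitude", "blocks"},
}


def _validate(raw: dict) -> list[str]:
    problems = []
    top = {"params", "schedule", "population", "individuals", "solver",
           "metrics", "seed", "out_dir"}
    for k in sorted(set(raw) - top):
        problems.append(f"unknown top-level key: {k}")
    for k, v in raw.get("params", {}).items():
        if k not in PARAM_NAMES:
            problems.append(f"unknown parameter key: params.{k}")
        else:
            try:
                fv = float(v)
            except (TypeError, ValueError):
                problems.append(f"params.{k} is not a number: {v!r}")
                continue
            if fv < 0:
                problems.append(f"params.{k} must be >= 0, got {fv}")
            if k in ("n", "p", "q", "r") and fv < 1:
                problems.append(f"params.{k} is a Hill exponent and must be "
                                f">= 1, got {fv}")
    for section, allowed in _SECTION_KEYS.items():
        for k in sorted(set(raw.get(section, {})) - allowed):
            problems.append(f"unknown key: {section}.{k}")
    if "seed" in raw and not isinstance(raw["seed"], int):
        problems.append(f"seed must be an integer, got {raw['seed']!r}")
    return problems


def load_config(path) -> RunConfig:
    """Load and strictly validate a YAML/JSON run configuration.

    An empty file yields the all-defaults configuration.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    text = path.read_text()
    if path.suffix in (".yml", ".yaml") or not text.lstrip().startswith("{"):
        import yaml

        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as e:
            raise ConfigError([f"cannot parse {path}: {e}"]) from e
    else:
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as e:
            raise ConfigError([f"cannot parse {path}: {e}"]) from e
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError([f"{path}: expected a mapping at top level"])
    problems = _validate(raw)
    if problems:
        raise ConfigError(problems)
    cfg = RunConfig(**{k: raw.get(k, getattr(RunConfig(), k))
                       for k in ("params", "schedule", "population",
                                 "individuals", "solver", "metrics", "seed",
                                 "out_dir")})
    cfg.model_parameters()   # surfaces invalid parameter combinations early
    return cfg


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def _canonical(config: RunConfig) -> str:
    # repr-based float serialization round-trips exactly (17 significant digits)
    return json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(config: RunConfig, seed: int, outputs, path) -> dict:
    """Write a JSON run manifest: canonical config + hash, seed, and the
    output files with their SHA-256 hashes."""
    path = Path(path)
    outputs = [Path(o) for o in outputs]
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(_canonical(config).encode()).hexdigest(),
        "seed": int(seed),
        "solver": {"dt": config.solver.get("dt", 0.05),
                   "record_every": config.solver.get("record_every", 5),
                   "rtol": config.solver.get("rtol", 1e-8),
                   "atol": config.solver.get("atol", 1e-10)},
        "outputs": [{"path": str(o), "sha256": _sha256_file(o)}
                    for o in outputs],
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=1))
    return manifest


def check_manifest(path) -> dict:
    """Verify a manifest: recompute the config hash and every output hash.

    Returns ``{"config_ok": bool, "outputs": {path: bool}}``; a tampered
    config or changed output is reported as False.
    """
    path = Path(path)
    manifest = json.loads(path.read_text())
    cfg = RunConfig(**manifest["config"])
    config_ok = (hashlib.sha256(_canonical(cfg).encode()).hexdigest()
                 == manifest["config_sha256"])
    outputs = {}
    for item in manifest["outputs"]:
        p = Path(item["path"])
        outputs[str(p)] = p.exists() and _sha256_file(p) == item["sha256"]
    return {"config_ok": config_ok, "outputs": outputs}
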