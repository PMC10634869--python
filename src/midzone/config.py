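"""Pipeline configuration and orchestration.

A pipeline is a YAML document with a seed, an output directory and an
ordered list of stages; unknown keys anywhere are rejected before any
computation so a typo cannot silently change an analysis.  Outputs are
written with fixed numeric formats so a rerun with the same configuration
and seed is byte-identical.
"""

from __future__ import annotations

import inspect
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError, MissingInputError, StageError

log = logging.getLogger("midzone")

_TOP_KEYS = {"seed", "outdir", "log_level", "stages"}


@dataclass(frozen=True)
class StageSpec:
    name: str
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    outdir: str = "midzone_out"
    log_level: str = "INFO"
    stages: tuple[StageSpec, ...] = ()

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        unknown = set(obj) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        stages = []
        for i, st in enumerate(obj.get("stages", [])):
            if not isinstance(st, dict) or "name" not in st:
                raise ConfigError(f"stage {i}: must be a mapping with a 'name'")
            extra = set(st) - {"name", "params"}
            if extra:
                raise ConfigError(f"stage {i}: unknown keys {sorted(extra)}")
            name = st["name"]
            params = st.get("params", {}) or {}
            if name not in STAGES:
                raise ConfigError(f"stage {i}: unknown stage '{name}' "
                                  f"(known: {sorted(STAGES)})")
            allowed = STAGES[name].allowed_params
            bad = set(params) - allowed
            if bad:
                raise ConfigError(f"stage '{name}': unknown params {sorted(bad)}")
            stages.append(StageSpec(name=name, params=dict(params)))
        return cls(seed=int(obj.get("seed", 0)),
                   outdir=str(obj.get("outdir", "midzone_out")),
                   log_level=str(obj.get("log_level", "INFO")),
                   stages=tuple(stages))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        p = Path(path)
        if not p.exists():
            raise MissingInputError(f"config file not found: {p}")
        obj = yaml.safe_load(p.read_text())
        if not isinstance(obj, dict):
            raise ConfigError(f"{p}: config must be a mapping")
        return cls.from_dict(obj)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Stage:
    run: callable
    allowed_params: frozenset


def _stage_synth(ctx: dict, params: dict) -> dict:
    from . import synth as _synth

    generator = params.get("generator")
    if generator not in _synth.GENERATORS:
        raise StageError(f"unknown generator '{generator}'")
    fn = _synth.GENERATORS[generator]
    kwargs = dict(params.get("kwargs", {}) or {})
    sig = set(inspect.signature(fn).parameters)
    bad = set(kwargs) - sig
    if bad:
        raise StageError(f"generator '{generator}': unknown kwargs {sorted(bad)}")
    kwargs.setdefault("seed", ctx["seed"])
    obj, truth = fn(**kwargs)
    ctx[generator] = obj
    ctx[f"{generator}-truth"] = truth
    out = ctx["outdir"] / f"{generator}-truth.json"
    out.write_text(truth.to_json())
    return {"generator": generator, "kwargs": kwargs, "truth_file": str(out)}


def _stage_track(ctx: dict, params: dict) -> dict:
    from . import tracking as trk

    movie = ctx.get("mitosis-movie")
    if movie is None:
        path = params.get("input")
        if path is None:
            raise StageError("track: no movie in context and no 'input' given")
        if not Path(path).exists():
            raise MissingInputError(f"track: input not found: {path}")
        import tifffile

        raw = tifffile.imread(path)
        movie = trk.to_eight_bit(
            raw, channels={"spindle": int(params.get("spindle_channel", 0)),
                           "dna": int(params.get("dna_channel", 1))},
            pixel_size=float(params.get("pixel_size", 1.0)),
            frame_interval=float(params.get("frame_interval", 1.0)))
    trace = trk.track_movie(movie)
    ctx["trace"] = trace
    out = ctx["outdir"] / "trace.csv"
    trk.trace_to_csv(trace, out)
    return {"trace_file": str(out), "onset_frame": trace.onset_frame,
            "n_valid": int(trace.valid.sum())}


def _stage_rates(ctx: dict, params: dict) -> dict:
    from . import tracking as trk

    trace = ctx.get("trace")
    if trace is None:
        raise StageError("rates: no trace in context (run 'track' first)")
    window = float(params.get("window", 40.0))
    rates = {
        "segregation_rate_um_s": round(trk.segregation_rate(trace, window), 6),
        "elongation_rate_um_s": round(trk.pole_separation_rate(trace, window), 6),
        "onset_frame": trace.onset_frame,
        "window_s": window,
    }
    out = ctx["outdir"] / "rates.json"
    out.write_text(json.dumps(rates, indent=1, sort_keys=True))
    ctx["rates"] = rates
    return {"rates_file": str(out), **rates}


def _stage_net_stats(ctx: dict, params: dict) -> dict:
    from . import filaments as fio
    from . import geometry as geo

    net = ctx.get("filament-network") or ctx.get("overlap-pairs") \
        or ctx.get("random-network")
    if net is None:
        path = params.get("input")
        if path is None:
            raise StageError("net-stats: no network in context and no 'input'")
        if not Path(path).exists():
            raise MissingInputError(f"net-stats: input not found: {path}")
        reader = fio.read_spatialgraph if str(path).endswith(".am") \
            else fio.read_csv_network
        net = reader(path)
    net = fio.filter_short(net, float(params.get("min_length", 100.0)))
    interactions = geo.detect_interactions(
        net, d_max=float(params.get("d_max", 100.0)),
        l_min=float(params.get("l_min", 100.0)),
        resample_step=float(params.get("resample_step", 20.0)))
    stats = geo.network_stats(net, interactions)
    out_csv = ctx["outdir"] / "interactions.csv"
    geo.interactions_to_csv(interactions, out_csv)
    out_json = ctx["outdir"] / "network_stats.json"
    out_json.write_text(json.dumps(stats.to_dict(), indent=1, sort_keys=True,
                                   default=float))
    ctx["network_stats"] = stats
    return {"stats_file": str(out_json), "interactions_file": str(out_csv),
            "n_interactions": stats.n_interactions}


STAGES: dict[str, _Stage] = {
    "synth": _Stage(_stage_synth, frozenset({"generator", "kwargs"})),
    "track": _Stage(_stage_track, frozenset({"input", "spindle_channel",
                                             "dna_channel", "pixel_size",
                                             "frame_interval"})),
    "rates": _Stage(_stage_rates, frozenset({"window"})),
    "net-stats": _Stage(_stage_net_stats, frozenset({"input", "min_length",
                                                     "d_max", "l_min",
                                                     "resample_step"})),
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the report bundle.

    Every parameter actually used is recorded in the report log so every
    number in an output file is traceable to a stage and parameter set.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx: dict = {"seed": config.seed, "outdir": outdir}
    report: dict = {"seed": config.seed, "outdir": str(outdir), "stages": []}
    for spec in config.stages:
        log.info("stage %s: params=%s", spec.name, spec.params)
        try:
            result = STAGES[spec.name].run(ctx, spec.params)
        except (ConfigError, MissingInputError):
            raise
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage '{spec.name}' failed: {exc}") from exc
        report["stages"].append({"name": spec.name, "params": spec.params,
                                 "result": result})
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True,
                                      default=str))
    return report
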