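"""End-to-end pipelines: synthetic/real traces → statistics, rates → yields.

A pipeline is described by a YAML/JSON mapping with a ``kind`` key:

``kind: trace``
    Generate (or load) gap traces, average replicates, and report the
    equalization time, ACF half period, and the activation rates implied by
    each (k_act = 1/t).

``kind: kinetics``
    Solve a rate configuration for terminal damage yields and, optionally,
    re-predict a yield-ratio table at a new activation time.

Every run returns a JSON-serializable summary with a provenance block
(config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

from . import __version__
from .errors import ConfigError
from .io import read_rates, read_trace, write_trace
from .kinetics import (
    activation_rate_from_time,
    build_scheme,
    predict_yield_table,
    solve_yields_absorption,
    solve_yields_ode,
    stochastic_yields,
)
from .synthetic import TraceConfig, generate_gap_trace
from .trajectory import (
    SiteEnergyTrace,
    acf_half_period,
    autocorrelation,
    equalization_time,
    gap_trace,
    replicate_average,
)

__all__ = ["provenance", "run_pipeline"]

logger = logging.getLogger("holehop")


def provenance(config: dict, seed: int | None = None) -> dict:
    """Provenance block stamped into every JSON output."""
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    return {"package": "holehop", "version": __version__,
            "config_sha256": digest, "seed": seed}


def _require_keys(config: dict, allowed: set[str], context: str) -> None:
    unknown = set(config) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {context}: {sorted(unknown)}")


def _trace_pipeline(config: dict, base_dir: Path) -> dict:
    _require_keys(config, {"kind", "seed", "trace", "analysis", "out"},
                  "trace pipeline")
    seed = int(config.get("seed", 0))
    trace_cfg = dict(config.get("trace", {}))
    analysis = dict(config.get("analysis", {}))
    _require_keys(
        analysis,
        {"equalization_window_ps", "equalization_mode", "acf_max_lag_ps",
         "acf_smooth_ps"},
        "analysis section",
    )

    t0 = time.perf_counter()
    if "path" in trace_cfg:
        loaded = read_trace(base_dir / trace_cfg["path"])
        replicates = loaded if isinstance(loaded, list) else [loaded]
        if not isinstance(replicates[0], SiteEnergyTrace):
            raise ConfigError("trace pipeline needs donor/acceptor traces")
        n_rep = len(replicates)
    else:
        allowed = {f.name for f in TraceConfig.__dataclass_fields__.values()}
        _require_keys(trace_cfg, allowed, "trace section")
        cfg = TraceConfig(**{**trace_cfg, "seed": seed})
        n_rep = cfg.n_replicates
        replicates = [generate_gap_trace(cfg, i) for i in range(n_rep)]
    averaged = replicate_average(replicates) if n_rep > 1 else replicates[0]
    gap = gap_trace(averaged)
    logger.info("trace stage: %d replicate(s), %d samples, %.3f s",
                n_rep, gap.values.size, time.perf_counter() - t0)

    t0 = time.perf_counter()
    eq = equalization_time(
        gap,
        window_ps=float(analysis.get("equalization_window_ps", 50.0)),
        mode=analysis.get("equalization_mode", "moving_average"),
    )
    acf = autocorrelation(gap, max_lag_ps=analysis.get("acf_max_lag_ps"))
    half = acf_half_period(acf, smooth_window_ps=float(analysis.get("acf_smooth_ps", 25.0)))
    logger.info("analysis stage: %.3f s", time.perf_counter() - t0)

    summary = {
        "provenance": provenance(config, seed),
        "n_replicates": n_rep,
        "n_samples": int(gap.values.size),
        "t_eq_ps": eq.t_eq_ps,
        "t_eq_found": eq.found,
        "half_period_ps": half.half_period_ps,
        "acf_reversal_lag_ps": half.reversal_lag_ps,
        "k_act_from_t_eq_s": (
            activation_rate_from_time(eq.t_eq_ps) if eq.found else None
        ),
        "k_act_from_half_period_s": (
            activation_rate_from_time(half.half_period_ps) if half.found else None
        ),
    }
    return summary


_METHODS = {
    "absorption": lambda scheme, seed, walkers: solve_yields_absorption(scheme),
    "ode": lambda scheme, seed, walkers: solve_yields_ode(scheme),
    "stochastic": lambda scheme, seed, walkers: stochastic_yields(
        scheme, n_walkers=walkers, seed=seed
    ),
}


def yields_summary(rates_source, method: str = "absorption",
                   seed: int = 0, walkers: int = 100_000) -> dict:
    """Solve a rates configuration for terminal yields; JSON-ready summary."""
    if method not in _METHODS:
        raise ConfigError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    rates = read_rates(rates_source)
    scheme = build_scheme(rates)
    result = _METHODS[method](scheme, seed, walkers)
    return {
        "p_PD": result.p_PD,
        "p_PA": result.p_PA,
        "ratio": result.ratio if result.ratio != float("inf") else "inf",
        "ratio_flag": result.ratio_flag,
        "method": result.method,
        "diagnostics": {
            k: v for k, v in result.diagnostics.items()
            if isinstance(v, (int, float, str, dict))
        },
    }


def _kinetics_pipeline(config: dict, base_dir: Path) -> dict:
    _require_keys(
        config,
        {"kind", "seed", "rates", "method", "walkers", "table", "out"},
        "kinetics pipeline",
    )
    seed = int(config.get("seed", 0))
    summary: dict = {"provenance": provenance(config, seed)}
    if "rates" in config:
        rates = config["rates"]
        if isinstance(rates, str):
            rates = base_dir / rates
        summary["yields"] = yields_summary(
            rates, method=config.get("method", "absorption"),
            seed=seed, walkers=int(config.get("walkers", 100_000)),
        )
    if "table" in config:
        table_cfg = dict(config["table"])
        _require_keys(
            table_cfg,
            {"tau_predict_ps", "tau_calibrate_ps", "ratios", "k_rel",
             "k_dam_D", "k_dam_A"},
            "table section",
        )
        ratios = table_cfg.pop("ratios")
        if isinstance(ratios, dict):
            ratios = {int(k): float(v) for k, v in ratios.items()}
        table = predict_yield_table(
            float(table_cfg.pop("tau_predict_ps")),
            float(table_cfg.pop("tau_calibrate_ps")),
            ratios,
            **{k: float(v) for k, v in table_cfg.items()},
        )
        summary["table"] = table.to_dict(orient="records")
    if "rates" not in config and "table" not in config:
        raise ConfigError("kinetics pipeline needs a 'rates' or 'table' section")
    return summary


def run_pipeline(config: dict, base_dir=".") -> dict:
    """Execute a pipeline configuration; returns the JSON-ready summary.

    Writes the summary to ``config['out']`` (path relative to ``base_dir``)
    when given.  Raises :class:`~holehop.errors.ConfigError` on unknown keys
    or a missing/unknown ``kind``.
    """
    if not isinstance(config, dict) or not config:
        raise ConfigError("pipeline config must be a non-empty mapping")
    base_dir = Path(base_dir)
    kind = config.get("kind")
    start = time.perf_counter()
    if kind == "trace":
        summary = _trace_pipeline(config, base_dir)
    elif kind == "kinetics":
        summary = _kinetics_pipeline(config, base_dir)
    else:
        raise ConfigError(f"unknown pipeline kind {kind!r}; use 'trace' or 'kinetics'")
    summary["elapsed_s"] = time.perf_counter() - start
    if config.get("out"):
        out_path = base_dir / config["out"]
        with open(out_path, "w") as fh:
            json.dump(summary, fh, indent=1)
            fh.write("\n")
        logger.info("wrote %s", out_path)
    return summary
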