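"""End-to-end orchestration: data -> trend -> screen -> decomposition -> models.

A :class:`RunConfig` fully determines one reproducible run: either a CSV of
individual records plus a schema file, or a named synthetic preset with a
seed.  :func:`run_pipeline` executes the stages in order, collects every
table in memory, and only then writes the output directory (publication-
shaped CSV tables, a ``metrics.json`` with every headline number, and a run
log), so a failed stage leaves no partial outputs behind.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .core import CovariateSpec, load_schema, records_to_frame
from .decomposition import advanced_decomposition, basic_decomposition
from .multilevel import default_model_specs, fit_model_sequence
from .survey import design_chisq, prevalence_ratio, relative_change, weighted_prevalence
from .synthetic import generate_frame, preset_haiti_margins

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

PRESETS = {"haiti-margins": preset_haiti_margins}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str) -> None:
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """Parameterization of one pipeline run.

    Exactly one of ``input_path`` / ``preset`` must be set.
    """

    output_dir: str | Path
    input_path: str | Path | None = None
    schema_path: str | Path | None = None
    preset: str | None = None
    seed: int = 0
    waves: tuple[str, ...] | None = None  # default: all waves, in data order
    decompose_by: str = "education"
    decompose_from: str | None = None  # default: first wave
    decompose_to: str | None = None  # default: last wave
    advanced_groupby: str | None = None  # e.g. "age_group"
    advanced_within: str | None = None  # e.g. "education"
    model_wave: str | None = None  # wave the model ladder is fitted on
    quadrature_nodes: int = 7
    use_weights: bool = False
    chisq_method: str = "rao-scott-2"
    verbosity: int = 1

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.preset is None):
            raise ValueError("set exactly one of input_path / preset")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, type(exc).__name__, str(exc)) from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


@_stage("ingest")
def _load_data(config: RunConfig) -> tuple[pd.DataFrame, Sequence[CovariateSpec]]:
    if config.preset is not None:
        if config.preset not in PRESETS:
            raise ValueError(f"unknown preset {config.preset!r}; available: {sorted(PRESETS)}")
        scenario = PRESETS[config.preset]().with_seed(config.seed)
        return generate_frame(scenario), scenario.covariate_specs
    if config.schema_path is None:
        raise ValueError("schema_path is required with input_path")
    schema = load_schema(config.schema_path)
    from .core import read_records

    return records_to_frame(read_records(config.input_path, schema)), schema


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the metrics."""
    frame, schema = _load_data(config)
    waves = list(config.waves) if config.waves else list(dict.fromkeys(frame["wave"].astype(str)))
    metrics: dict = {"seed": config.seed, "version": __version__, "waves": waves}
    tables: dict[str, pd.DataFrame] = {}

    # --- prevalence & trend -------------------------------------------------
    @_stage("trend")
    def trend():
        est = {
            w: weighted_prevalence(
                frame, lambda f, w=w: f["wave"].astype(str) == w, domain_label=w
            )
            for w in waves
        }
        tables["prevalence"] = pd.DataFrame(
            {
                "wave": waves,
                "prevalence_pct": [100 * est[w].p_hat for w in waves],
                "se_pct": [100 * est[w].se for w in waves],
                "ci_low_pct": [100 * est[w].ci_low for w in waves],
                "ci_high_pct": [100 * est[w].ci_high for w in waves],
                "n": [est[w].n for w in waves],
            }
        )
        for w in waves:
            metrics[f"prevalence_{w}_pct"] = 100 * est[w].p_hat
        if len(waves) >= 2:
            metrics["ratio_last_vs_first"] = prevalence_ratio(est[waves[-1]], est[waves[0]])
            for a, b in zip(waves, waves[1:]):
                metrics[f"relative_change_{a}_to_{b}_pct"] = relative_change(est[a], est[b])
        return est

    trend()

    # --- chi-square screen --------------------------------------------------
    @_stage("chisq")
    def screen():
        rows = []
        for w in waves:
            sub = frame[frame["wave"].astype(str) == w]
            for spec in schema:
                res = design_chisq(sub, spec.name, method=config.chisq_method)
                rows.append(
                    {
                        "wave": w,
                        "factor": spec.name,
                        "statistic": res.statistic,
                        "df": res.df,
                        "p_value": res.p_value,
                        "method": res.method,
                    }
                )
        tables["chisq"] = pd.DataFrame(rows)

    screen()

    # --- decomposition ------------------------------------------------------
    @_stage("decompose")
    def decompose():
        w_from = config.decompose_from or waves[0]
        w_to = config.decompose_to or waves[-1]
        result = basic_decomposition(frame, w_from, w_to, config.decompose_by)
        tables["decomposition"] = result.to_frame()
        metrics["decomposition_from"] = w_from
        metrics["decomposition_to"] = w_to
        metrics["delta_prevalence_pp"] = 100 * result.delta_Y
        metrics["compositional_share_pct"] = result.compositional_share
        metrics["behavioral_share_pct"] = result.behavioral_share
        if config.advanced_groupby and config.advanced_within:
            adv = advanced_decomposition(
                frame, w_from, w_to, config.advanced_groupby, config.advanced_within
            )
            tables["decomposition_advanced"] = adv.to_frame()
            metrics["advanced_alpha_change"] = adv.alpha_change
            metrics["advanced_beta_change"] = adv.beta_change

    decompose()

    # --- model ladder -------------------------------------------------------
    @_stage("models")
    def models():
        w = config.model_wave or waves[0]
        sub = frame[frame["wave"].astype(str) == w]
        specs = default_model_specs(schema)
        report, fits = fit_model_sequence(
            sub,
            specs,
            schema=schema,
            quadrature_nodes=config.quadrature_nodes,
            use_weights=config.use_weights,
        )
        tables["variance_report"] = report.to_frame()
        for f in fits:
            tables[f"aor_{f.label}"] = f.odds_ratios()
            metrics[f"{f.label}_variance"] = f.sigma2_u
            metrics[f"{f.label}_icc_pct"] = 100 * report.icc[report.models.index(f.label)]
            metrics[f"{f.label}_loglik"] = f.loglik
            metrics[f"{f.label}_aic"] = f.aic
        for label, p in zip(report.models[1:], report.pcv[1:]):
            metrics[f"{label}_pcv_pct"] = 100 * p
        metrics["model_wave"] = w

    models()

    # --- write bundle -------------------------------------------------------
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        table.to_csv(outdir / f"{name}.csv", index=False)
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    with open(outdir / "run.log", "w") as fh:
        fh.write(
            f"prevdecomp {__version__}\nseed={config.seed}\n"
            f"python={sys.version.split()[0]}\nwaves={','.join(waves)}\n"
        )
    logger.info("wrote %d tables to %s", len(tables), outdir)
    return metrics
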