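"""End-to-end analysis pipeline: fit, ANOVA, effects, optima, kinetics.

``run_pipeline`` ties the stages together on one design/response table:
least-squares quadratic fit, ANOVA with lack-of-fit split, standardized
effects, desirability optimum, crow-search optimum with repeated-run
statistics, and (optionally) kinetic fits of a concentration trace.
Every machine-readable output is delimited text round-trippable by the
package's own readers, and each run logs the package version, seed and
a hash of the effective configuration.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import csa as csa_mod
from . import datasets, io
from .design import DesignTable, FactorSpec, read_design, write_design
from .desirability import DesirabilitySpec, maximize_desirability
from .errors import PipelineError, ValidationError
from .kinetics import (
    KineticTrace,
    fit_pseudo_first_order,
    fit_pseudo_second_order,
    qt_series,
    removal_efficiency,
)
from .rsm import anova, fit_quadratic, predict, standardized_effects

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    With ``design_path`` unset the packaged Pb(II) table is analyzed.
    Desirability bounds default to the published convention: L = the
    worst observed response, U = 100 (the percent-removal ceiling).
    Kinetics runs only when ``kinetics_path`` is given; the trace file
    has two columns (time_min, concentration_mg_l) and the batch
    constants come from the config.
    """

    design_path: str | None = None
    factors: tuple[FactorSpec, ...] | None = None
    outdir: str = "sorbopt_out"
    seed: int = 0
    # desirability
    lower: float | None = None
    upper: float = 100.0
    weight: float = 1.0
    grid_step: float = 0.01
    # crow search
    n_crows: int = 50
    flight_length: float = 2.0
    awareness_prob: float = 0.1
    n_iter: int = 150
    n_runs: int = 50
    # kinetics (optional)
    kinetics_path: str | None = None
    c0: float | None = None
    volume_l: float | None = None
    mass_g: float | None = None
    qe_exp: float | None = None

    def config_hash(self) -> str:
        text = repr(sorted(self.__dict__.items(), key=lambda kv: kv[0]))
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _load_design(config: PipelineConfig) -> DesignTable:
    if config.design_path is None:
        return datasets.load_pb_design()
    path = Path(config.design_path)
    if not path.exists():
        raise ValidationError(f"design/response file not found: {path}")
    return read_design(path, factors=config.factors)


def _read_trace(config: PipelineConfig) -> KineticTrace:
    import pandas as pd

    path = Path(config.kinetics_path)
    if not path.exists():
        raise ValidationError(f"kinetic trace file not found: {path}")
    frame = pd.read_csv(path, comment="#")
    cols = list(frame.columns[:2])
    if config.c0 is None or config.volume_l is None or config.mass_g is None:
        raise ValidationError("kinetics needs c0, volume_l and mass_g batch constants")
    return KineticTrace(
        times=frame[cols[0]].to_numpy(float),
        concentrations=frame[cols[1]].to_numpy(float),
        c0=config.c0,
        volume_l=config.volume_l,
        mass_g=config.mass_g,
        c_tolerance=0.05 * config.c0,
    )


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Execute every stage; returns the in-memory report bundle.

    Stage failures re-raise as :class:`PipelineError` with the stage
    name attached.  Outputs land in ``config.outdir``.
    """
    from . import __version__

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info(
        "pipeline: sorbopt %s, seed %d, config %s",
        __version__, config.seed, config.config_hash(),
    )
    report: dict[str, object] = {}
    stage = "load-design"
    try:
        design = _load_design(config)
        write_design(design, outdir / "design.csv", comments=[f"seed={config.seed}"])
        report["design"] = design

        stage = "fit"
        model, summary = fit_quadratic(design)
        io.model_to_kv(model, outdir / "model.txt", comments=[f"seed={config.seed}"])
        report["model"], report["fit_summary"] = model, summary
        log.info("fit: R^2 = %.4f, adj R^2 = %.4f", summary.r_squared, summary.adj_r_squared)

        stage = "anova"
        table = anova(model, design)
        table.to_frame().to_csv(outdir / "anova.csv", index=False)
        report["anova"] = table

        stage = "effects"
        effects = standardized_effects(model)
        effects.to_frame().to_csv(outdir / "effects.csv", index=False)
        report["effects"] = effects

        stage = "optimize-df"
        lower = config.lower if config.lower is not None else float(design.responses.min())
        spec = DesirabilitySpec(lower=lower, upper=config.upper, weight=config.weight)
        optimum = maximize_desirability(
            model, spec, factors=design.factors, grid_step=config.grid_step
        )
        io.write_kv(
            outdir / "optimum_df.txt",
            optimum.to_kv(design.factor_names),
            comments=[f"seed={config.seed}", f"L={lower} U={config.upper} w={config.weight}"],
        )
        report["df_optimum"] = optimum

        stage = "optimize-csa"
        cfg = csa_mod.CsaConfig(
            bounds=tuple((-1.0, 1.0) for _ in design.factors),
            n_crows=config.n_crows,
            flight_length=config.flight_length,
            awareness_prob=config.awareness_prob,
            n_iter=config.n_iter,
            seed=config.seed,
            n_runs=config.n_runs,
        )
        objective = lambda p: predict(model, p)  # noqa: E731
        if config.n_runs >= 2:
            result = csa_mod.multi_run_stats(objective, cfg)
        else:
            result = csa_mod.optimize(objective, cfg)
        result.trace_frame().to_csv(outdir / "csa_trace.csv", index=False)
        summary_kv: dict[str, object] = {
            f"coded_{n}": float(v)
            for n, v in zip(design.factor_names, result.best_position)
        }
        summary_kv.update(
            {
                f"actual_{f.name}": float(f.to_actual(v))
                for f, v in zip(design.factors, result.best_position)
            }
        )
        summary_kv["best_fitness"] = result.best_fitness
        if result.stats is not None:
            summary_kv.update(result.stats)
        io.write_kv(outdir / "csa_summary.txt", summary_kv, comments=[f"seed={config.seed}"])
        report["csa_result"] = result

        if config.kinetics_path is not None:
            stage = "kinetics"
            trace = _read_trace(config)
            qt = qt_series(trace)
            qe_exp = config.qe_exp
            if qe_exp is None:
                qe_exp = float(qt[-1])
                log.info("kinetics: qe_exp not supplied, using final q_t = %.4g", qe_exp)
            fits = {
                "first": fit_pseudo_first_order(trace.times, qt, qe_exp),
                "second": fit_pseudo_second_order(trace.times, qt),
            }
            kv: dict[str, object] = {
                "qe_exp": qe_exp,
                "removal_efficiency_final": removal_efficiency(
                    trace.c0, float(trace.concentrations[-1])
                ),
            }
            for label, fit in fits.items():
                kv[f"{label}_qe_calc"] = fit.qe_calc
                kv[f"{label}_rate_constant"] = fit.rate_constant
                kv[f"{label}_r_squared"] = fit.r_squared
            io.write_kv(outdir / "kinetics.txt", kv, comments=[f"seed={config.seed}"])
            report["kinetics"] = fits
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[{stage}] {exc}") from exc
    return report
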