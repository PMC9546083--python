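"""End-to-end analysis runner producing a results directory.

``run_analysis`` executes read -> validate -> fill-in -> effects /
pseudo-IPD -> models -> pooling -> plots and writes machine-readable JSON,
CSV tables, figures with sidecar coordinate CSVs, the fill-in provenance
report, and a log sufficient to reproduce the run.  Numbers are written at
full precision; the CLI adds no rounding.  On any stage failure, partial
outputs are removed.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .ancova_models import OneStageSpec, fit_onestage, twostage
from .data_model import read_dataset, validate_dataset, write_dataset
from .effects_ad import TrialEffect, compute_effects
from .fillin import run_fillin
from .plots import forest_plot, funnel_plot
from .pooling import pool_ce, pool_re
from .pseudo_ipd import generate_dataset, verify_moments

__all__ = ["AnalysisConfig", "run_analysis"]

AD_METHODS = ("followup", "change", "ancova_recovered")


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run."""

    input: str
    outdir: str
    model: str = "RE"                  # CE | RE
    hk: bool = False
    level: float = 0.95
    seed: int = 1
    corr_strategy: str = "weighted_mean"
    corr_value: Optional[float] = None
    negate_change: bool = False
    methods: tuple[str, ...] = AD_METHODS
    resid_structure: str = "study"
    interaction: bool = False
    plot_format: str = "png"

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load a flat key=value config file; keyword overrides win."""
        values: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key in ("hk", "negate_change", "interaction"):
                values[key] = raw.lower() in ("1", "true", "yes")
            elif key in ("level", "corr_value"):
                values[key] = float(raw)
            elif key == "seed":
                values[key] = int(raw)
            elif key == "methods":
                values[key] = tuple(m.strip() for m in raw.split(",") if m.strip())
            else:
                values[key] = raw
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def run_analysis(config: AnalysisConfig) -> dict:
    """Execute the full pipeline and write the results directory.

    Returns the results dictionary that is also serialised to
    ``results.json``.  Raises with the failing stage named; no partial
    output directory is left behind on error.
    """
    outdir = Path(config.outdir)
    stage = "setup"
    work = Path(tempfile.mkdtemp(prefix="prepost_ma_"))
    try:
        stage = "read"
        ds = read_dataset(config.input, negate_change=config.negate_change)
        stage = "validate"
        report = validate_dataset(ds)
        if not report.valid:
            raise ValueError(
                "input dataset invalid:\n" + "\n".join(str(v) for v in report.violations)
            )
        stage = "fill"
        complete, fill_report = run_fillin(
            ds, corr_strategy=config.corr_strategy, corr_value=config.corr_value
        )
        write_dataset(complete, work / "complete.csv")
        fill_report.to_frame().to_csv(work / "fill_report.csv", index=False)

        results: dict = {
            "package": "prepost-ma",
            "version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "k": complete.k,
            "methods": {},
        }

        def _pool(effects):
            if config.model == "CE":
                return pool_ce(effects, level=config.level)
            return pool_re(effects, level=config.level, hk=config.hk)

        stage = "effects"
        for method in config.methods:
            effects = compute_effects(complete, method)
            pd.DataFrame(
                [
                    {
                        "trial_id": e.trial_id, "method": e.method,
                        "estimate": e.estimate, "variance": e.variance, "se": e.se,
                    }
                    for e in effects
                ]
            ).to_csv(work / f"effects_{method}.csv", index=False, float_format="%.17g")
            pooled = _pool(effects)
            results["methods"][method] = pooled.to_dict()
            stage = f"plots[{method}]"
            forest_plot(effects, pooled, work / f"forest_{method}.{config.plot_format}",
                        format=config.plot_format)
            if len(effects) >= 2:
                funnel_plot(effects, pooled, work / f"funnel_{method}.{config.plot_format}",
                            format=config.plot_format)
            stage = "effects"

        stage = "pseudo_ipd"
        pseudo = generate_dataset(complete, seed=config.seed)
        pseudo.to_csv(work / "pseudo_ipd.csv")
        moments = verify_moments(pseudo, complete)
        if not moments.passed:
            raise ValueError(f"pseudo-IPD moment check failed (worst {moments.worst:.3g})")

        stage = "twostage"
        ts = twostage(pseudo, model=config.model, hk=config.hk,
                      interaction=config.interaction, level=config.level)
        results["methods"]["twostage"] = ts.theta.to_dict()
        if ts.interaction is not None:
            results["methods"]["twostage_interaction"] = ts.interaction.to_dict()
        forest_plot(
            [
                TrialEffect(rec.trial_id, "ancova_recovered", rec.treatment, rec.treatment_se**2)
                for rec in ts.per_trial.itertuples()
            ],
            ts.theta,
            work / f"forest_twostage.{config.plot_format}",
            format=config.plot_format,
        )

        stage = "onestage"
        spec = OneStageSpec(
            resid_structure=config.resid_structure,
            model=config.model,
            interaction=config.interaction,
            level=config.level,
        )
        fit = fit_onestage(pseudo, spec)
        results["methods"]["onestage"] = fit.to_dict()

        stage = "write"
        (work / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))
        log = [
            f"prepost-ma {__version__}",
            f"seed = {config.seed}",
            "config = " + json.dumps(dataclasses.asdict(config), sort_keys=True),
            f"fill-in: {fill_report.n_filled('calculated')} calculated, "
            f"{fill_report.n_filled('imputed')} imputed cells",
            f"pseudo-IPD moment check: worst discrepancy {moments.worst:.3e}",
        ]
        (work / "log.txt").write_text("\n".join(log) + "\n")

        outdir.mkdir(parents=True, exist_ok=True)
        for item in work.iterdir():
            shutil.move(str(item), outdir / item.name)
        return results
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
    finally:
        shutil.rmtree(work, ignore_errors=True)
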