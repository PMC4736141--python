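"""One-command reproduction of the full puberty-onset analysis.

Given a cohort (loaded from CSV or freshly simulated), the pipeline runs
the stages in the order the analysis prescribes:

1. descriptive metadata and a binned contingency table;
2. Bayesian growth fits — null, increment, and (when every record has a
   BCS) increment + BCS with beta pinned at its increment-fit posterior
   mode — with DIC differences against their reference models;
3. the sperm-presence logistic comparison (length versus age) and the
   0.99/0.01 management thresholds, skipped with an explicit notice when
   the cohort carries no sperm outcomes.

A single master seed drives everything.  Per-stage seeds are derived via
``SeedSequence([master, stage_index])`` with a fixed stage numbering
(0 = simulation, 1 = null fit, 2 = increment fit, 3 = BCS fit,
4 = logistic bootstrap), so each stage can be re-run in isolation and the
whole report is byte-identical under the same inputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .cohort import CohortConfig, simulate_cohort, table_fixture
from .growth import MCMCConfig, PosteriorResult, PriorSpec, fit_model
from .logistic import PredictorComparison, compare_predictors
from .records import (
    AnimalRecord,
    Source,
    cohort_summary,
    read_cohort_csv,
    write_cohort_csv,
)
from .tables import EXPERIMENT1_SCHEME, EXPERIMENT2_SCHEME, cross_tabulate

__all__ = ["AnalysisReport", "run_full_analysis", "stage_seed"]

_STAGES = {
    "simulate": 0,
    "fit_null": 1,
    "fit_increment": 2,
    "fit_increment_bcs": 3,
    "logistic_bootstrap": 4,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive the per-stage seed from the master seed (documented scheme:
    ``SeedSequence([master, stage_index])``, folded below 2**31)."""
    ss = np.random.SeedSequence([int(master_seed) % (2**31), _STAGES[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class AnalysisReport:
    """Fully serializable record of one analysis run."""

    cohort: dict
    table: dict
    growth: dict
    logistic: dict
    seeds: dict
    software: dict

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "table": self.table,
            "growth": self.growth,
            "logistic": self.logistic,
            "seeds": self.seeds,
            "software": self.software,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisReport":
        return cls(
            cohort=d["cohort"],
            table=d["table"],
            growth=d["growth"],
            logistic=d["logistic"],
            seeds=d["seeds"],
            software=d["software"],
        )

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls.from_dict(json.loads(text))


def _growth_stage(
    records: Sequence[AnimalRecord],
    priors: PriorSpec,
    mcmc: MCMCConfig,
    master_seed: int,
    log,
) -> dict:
    from dataclasses import replace

    usable = [r for r in records if r.age_months is not None]
    out: dict = {}
    t0 = time.perf_counter()
    null_cfg = replace(mcmc, seed=stage_seed(master_seed, "fit_null"))
    null_fit = fit_model(usable, "null", priors=priors, config=null_cfg)
    null_fit.delta_dic = 0.0
    out["null"] = null_fit.to_dict()
    log(f"null fit done in {time.perf_counter() - t0:.1f}s, DIC {null_fit.dic:.2f}")

    t0 = time.perf_counter()
    inc_cfg = replace(mcmc, seed=stage_seed(master_seed, "fit_increment"))
    inc_fit = fit_model(usable, "increment", priors=priors, config=inc_cfg, reference=null_fit)
    out["increment"] = inc_fit.to_dict()
    log(
        f"increment fit done in {time.perf_counter() - t0:.1f}s, "
        f"DIC {inc_fit.dic:.2f} (delta {inc_fit.delta_dic:.2f})"
    )

    if all(r.bcs is not None for r in usable):
        t0 = time.perf_counter()
        bcs_cfg = replace(mcmc, seed=stage_seed(master_seed, "fit_increment_bcs"))
        bcs_fit = fit_model(
            usable,
            "increment_bcs",
            priors=priors,
            config=bcs_cfg,
            reference=inc_fit,
            increment_result=inc_fit,
        )
        out["increment_bcs"] = bcs_fit.to_dict()
        log(
            f"increment+BCS fit done in {time.perf_counter() - t0:.1f}s, "
            f"DIC {bcs_fit.dic:.2f} (delta vs increment {bcs_fit.delta_dic:.2f})"
        )
    else:
        out["increment_bcs"] = {
            "skipped": "not every record carries a body condition score"
        }
        log("increment+BCS fit skipped: BCS not available for every record")
    return out


def run_full_analysis(
    cohort: Sequence[AnimalRecord] | None = None,
    *,
    cohort_path: str | Path | None = None,
    simulate_config: CohortConfig | None = None,
    fixture: str | None = None,
    priors: PriorSpec | None = None,
    mcmc_config: MCMCConfig | None = None,
    seed: int = 0,
    n_boot: int = 0,
    verbose: bool = False,
) -> AnalysisReport:
    """Run every analysis stage on one cohort and return the report.

    Exactly one cohort source must be given: an in-memory record list, a
    CSV path, a simulation config (its seed is overridden by the derived
    stage seed) or a fixture name.  Stages degrade gracefully: a cohort
    without sperm outcomes skips the logistic stage with a notice, and a
    cohort without complete BCS skips only the BCS growth variant.
    """

    def log(msg: str) -> None:
        if verbose:
            import sys

            print(f"[spermarche] {msg}", file=sys.stderr)

    sources_given = sum(
        x is not None for x in (cohort, cohort_path, simulate_config, fixture)
    )
    if sources_given != 1:
        raise ValueError(
            "supply exactly one of cohort, cohort_path, simulate_config, fixture"
        )

    timings: dict[str, float] = {}  # logged, not serialized: keeps reports deterministic
    seeds = {"master": int(seed)}

    t0 = time.perf_counter()
    if cohort_path is not None:
        records = read_cohort_csv(cohort_path)
        cohort_origin = {"kind": "csv", "path": str(cohort_path)}
    elif simulate_config is not None:
        from dataclasses import replace as _replace

        sim_seed = stage_seed(seed, "simulate")
        seeds["simulate"] = sim_seed
        records = simulate_cohort(_replace(simulate_config, seed=sim_seed))
        cohort_origin = {"kind": "simulated", "n": simulate_config.n}
    elif fixture is not None:
        records = table_fixture(fixture)
        cohort_origin = {"kind": "fixture", "table": fixture}
    else:
        records = list(cohort)  # type: ignore[arg-type]
        cohort_origin = {"kind": "in_memory"}
    timings["load"] = time.perf_counter() - t0
    log(f"cohort ready: {len(records)} records ({cohort_origin['kind']})")

    meta = cohort_summary(records)
    meta["origin"] = cohort_origin

    all_in_vivo = all(r.source is Source.IN_VIVO for r in records)
    scheme = EXPERIMENT1_SCHEME if all_in_vivo else EXPERIMENT2_SCHEME
    t0 = time.perf_counter()
    table = cross_tabulate(records, scheme)
    timings["tabulate"] = time.perf_counter() - t0

    priors = priors or PriorSpec()
    mcmc = mcmc_config or MCMCConfig()
    for stage in ("fit_null", "fit_increment", "fit_increment_bcs"):
        seeds[stage] = stage_seed(seed, stage)
    t0 = time.perf_counter()
    growth = _growth_stage(records, priors, mcmc, seed, log)
    timings["growth"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    with_sperm = [r for r in records if r.sperm_present is not None]
    classes = {r.sperm_present for r in with_sperm}
    if len(with_sperm) >= 3 and classes == {True, False}:
        boot_seed = stage_seed(seed, "logistic_bootstrap")
        seeds["logistic_bootstrap"] = boot_seed
        comparison = compare_predictors(with_sperm, n_boot=n_boot, seed=boot_seed)
        logistic: dict = comparison.to_dict()
        log(
            "logistic stage done: preferred predictor "
            f"{comparison.preferred} (delta AIC {comparison.aic_difference:.2f})"
        )
    else:
        reason = (
            "no records carry a sperm outcome"
            if not with_sperm
            else "sperm outcomes lack variation or are too few (< 3)"
        )
        logistic = {"skipped": reason}
        log(f"logistic stage skipped: {reason}")
    timings["logistic"] = time.perf_counter() - t0
    log("stage timings (s): " + ", ".join(f"{k}={v:.2f}" for k, v in timings.items()))

    software = {
        "package": "spermarche",
        "version": __version__,
        "numpy": np.__version__,
    }
    return AnalysisReport(
        cohort=meta,
        table=table.to_dict(),
        growth=growth,
        logistic=logistic,
        seeds=seeds,
        software=software,
    )
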