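"""One-call orchestration: data -> binarize -> classify -> permute -> model -> rates.

`run` takes either file paths (roster / schedule / observations CSVs) or a
:class:`~dyadseq.simulate.SimulationConfig`, executes every analysis stage,
writes per-stage artifacts into an output directory, and returns a single
report dictionary with every headline statistic.  Every stage draws its
randomness from a named substream of the top-level seed, so reruns with the
same inputs and seed are identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ethogram, mmodel, permutation, rates, sequences
from .simulate import SimulationConfig, simulate

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything a full run needs.

    Either ``simulation`` or all three input paths must be set.  Iteration
    counts default to the analysis-standard values (1000 sequence-shuffle
    iterations, 5000 paired sign-flips, 4 chains x 8000 MCMC iterations with
    4000 warmup).
    """

    outdir: str | Path = "dyadseq_out"
    simulation: SimulationConfig | None = None
    roster_path: str | Path | None = None
    schedule_path: str | Path | None = None
    observations_path: str | Path | None = None
    sequence_types: tuple[str, ...] = ("generalized", "precise")
    perm_stratum: str = "stranger"
    n_iter_sequence_perm: int = 1000
    n_iter_paired_perm: int = 5000
    chains: int = 4
    total_iter: int = 8000
    warmup: int = 4000
    include_sex: bool = False
    skip_model: bool = False
    noncontact_as_supported: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_iter_sequence_perm < 1 or self.n_iter_paired_perm < 1:
            raise ValueError("iteration counts must be >= 1")
        have_paths = all(
            p is not None for p in (self.roster_path, self.schedule_path, self.observations_path)
        )
        if self.simulation is None and not have_paths:
            raise ValueError("provide either a simulation config or all three input paths")


def _stage(report: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            report.setdefault("timings_s", {})[name] = round(dt, 3)
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, dt)

    return _Timer()


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and return the consolidated report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(8).astype(np.int64)
    report: dict = {"seed": int(config.seed), "stages": []}

    with _stage(report, "ingest"):
        if config.simulation is not None:
            cohort = simulate(config.simulation, seed=int(seeds[0]) % (2 ** 31))
            cohort.write(outdir / "simulated")
            roster, schedule, obs = cohort.roster, cohort.schedule, cohort.observations
        else:
            roster = ethogram.read_roster(config.roster_path)
            schedule = ethogram.read_schedule(config.schedule_path)
            obs = ethogram.read_observations(config.observations_path, roster, schedule)
        matrix = ethogram.binarize(obs, roster, schedule)
        matrix.to_long_csv(outdir / "binarized_long.csv")
        fam = matrix.dyads["familiarity"]
        report["n_birds"] = len(roster)
        report["n_dyads_familiar"] = int((fam == "familiar").sum())
        report["n_dyads_stranger"] = int((fam == "stranger").sum())
        report["hours_observed"] = round(matrix.hours_observed, 2)

    with _stage(report, "classify"):
        cls, summary = sequences.classify_all(
            matrix, noncontact_as_supported=config.noncontact_as_supported
        )
        cls.to_csv(outdir / "classifications.csv", index=False)
        summary.to_csv(outdir / "sequence_summary.csv", index=False)
        report["sequence_summary"] = summary.to_dict(orient="records")

    report["permutation"] = {}
    with _stage(report, "permute"):
        for k, seq in enumerate(config.sequence_types):
            res = permutation.null_distribution(
                matrix, seq, stratum=config.perm_stratum,
                n_iter=config.n_iter_sequence_perm, seed=int(seeds[1 + k]) % (2 ** 31),
            )
            res.to_json(outdir / f"permutation_{seq}_{config.perm_stratum}.json")
            res.null_to_csv(outdir / f"permutation_{seq}_{config.perm_stratum}_null.csv")
            report["permutation"][seq] = res.to_dict()

    report["model"] = {}
    if not config.skip_model:
        with _stage(report, "model"):
            for k, seq in enumerate(config.sequence_types):
                data = mmodel.build_model_data(cls, seq, include_sex=config.include_sex)
                fitres = mmodel.fit(
                    data, chains=config.chains, total_iter=config.total_iter,
                    warmup=config.warmup, seed=int(seeds[3 + k]) % (2 ** 31),
                )
                summ = mmodel.summarize(fitres)
                summ.to_csv(outdir / f"posterior_summary_{seq}.csv", index=False)
                beta = summ.set_index("parameter").loc["beta_stranger"]
                ok = bool(fitres.stuck_fraction <= 1e-3 and beta["rhat"] < 1.05)
                report["model"][seq] = {
                    "beta_stranger_mean": float(beta["mean"]),
                    "beta_stranger_ci": [float(beta["ci_low"]), float(beta["ci_high"])],
                    "odds_factor": float(beta["odds_factor"]),
                    "odds_factor_ci": [float(beta["odds_ci_low"]), float(beta["odds_ci_high"])],
                    "rhat": float(beta["rhat"]),
                    "ess": float(beta["ess"]),
                    "stuck_fraction": fitres.stuck_fraction,
                    "diagnostics_ok": ok,
                }
                (outdir / f"model_diagnostics_{seq}.json").write_text(
                    fitres.diagnostics().to_json(orient="records")
                )

    with _stage(report, "rates"):
        pr = rates.paired_rates(matrix)
        pr.to_csv(outdir / "paired_rates.csv", index=False)
        if len(pr) >= 2:
            test = rates.permuted_paired_test(
                pr, n_iter=config.n_iter_paired_perm, seed=int(seeds[5]) % (2 ** 31)
            )
            test.to_json(outdir / "paired_test.json")
            d = pr["rate_contact"] - pr["rate_noncontact"]
            report["paired_rates"] = {
                "n_birds": len(pr),
                "mean_rate_contact": float(pr["rate_contact"].mean()),
                "sd_rate_contact": float(pr["rate_contact"].std(ddof=1)),
                "se_rate_contact": float(pr["rate_contact"].std(ddof=1) / np.sqrt(len(pr))),
                "mean_rate_noncontact": float(pr["rate_noncontact"].mean()),
                "sd_rate_noncontact": float(pr["rate_noncontact"].std(ddof=1)),
                "se_rate_noncontact": float(pr["rate_noncontact"].std(ddof=1) / np.sqrt(len(pr))),
                "mean_difference": float(d.mean()),
                "p_one_sided": test.p_one_sided,
            }
        else:
            logger.warning("fewer than 2 paired-rate birds; paired test skipped")
            report["paired_rates"] = {"n_birds": len(pr)}

    report["diagnostics_ok"] = all(
        m.get("diagnostics_ok", True) for m in report["model"].values()
    )
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
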