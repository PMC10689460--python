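"""Experiment harness: budgets, campaigns, the control experiment, comparisons.

The evaluation arithmetic of the full experimental design is reproduced in
closed form by :func:`budget_report` and checked against the observed run
counters. Per run the nominal accounting is lambda * (generations + 1)
evolution-level fitness evaluations (25 + 25*30 = 775 at defaults), each
newborn's RevDE session adds K + 3K*(iterations-1) = 280 reward assessments,
and a two-system campaign totals 775 * 280 * 2 = 434,000 evaluations, i.e.
434,000 * 40 s = 4,822 h of simulated time. The nominal per-run figure
counts lambda newborns at initialization although mu robots are created
then; the ledger reports both figures and verifies the observed counters
against the actual one.

:func:`run_campaign` executes (mode x repetition) runs with deterministic
per-run seeds and aggregates per-generation statistics with 95% confidence
bands (sample mean +- t * standard error); :func:`control_experiment` is the
same loop with every newborn's inherited body replaced by a random one;
:func:`compare_modes` applies Welch's t-tests with Bonferroni correction and
the fitness vs. parent-child-distance correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .env import EvalLedger
from .evolution import EvoConfig, RunRecord, run as run_evolution

#: scaled-down default campaign: finishes in minutes on one CPU while
#: exercising every mechanism; full-scale settings are one config switch away
SMOKE_CONFIG = EvoConfig(mu=8, lam=4, generations=5)


class AccountingError(AssertionError):
    """Observed evaluation counters disagree with the closed-form budget."""


@dataclass(frozen=True)
class CampaignSpec:
    modes: tuple[str, ...] = ("lamarckian", "darwinian")
    repetitions: int = 20
    base_config: EvoConfig = field(default_factory=EvoConfig)
    seed: int = 0
    comparisons: int = 6            # Bonferroni correction count

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")

    def run_seed(self, mode_index: int, repetition: int) -> int:
        """Deterministic, distinct per-run seed below 2**31."""
        ss = np.random.SeedSequence([self.seed, mode_index, repetition])
        return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass(frozen=True)
class BudgetReport:
    """Closed-form evaluation counts implied by a configuration."""

    assessments_per_robot: int
    evolution_evaluations_nominal: int   # lambda * (generations + 1)
    evaluated_robots: int                # mu + lambda * generations
    campaign_evaluations: int            # nominal * assessments * n_modes
    simulated_hours: float
    repetitions: int

    def as_dict(self) -> dict:
        return {
            "assessments_per_robot": self.assessments_per_robot,
            "evolution_evaluations_nominal": self.evolution_evaluations_nominal,
            "evaluated_robots": self.evaluated_robots,
            "campaign_evaluations": self.campaign_evaluations,
            "simulated_hours": self.simulated_hours,
            "repetitions": self.repetitions,
        }


def budget_report(
    cfg: EvoConfig, repetitions: int = 20, n_modes: int = 2
) -> BudgetReport:
    """Predicted evaluation counts, recomputed from the configuration."""
    learner = cfg.learner
    assessments = learner.population_size + 3 * learner.population_size * (
        learner.iterations - 1
    )
    nominal = cfg.lam * (cfg.generations + 1)
    actual = cfg.mu + cfg.lam * cfg.generations
    campaign = nominal * assessments * n_modes
    hours = campaign * cfg.task.duration / 3600.0
    return BudgetReport(
        assessments_per_robot=assessments,
        evolution_evaluations_nominal=nominal,
        evaluated_robots=actual,
        campaign_evaluations=campaign,
        simulated_hours=hours,
        repetitions=repetitions,
    )


def verify_ledger(cfg: EvoConfig, ledger: EvalLedger | dict) -> None:
    """Assert the observed counters equal the closed-form predictions.

    Checked against the actual robot count (mu + lambda * generations); the
    nominal per-run accounting undercounts initialization by mu - lambda.
    """
    snap = ledger if isinstance(ledger, dict) else ledger.snapshot()
    report = budget_report(cfg)
    robots = report.evaluated_robots
    expected = {
        "evolution_evaluations": robots,
        "prelearning_evaluations": robots,
        "learning_assessments": robots * report.assessments_per_robot,
    }
    for key, want in expected.items():
        if snap[key] != want:
            raise AccountingError(
                f"{key}: observed {snap[key]}, closed form predicts {want}"
            )
    per_test_seconds = cfg.task.duration
    want_seconds = sum(expected.values()) * per_test_seconds
    if abs(snap["simulated_seconds"] - want_seconds) > 1e-6:
        raise AccountingError(
            f"simulated_seconds: observed {snap['simulated_seconds']}, "
            f"predicted {want_seconds}"
        )


def savings_estimate(
    gen_equal: int, cfg: EvoConfig | None = None, repetitions: int = 20
) -> int:
    """Evaluations saved if one system matches the other's final quality by
    generation ``gen_equal``: lambda * (generations - gen_equal) *
    assessments-per-robot * repetitions."""
    cfg = cfg or EvoConfig()
    if gen_equal > cfg.generations:
        raise ValueError("gen_equal cannot exceed the generation count")
    report = budget_report(cfg, repetitions)
    return (
        cfg.lam
        * (cfg.generations - gen_equal)
        * report.assessments_per_robot
        * repetitions
    )


# --------------------------------------------------------------------------
# campaigns
# --------------------------------------------------------------------------

@dataclass
class CampaignResult:
    spec: CampaignSpec
    records: list[RunRecord]
    aggregate: pd.DataFrame
    manifest: dict

    def records_for(self, mode: str) -> list[RunRecord]:
        return [r for r in self.records if r.mode == mode]


def _aggregate(records: list[RunRecord]) -> pd.DataFrame:
    """Per-mode, per-generation mean with a 95% t confidence band."""
    from scipy import stats as sps

    frames = []
    for r in records:
        df = r.generation_stats.copy()
        df["mode"] = r.mode
        df["seed"] = r.seed
        frames.append(df)
    stacked = pd.concat(frames, ignore_index=True)
    rows = []
    for (mode, gen), group in stacked.groupby(["mode", "generation"]):
        n = len(group)
        for col in ("mean_fitness", "max_fitness", "mean_learning_delta",
                    "diversity", "mean_parent_child_ted"):
            values = group[col].to_numpy(dtype=float)
            finite = values[np.isfinite(values)]
            mean = float(finite.mean()) if finite.size else float("nan")
            if n > 1 and finite.size > 1:
                sem = float(np.nanstd(values, ddof=1) / np.sqrt(n))
                tval = float(sps.t.ppf(0.975, n - 1))
                half = tval * sem
            else:
                half = 0.0
            rows.append(
                {
                    "mode": mode,
                    "generation": gen,
                    "metric": col,
                    "mean": mean,
                    "ci_halfwidth": half,
                    "n_runs": n,
                }
            )
    return pd.DataFrame(rows)


def run_campaign(spec: CampaignSpec, backend=None) -> CampaignResult:
    """All (mode x repetition) runs; ledger verified at the end of each."""
    records: list[RunRecord] = []
    for mi, mode in enumerate(spec.modes):
        for rep in range(spec.repetitions):
            cfg = replace(
                spec.base_config, mode=mode, seed=spec.run_seed(mi, rep)
            )
            record = run_evolution(cfg, backend)
            verify_ledger(cfg, record.ledger)
            records.append(record)
    aggregate = _aggregate(records)
    budget = budget_report(spec.base_config, spec.repetitions, len(spec.modes))
    manifest = {
        "modes": list(spec.modes),
        "repetitions": spec.repetitions,
        "seed": spec.seed,
        "run_seeds": {
            f"{mode}/{rep}": spec.run_seed(mi, rep)
            for mi, mode in enumerate(spec.modes)
            for rep in range(spec.repetitions)
        },
        "budget": budget.as_dict(),
        "body_source": spec.base_config.body_source,
        "runs": [r.manifest() for r in records],
    }
    return CampaignResult(spec, records, aggregate, manifest)


def control_experiment(spec: CampaignSpec, backend=None) -> CampaignResult:
    """The random-body control: identical loop, but every newborn's inherited
    body is replaced by a randomly generated one before learning (learned
    weights are still written back in lamarckian mode)."""
    spec = replace(spec, base_config=replace(spec.base_config, body_source="random"))
    return run_campaign(spec, backend)


# --------------------------------------------------------------------------
# mode comparison
# --------------------------------------------------------------------------

def compare_modes(
    result: CampaignResult,
    mode_a: str = "lamarckian",
    mode_b: str = "darwinian",
    alpha: float = 0.05,
) -> dict:
    """Welch tests per generation, Bonferroni threshold, and the correlation
    between newborn fitness and parent-child tree-edit distance."""
    from scipy import stats as sps

    rec_a = result.records_for(mode_a)
    rec_b = result.records_for(mode_b)
    if len(rec_a) < 2 or len(rec_b) < 2:
        raise ValueError("compare_modes needs at least two runs per mode")

    m = result.spec.comparisons
    comparison_rows = []
    for gen in rec_a[0].generation_stats["generation"]:
        a = np.array(
            [r.generation_stats.loc[
                r.generation_stats["generation"] == gen, "mean_fitness"
            ].iloc[0] for r in rec_a]
        )
        b = np.array(
            [r.generation_stats.loc[
                r.generation_stats["generation"] == gen, "mean_fitness"
            ].iloc[0] for r in rec_b]
        )
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(
            a[0], b[0]
        ):
            t, p = 0.0, 1.0   # identical constant samples: no difference
        else:
            t, p = sps.ttest_ind(a, b, equal_var=False)
        comparison_rows.append(
            {
                "generation": int(gen),
                "t": float(t),
                "p": float(p),
                "p_bonferroni": float(min(1.0, p * m)),
                "significant": bool(p < alpha / m),
            }
        )

    correlations = {}
    for mode, recs in ((mode_a, rec_a), (mode_b, rec_b)):
        rows = pd.concat([r.newborns for r in recs], ignore_index=True)
        rows = rows.dropna(subset=["parent_child_ted"])
        if len(rows) >= 2 and rows["parent_child_ted"].nunique() > 1 and rows[
            "fitness_after"
        ].nunique() > 1:
            r_val, p_val = sps.pearsonr(
                rows["fitness_after"], rows["parent_child_ted"]
            )
        else:
            r_val, p_val = float("nan"), float("nan")
        correlations[mode] = {"r": float(r_val), "p": float(p_val)}

    return {
        "per_generation": comparison_rows,
        "bonferroni_threshold": alpha / m,
        "comparisons": m,
        "fitness_vs_parent_child_ted": correlations,
    }
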