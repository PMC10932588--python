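"""Dataset loading, the end-to-end evaluation battery, and result writers.

The full evaluation mirrors the structure of a classifier-style test of
the uniform-information-density hypotheses on an alternation-pair corpus:
per construction and per metric it tabulates the confusion matrix, F1 and
accuracy; adds the majority-class baseline; simulates the fair-coin random
model to calibrate the F1 scale; runs chi-square tests of each classifier
against chance; and contrasts per-construction F1 vectors with the random
baseline via one-sided paired t-tests.  Everything is seeded from a single
root seed recorded in the run manifest, and re-running with the same
config and seed reproduces byte-identical CSVs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    ConfusionMatrix,
    MajorityBaseline,
    MetricEvaluation,
    SentencePair,
    construction_counts,
    evaluate_metric,
    majority_predictions,
)
from .errors import DegenerateTestError, FormatError, InvalidInputError, ValidationError
from .metrics import DEFAULT_GLOBAL_MEAN, METRIC_NAMES, MetricConfig
from .stats import (
    SimulationResult,
    TestResult,
    accuracy_from_confusion,
    f1_from_confusion,
    chisq_vs_chance,
    paired_one_sided_t,
    simulate_random_model,
)
from .surprisal import NgramModel, SurprisalProfile, read_profile_table, sequence_surprisal

logger = logging.getLogger("uidlab")

PAIR_COLUMNS = ("pair_id", "construction", "occurred", "critical_text", "baseline_text")

RESULT_FILES = (
    "f1_table.csv",
    "accuracy_table.csv",
    "chisq_table.csv",
    "simulation_summary.csv",
    "manifest.json",
)


@dataclass(frozen=True)
class RunConfig:
    """Knobs for a full evaluation run."""

    metrics: tuple[str, ...] = METRIC_NAMES
    global_mean: float = DEFAULT_GLOBAL_MEAN
    normalize: bool = True
    n_reps: int = 1000
    seed: int = 0

    def metric_config(self, metric: str) -> MetricConfig:
        return MetricConfig(metric=metric, normalize=self.normalize, global_mean=self.global_mean)


@dataclass
class ResultsBundle:
    """Everything a full evaluation produces, pre-shaped for the CSV writers."""

    config: RunConfig
    counts: dict[str, tuple[int, int]]
    evaluations: dict[str, MetricEvaluation]
    majority: dict[str, MajorityBaseline]
    simulations: dict[str, SimulationResult]
    f1_table: pd.DataFrame
    accuracy_table: pd.DataFrame
    chisq_table: pd.DataFrame
    simulation_table: pd.DataFrame
    paired_t: dict[str, dict] = field(default_factory=dict)

    @property
    def manifest(self) -> dict:
        return {
            "uidlab_version": __version__,
            "seed": self.config.seed,
            "metrics": list(self.config.metrics),
            "global_mean": self.config.global_mean,
            "normalize": self.config.normalize,
            "n_reps": self.config.n_reps,
            "n_pairs": int(sum(nc + nb for nc, nb in self.counts.values())),
            "construction_counts": {
                cons: {"n_critical": nc, "n_baseline": nb}
                for cons, (nc, nb) in sorted(self.counts.items())
            },
            "simulation_seeds": {
                cons: sim.seed for cons, sim in sorted(self.simulations.items())
            },
            "paired_t_vs_random": self.paired_t,
        }


def pairs_from_profiles(profiles: list[SurprisalProfile]) -> list[SentencePair]:
    """Join a flat profile collection into pairs keyed by sentence_id.

    Each sentence_id must contribute exactly one critical and one baseline
    profile, exactly one of which is flagged as occurred.
    """
    groups: dict[str, dict[str, SurprisalProfile]] = {}
    for prof in profiles:
        slot = groups.setdefault(prof.sentence_id, {})
        if prof.variant_role in slot:
            raise ValidationError(
                f"pair {prof.sentence_id!r}: duplicate {prof.variant_role} profile"
            )
        slot[prof.variant_role] = prof

    pairs = []
    for pair_id, slot in groups.items():
        for role in ("critical", "baseline"):
            if role not in slot:
                raise ValidationError(f"pair {pair_id!r} is missing its {role} variant")
        crit, base = slot["critical"], slot["baseline"]
        if crit.construction != base.construction:
            raise ValidationError(
                f"pair {pair_id!r}: construction labels differ "
                f"({crit.construction!r} vs {base.construction!r})"
            )
        if crit.occurred == base.occurred:
            raise ValidationError(
                f"pair {pair_id!r}: exactly one variant must be flagged as occurred"
            )
        pairs.append(
            SentencePair(
                pair_id=pair_id,
                construction=crit.construction,
                critical=crit,
                baseline=base,
                occurred="critical" if crit.occurred else "baseline",
            )
        )
    return pairs


def load_pair_dataset(
    path: str | Path,
    model: NgramModel | None = None,
    profile_table: str | Path | None = None,
) -> list[SentencePair]:
    """Load sentence pairs, attaching surprisal from the configured backend.

    Two routes: a pair TSV with raw sentence texts plus a trained n-gram
    ``model`` (whitespace tokenisation), or a per-token ``profile_table``
    whose sentence_ids are the pair_ids (texts route ignored).  Logs the
    per-construction occurred-variant balance.
    """
    if profile_table is not None:
        pairs = pairs_from_profiles(read_profile_table(profile_table))
    else:
        if model is None:
            raise InvalidInputError("need either a trained model or a profile table")
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in PAIR_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"pair dataset is missing required column {col!r}")
        pairs = []
        for row in df.itertuples(index=False):
            if row.occurred not in ("critical", "baseline"):
                raise FormatError(
                    f"pair {row.pair_id!r}: occurred must be 'critical' or 'baseline', "
                    f"got {row.occurred!r}"
                )
            texts = {"critical": row.critical_text, "baseline": row.baseline_text}
            profs = {}
            for role, text in texts.items():
                if not isinstance(text, str) or not text.strip():
                    raise ValidationError(f"pair {row.pair_id!r} is missing its {role} text")
                profs[role] = sequence_surprisal(
                    model,
                    text.split(),
                    sentence_id=row.pair_id,
                    construction=row.construction,
                    variant_role=role,
                    occurred=(row.occurred == role),
                )
            pairs.append(
                SentencePair(
                    pair_id=row.pair_id,
                    construction=row.construction,
                    critical=profs["critical"],
                    baseline=profs["baseline"],
                    occurred=row.occurred,
                )
            )

    for cons, (nc, nb) in sorted(construction_counts(pairs).items()):
        logger.info("construction %s: %d critical-occurred, %d baseline-occurred", cons, nc, nb)
    return pairs


def write_pair_dataset(pairs: list[SentencePair], path: str | Path) -> None:
    """Write the text-level pair TSV (tokens joined by spaces)."""
    rows = [
        {
            "pair_id": p.pair_id,
            "construction": p.construction,
            "occurred": p.occurred,
            "critical_text": " ".join(p.critical.tokens),
            "baseline_text": " ".join(p.baseline.tokens),
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=list(PAIR_COLUMNS)).to_csv(path, sep="\t", index=False)


def predictions_frame(evaluations: dict[str, MetricEvaluation], pairs: list[SentencePair]) -> pd.DataFrame:
    """Long-format per-pair prediction table across metrics."""
    occurred = {p.pair_id: p.occurred for p in pairs}
    rows = []
    for metric, ev in evaluations.items():
        for pred in ev.predictions:
            rows.append(
                {
                    "pair_id": pred.pair_id,
                    "metric": metric,
                    "predicted": pred.predicted,
                    "tie": pred.tie,
                    "score_critical": pred.score_critical,
                    "score_baseline": pred.score_baseline,
                    "correct": pred.predicted == occurred[pred.pair_id],
                }
            )
    return pd.DataFrame(rows)


def run_full_evaluation(pairs: list[SentencePair], config: RunConfig) -> ResultsBundle:
    """Run the whole contextualisation battery on a pair dataset."""
    if len(pairs) == 0:
        raise InvalidInputError("run_full_evaluation needs at least one pair")
    counts = construction_counts(pairs)
    constructions = sorted(counts)
    for cons, (nc, nb) in counts.items():
        if nc + nb == 0:  # pragma: no cover - construction_counts never emits empties
            logger.warning("construction %s has no pairs; skipping", cons)

    evaluations = {m: evaluate_metric(pairs, config.metric_config(m)) for m in config.metrics}
    _, majority = majority_predictions(pairs)

    # one child seed per construction, all derived from the root seed
    seed_rng = np.random.default_rng(config.seed)
    child_seeds = {
        cons: int(seed_rng.integers(0, 2**31 - 1)) for cons in constructions
    }
    simulations = {
        cons: simulate_random_model(
            counts[cons][0], counts[cons][1], config.n_reps, child_seeds[cons], cons
        )
        for cons in constructions
    }

    f1_rows, acc_rows, chi_rows, sim_rows = [], [], [], []
    for cons in constructions:
        nc, nb = counts[cons]
        f1_row: dict = {"construction": cons}
        acc_row: dict = {"construction": cons, "majority": majority[cons].accuracy}
        chi_row: dict = {"construction": cons, "n_pairs": nc + nb}
        for m in config.metrics:
            cm = evaluations[m].per_construction[cons]
            f1_row[m] = f1_from_confusion(cm)
            acc_row[m] = accuracy_from_confusion(cm)
            test = chisq_vs_chance(cm.n_correct, cm.total)
            chi_row[f"{m}_chisq"] = test.statistic
            chi_row[f"{m}_p"] = test.p_value
        sim = simulations[cons]
        sim_rows.append(
            {
                "construction": cons,
                "n_critical": nc,
                "n_baseline": nb,
                "median": sim.median,
                "q1": sim.q1,
                "q3": sim.q3,
                "mean": sim.mean,
                "sd": sim.sd,
                "n_reps": sim.n_reps,
                "seed": sim.seed,
            }
        )
        f1_rows.append(f1_row)
        acc_rows.append(acc_row)
        chi_rows.append(chi_row)

    f1_table = pd.DataFrame(f1_rows)
    accuracy_table = pd.DataFrame(acc_rows)
    chisq_table = pd.DataFrame(chi_rows)
    simulation_table = pd.DataFrame(sim_rows)

    # average row, as conventional for per-construction grids
    if len(constructions) > 1:
        for table in (f1_table, accuracy_table):
            mean_row = {"construction": "Average"}
            for col in table.columns:
                if col != "construction":
                    mean_row[col] = table[col].mean()
            table.loc[len(table)] = mean_row

    paired_t: dict[str, dict] = {}
    if len(constructions) >= 2:
        random_vector = [simulations[c].mean for c in constructions]
        for m in config.metrics:
            model_vector = [
                f1_from_confusion(evaluations[m].per_construction[c]) for c in constructions
            ]
            try:
                res: TestResult = paired_one_sided_t(model_vector, random_vector)
                paired_t[m] = {
                    "t": round(res.statistic, 3),
                    "df": res.df,
                    "p": round(res.p_value, 3),
                    "degenerate": res.degenerate,
                }
            except DegenerateTestError as exc:
                paired_t[m] = {"error": str(exc)}

    return ResultsBundle(
        config=config,
        counts=counts,
        evaluations=evaluations,
        majority=majority,
        simulations=simulations,
        f1_table=f1_table,
        accuracy_table=accuracy_table,
        chisq_table=chisq_table,
        simulation_table=simulation_table,
        paired_t=paired_t,
    )


def write_results(bundle: ResultsBundle, out_dir: str | Path) -> list[Path]:
    """Write the five-file result set; deterministic for a fixed config + seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "f1_table.csv": bundle.f1_table,
        "accuracy_table.csv": bundle.accuracy_table,
        "chisq_table.csv": bundle.chisq_table,
        "simulation_summary.csv": bundle.simulation_table,
    }
    written = []
    for name, table in tables.items():
        path = out / name
        table.to_csv(path, index=False, float_format="%.3f")
        written.append(path)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)
    return written


def plot_simulation(simulations: dict[str, SimulationResult], path: str | Path) -> None:
    """Box plots of the random-model F1 distributions, one box per construction.

    Requires matplotlib (optional dependency); the dashed line marks 0.5,
    the F1 a fair coin attains on a perfectly balanced dataset.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    constructions = sorted(simulations)
    fig, ax = plt.subplots(figsize=(1.2 * max(4, len(constructions)), 4))
    ax.boxplot(
        [simulations[c].f1_values for c in constructions], tick_labels=constructions
    )
    ax.axhline(0.5, linestyle="--", color="grey")
    ax.set_ylabel("F1 (random model)")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
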