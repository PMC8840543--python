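"""End-to-end orchestration and reporting.

simulate -> filter/segment -> extract 62 features -> baseline (all-ones
weights) -> NSGA-III optimisation of the weight genome -> best-individual
selection -> accuracy table, objective scatter, weight bars and confusion
matrices.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import EvolutionConfig, FilterSpec, GeneratorConfig, InductorSpec, WindowSpec
from .features import FEATURE_NAMES, extract_matrix
from .inductor import (
    ConfusionMatrix,
    TrainingCounter,
    cv_accuracy,
    evaluate_objectives,
    export_confusion,
    make_folds,
)
from .nsga3 import Individual, Population, evolve
from .preprocessing import preprocess
from .simulate import generate_dataset
from .types import TASKS, ObjectiveVector, RawSequence

logger = logging.getLogger(__name__)

TASK_DISPLAY = {"gender": "Gender", "age_group": "Age", "activity": "HAR"}


def sequences_to_matrix(
    sequences: list[RawSequence],
    filter_spec: FilterSpec | None = None,
    window_spec: WindowSpec | None = None,
) -> pd.DataFrame:
    """Filter, segment and featurize a collection of sequences."""
    windows = []
    for seq in sequences:
        windows.extend(preprocess(seq, filter_spec, window_spec))
    if not windows:
        raise ValueError("no windows produced; sequences shorter than one window?")
    return extract_matrix(windows)


def chance_levels(matrix: pd.DataFrame) -> dict[str, float]:
    """Expected accuracy of a random-choice classifier per task: 1/#classes."""
    return {task: 1.0 / matrix[task].nunique() for task in TASKS}


def run_baseline(
    matrix: pd.DataFrame,
    spec: InductorSpec,
    folds: np.ndarray | None = None,
    counter: TrainingCounter | None = None,
    n_jobs: int = 1,
) -> tuple[dict[str, float], dict[str, ConfusionMatrix]]:
    """Evaluate the all-ones genome (unweighted features): the 'Initial'
    column of the accuracy table."""
    if folds is None:
        folds = make_folds(matrix, spec)
    ones = np.ones(len(FEATURE_NAMES))
    accs, confs = {}, {}
    for task in TASKS:
        accs[task], confs[task] = cv_accuracy(
            matrix, ones, task, spec, folds=folds, counter=counter, n_jobs=n_jobs
        )
    return accs, confs


def make_fitness(
    matrix: pd.DataFrame,
    spec: InductorSpec,
    folds: np.ndarray,
    counter: TrainingCounter | None = None,
    n_jobs: int = 1,
):
    """Fitness closure for the optimizer.

    Maintains its own evaluation index so each fresh candidate gets a
    distinct, deterministic set of classifier seeds.
    """
    state = {"eval_index": 0}

    def fitness(genome: np.ndarray) -> ObjectiveVector:
        idx = state["eval_index"]
        state["eval_index"] += 1
        return evaluate_objectives(
            matrix, genome, spec,
            folds=folds, counter=counter, eval_index=idx, n_jobs=n_jobs,
        )

    return fitness


def optimize(
    matrix: pd.DataFrame,
    inductor_spec: InductorSpec,
    evolution_config: EvolutionConfig,
    counter: TrainingCounter | None = None,
    n_jobs: int = 1,
) -> list[Population]:
    """Run the NSGA-III search over feature-weight genomes."""
    folds = make_folds(matrix, inductor_spec)
    fitness = make_fitness(matrix, inductor_spec, folds, counter, n_jobs)
    return evolve(evolution_config, fitness)


def select_best_individual(front: list[Individual]) -> Individual:
    """Pick the overall-best member of a nondominated front.

    Minimises the Chebyshev (max-coordinate) distance to the front's ideal
    point after per-objective min-max normalization over the front;
    deterministic tie-break by lowest index.
    """
    if not front:
        raise ValueError("select_best_individual requires a non-empty front")
    F = np.vstack([ind.objectives for ind in front])
    lo = F.min(axis=0)
    extent = F.max(axis=0) - lo
    extent = np.where(extent > 1e-12, extent, 1.0)
    chebyshev = ((F - lo) / extent).max(axis=1)
    return front[int(np.argmin(chebyshev))]


@dataclass
class RunReport:
    """All reporting quantities of one full run (accuracies as fractions)."""

    baseline_acc: dict[str, float]
    best_acc: dict[str, float]
    chance: dict[str, float]
    best_genome: np.ndarray
    baseline_confusions: dict[str, ConfusionMatrix]
    best_confusions: dict[str, ConfusionMatrix]
    final_objectives: np.ndarray  # final-population objective vectors
    n_trainings: int = 0

    @property
    def diff_best_minus_initial(self) -> dict[str, float]:
        return {t: self.best_acc[t] - self.baseline_acc[t] for t in TASKS}

    @property
    def diff_best_minus_chance(self) -> dict[str, float]:
        return {t: self.best_acc[t] - self.chance[t] for t in TASKS}

    def weights(self) -> pd.Series:
        return pd.Series(self.best_genome, index=list(FEATURE_NAMES), name="weight")

    def accuracy_table(self) -> pd.DataFrame:
        """Accuracy table in percent, one decimal: Initial, Best, Diff (B-I),
        Random, Diff (B-R) per task."""
        rows = []
        for task in TASKS:
            initial = round(100 * self.baseline_acc[task], 1)
            best = round(100 * self.best_acc[task], 1)
            chance = round(100 * self.chance[task], 1)
            rows.append(
                {
                    "Classifier": TASK_DISPLAY[task],
                    "Initial (I) Acc.": initial,
                    "Best (B) Acc.": best,
                    # differences recomputed from the printed columns so the
                    # table is internally consistent at one decimal
                    "Diff. (B-I)": round(best - initial, 1),
                    "Random": chance,
                    "Diff. (B-R)": round(best - chance, 1),
                }
            )
        return pd.DataFrame(rows)

    def objective_scatter(self) -> pd.DataFrame:
        """Final-population accuracies for the 2-D scatter projections
        (gender vs. action and age vs. action)."""
        F = self.final_objectives
        return pd.DataFrame(
            {
                "gender_accuracy": F[:, 0],
                "age_accuracy": F[:, 1],
                "action_accuracy": 1.0 - F[:, 2],
            }
        )


def build_report(
    matrix: pd.DataFrame,
    inductor_spec: InductorSpec,
    history: list[Population],
    folds: np.ndarray | None = None,
    counter: TrainingCounter | None = None,
    n_jobs: int = 1,
) -> RunReport:
    """Assemble the run report: baseline vs. best accuracies, chance levels,
    the selected genome and all six confusion matrices."""
    if folds is None:
        folds = make_folds(matrix, inductor_spec)
    baseline_acc, baseline_confs = run_baseline(
        matrix, inductor_spec, folds=folds, counter=counter, n_jobs=n_jobs
    )
    final = history[-1]
    best = select_best_individual(final.front(0))
    best_acc, best_confs = {}, {}
    for task in TASKS:
        best_acc[task], best_confs[task] = cv_accuracy(
            matrix, best.genome, task, inductor_spec,
            folds=folds, counter=counter, eval_index=10**6, n_jobs=n_jobs,
        )
    return RunReport(
        baseline_acc=baseline_acc,
        best_acc=best_acc,
        chance=chance_levels(matrix),
        best_genome=best.genome.copy(),
        baseline_confusions=baseline_confs,
        best_confusions=best_confs,
        final_objectives=final.objectives(),
        n_trainings=counter.count if counter is not None else 0,
    )


def save_history(history: list[Population], outdir: str | Path) -> None:
    """Per-generation run artifacts: genomes, objectives and front ranks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for pop in history:
        tag = f"gen{pop.generation:03d}"
        pd.DataFrame(pop.genomes(), columns=list(FEATURE_NAMES)).to_csv(
            outdir / f"{tag}_genomes.csv", index=False
        )
        obj = pd.DataFrame(
            pop.objectives(), columns=["gender_obj", "age_obj", "action_obj"]
        )
        obj["rank"] = [ind.rank for ind in pop.individuals]
        obj.to_csv(outdir / f"{tag}_objectives.csv", index=False)


def save_report(report: RunReport, outdir: str | Path, plots: bool = True) -> None:
    """Write the report tables (CSV) and, optionally, the standard plots."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.accuracy_table().to_csv(outdir / "accuracy_table.csv", index=False)
    report.weights().to_csv(outdir / "best_weights.csv")
    report.objective_scatter().to_csv(outdir / "final_front_accuracies.csv", index=False)
    for task in TASKS:
        export_confusion(
            report.baseline_confusions[task],
            outdir / f"confusion_{task}_baseline_counts.csv",
            outdir / f"confusion_{task}_baseline_percent.csv",
        )
        export_confusion(
            report.best_confusions[task],
            outdir / f"confusion_{task}_best_counts.csv",
            outdir / f"confusion_{task}_best_percent.csv",
        )
    if plots:
        save_plots(report, outdir)


def save_plots(report: RunReport, outdir: str | Path) -> None:
    """Objective-scatter projections, log-scale weight bars and confusion
    heatmaps as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    scatter = report.objective_scatter()

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, xcol in zip(axes, ("gender_accuracy", "age_accuracy")):
        ax.scatter(scatter[xcol], scatter["action_accuracy"], marker="x", c="k",
                   label="population")
        ax.scatter(
            [report.baseline_acc["gender" if xcol.startswith("gender") else "age_group"]],
            [report.baseline_acc["activity"]],
            c="r", label="initial (all ones)",
        )
        ax.scatter(
            [report.best_acc["gender" if xcol.startswith("gender") else "age_group"]],
            [report.best_acc["activity"]],
            c="g", label="best",
        )
        ax.set_xlabel(xcol.replace("_", " "))
        ax.set_ylabel("action accuracy")
    axes[0].legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "final_front_scatter.png", dpi=120)
    plt.close(fig)

    weights = report.weights()
    fig, ax = plt.subplots(figsize=(12, 4))
    ax.bar(range(len(weights)), np.maximum(weights.values, 1e-6))
    ax.set_yscale("log")
    ax.set_xticks(range(len(weights)))
    ax.set_xticklabels(weights.index, rotation=90, fontsize=5)
    ax.set_ylabel("weight (log)")
    fig.tight_layout()
    fig.savefig(outdir / "best_weights.png", dpi=120)
    plt.close(fig)

    for task in TASKS:
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, (label, conf) in zip(
            axes,
            (("baseline", report.baseline_confusions[task]),
             ("best", report.best_confusions[task])),
        ):
            ax.imshow(conf.row_percentages().values, cmap="Greys", vmin=0, vmax=100)
            ax.set_title(f"{TASK_DISPLAY[task]} — {label}")
            ax.set_xlabel("predicted")
            ax.set_ylabel("true")
        fig.tight_layout()
        fig.savefig(outdir / f"confusion_{task}.png", dpi=120)
        plt.close(fig)


def run_full(
    generator_config: GeneratorConfig,
    filter_spec: FilterSpec | None = None,
    window_spec: WindowSpec | None = None,
    inductor_spec: InductorSpec | None = None,
    evolution_config: EvolutionConfig | None = None,
    outdir: str | Path | None = None,
    n_jobs: int = 1,
    plots: bool = True,
) -> RunReport:
    """Full pipeline from one seed: simulate, featurize, optimise, report.

    Bit-reproducible given identical configs.
    """
    filter_spec = filter_spec or FilterSpec()
    window_spec = window_spec or WindowSpec()
    inductor_spec = inductor_spec or InductorSpec()
    evolution_config = evolution_config or EvolutionConfig()

    sequences = generate_dataset(generator_config)
    matrix = sequences_to_matrix(sequences, filter_spec, window_spec)
    folds = make_folds(matrix, inductor_spec)
    counter = TrainingCounter()
    fitness = make_fitness(matrix, inductor_spec, folds, counter, n_jobs)
    history = evolve(evolution_config, fitness)
    logger.info("optimisation done after %d trainings", counter.count)
    report = build_report(
        matrix, inductor_spec, history, folds=folds, counter=counter, n_jobs=n_jobs
    )
    if outdir is not None:
        outdir = Path(outdir)
        save_report(report, outdir, plots=plots)
        save_history(history, outdir / "history")
        meta = {
            "generator": dataclasses.asdict(generator_config),
            "filter": dataclasses.asdict(filter_spec),
            "window": dataclasses.asdict(window_spec),
            "inductor": dataclasses.asdict(inductor_spec),
            "evolution": dataclasses.asdict(evolution_config),
            "n_trainings": counter.count,
        }
        (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2))
    return report
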