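"""Experiment protocol: split, model selection, evaluation, report arithmetic.

For each pesticide group the pipeline holds out a fixed number of test
recordings per class (30/30 for pyrethroids and carbamates, 50/50 for
organophosphates), standardizes the meta-features on the remaining training
rows, trains every architecture/minimizer candidate in a grid with restarts,
ranks the candidates by validation error, and evaluates only the winner on
the untouched test set.  Per-class correct counts are reported as in a
confusion table (control row, positive row, overall), and the three group
reports pool sample-weighted into a single overall success rate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ann_core import (
    NetworkModel,
    NetworkSpec,
    TrainConfig,
    classify,
    train,
)
from .errors import NumericalError, ValidationError
from .features import (
    Standardizer,
    apply_standardizer,
    build_feature_matrix,
    fit_standardizer,
)
from .signal_synth import (
    GROUPS,
    SimulatorConfig,
    TimeSeriesRecord,
    covariate_benefit_config,
    generate_paper_scale_datasets,
    generate_sample_set,
)

#: per-group test holdout per class used by the full protocol
PROTOCOL_TEST_PER_CLASS = {
    "pyrethroid": 30,
    "organophosphate": 50,
    "carbamate": 30,
}


# -- domain types -------------------------------------------------------------


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint, exhaustive train/test index partition with a fixed per-class
    test holdout."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    n_test_per_class: int
    seed: int


@dataclass(frozen=True)
class ClassificationReport:
    """Per-class correct counts in the layout of the published tables."""

    n_neg_correct: int
    n_neg_total: int
    n_pos_correct: int
    n_pos_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_neg_correct <= self.n_neg_total):
            raise ValidationError("negative counts out of range")
        if not (0 <= self.n_pos_correct <= self.n_pos_total):
            raise ValidationError("positive counts out of range")
        if self.n_neg_total + self.n_pos_total == 0:
            raise ValidationError("report needs at least one test sample")

    @property
    def neg_rate(self) -> float:
        return 100.0 * self.n_neg_correct / self.n_neg_total if self.n_neg_total else float("nan")

    @property
    def pos_rate(self) -> float:
        return 100.0 * self.n_pos_correct / self.n_pos_total if self.n_pos_total else float("nan")

    @property
    def n_correct(self) -> int:
        return self.n_neg_correct + self.n_pos_correct

    @property
    def n_total(self) -> int:
        return self.n_neg_total + self.n_pos_total

    @property
    def overall_rate(self) -> float:
        return 100.0 * self.n_correct / self.n_total

    def to_dict(self) -> dict:
        return {
            "n_neg_correct": self.n_neg_correct,
            "n_neg_total": self.n_neg_total,
            "n_pos_correct": self.n_pos_correct,
            "n_pos_total": self.n_pos_total,
            "neg_rate": self.neg_rate,
            "pos_rate": self.pos_rate,
            "overall_rate": self.overall_rate,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClassificationReport":
        return cls(
            n_neg_correct=int(d["n_neg_correct"]),
            n_neg_total=int(d["n_neg_total"]),
            n_pos_correct=int(d["n_pos_correct"]),
            n_pos_total=int(d["n_pos_total"]),
        )

    def render(self) -> str:
        # displayed percentages rounded to one decimal; counts stay exact
        return (
            f"Control (negative) sample set  {self.n_neg_correct}/{self.n_neg_total}"
            f" ({self.neg_rate:.1f}%)\n"
            f"Positive sample set            {self.n_pos_correct}/{self.n_pos_total}"
            f" ({self.pos_rate:.1f}%)\n"
            f"Overall                        {self.n_correct}/{self.n_total}"
            f" ({self.overall_rate:.1f}%)"
        )


@dataclass(frozen=True)
class Candidate:
    """One architecture/minimizer combination of the trial-and-error grid."""

    name: str
    spec: NetworkSpec
    algorithm: str


@dataclass
class TrainedClassifier:
    """A trained network together with the standardizer fitted on its
    training features; the deployable unit."""

    model: NetworkModel
    standardizer: Standardizer
    candidate: Candidate
    val_error: float

    @property
    def include_covariates(self) -> bool:
        return self.model.spec.n_inputs == 14


@dataclass
class LeaderboardEntry:
    candidate: Candidate
    val_error: float
    classifier: TrainedClassifier


@dataclass
class SelectionResult:
    best: TrainedClassifier
    leaderboard: list[LeaderboardEntry]


def default_grid(n_inputs: int = 14) -> list[Candidate]:
    """The six named architecture/minimizer combinations of the trial-and-
    error search: the initial 10-node tanh quasi-Newton network and the five
    logistic Levenberg-Marquardt networks that won per group."""
    def cand(name, hidden, activation, algorithm):
        return Candidate(
            name=name,
            spec=NetworkSpec(
                n_inputs=n_inputs,
                hidden_layers=hidden,
                hidden_activation=activation,
            ),
            algorithm=algorithm,
        )

    return [
        cand("1HL-10-tanh-quasinewton", (10,), "tanh", "quasi_newton"),
        cand("ANN-P1-1HL-23-logistic-lm", (23,), "logistic", "levenberg_marquardt"),
        cand("ANN-P2-2HL-5-15-logistic-lm", (5, 15), "logistic", "levenberg_marquardt"),
        cand("ANN-P3-2HL-10-10-logistic-lm", (10, 10), "logistic", "levenberg_marquardt"),
        cand("2HL-4-19-logistic-lm", (4, 19), "logistic", "levenberg_marquardt"),
        cand("1HL-10-logistic-lm", (10,), "logistic", "levenberg_marquardt"),
    ]


# -- operations ---------------------------------------------------------------


def split_dataset(
    dataset: Sequence[TimeSeriesRecord], n_test_per_class: int, seed: int
) -> DatasetSplit:
    """Stratified random holdout of ``n_test_per_class`` recordings per label,
    uniform without replacement; the remainder forms the training set."""
    labels = np.array([r.label for r in dataset])
    rng = np.random.default_rng(seed)
    test_parts = []
    for cls in (0, 1):
        members = np.flatnonzero(labels == cls)
        if members.size <= n_test_per_class:
            raise ValidationError(
                f"class {cls} has {members.size} members; cannot hold out "
                f"{n_test_per_class}"
            )
        test_parts.append(rng.choice(members, size=n_test_per_class, replace=False))
    test_idx = np.sort(np.concatenate(test_parts))
    mask = np.ones(len(dataset), dtype=bool)
    mask[test_idx] = False
    return DatasetSplit(
        train_indices=np.flatnonzero(mask),
        test_indices=test_idx,
        n_test_per_class=n_test_per_class,
        seed=seed,
    )


def _train_candidate(
    candidate: Candidate,
    train_records: Sequence[TimeSeriesRecord],
    config: TrainConfig,
) -> TrainedClassifier:
    include_covariates = candidate.spec.n_inputs == 14
    X, y = build_feature_matrix(train_records, include_covariates)
    standardizer = fit_standardizer(X)
    result = train(
        candidate.spec,
        apply_standardizer(standardizer, X),
        y,
        dataclasses.replace(config, algorithm=candidate.algorithm),
    )
    return TrainedClassifier(
        model=result.model,
        standardizer=standardizer,
        candidate=candidate,
        val_error=result.val_error,
    )


def select_model(
    train_records: Sequence[TimeSeriesRecord],
    grid: Sequence[Candidate],
    config: TrainConfig | None = None,
) -> SelectionResult:
    """Trial-and-error model selection over the candidate grid.

    Every candidate is trained (with restarts) on the training records; the
    leaderboard ranks candidates by the validation error of their returned
    snapshot and the winner is the entry with the lowest validation error.
    The test set plays no role here.
    """
    grid = list(grid)
    if not grid:
        raise ValidationError("candidate grid must be non-empty")
    config = (config or TrainConfig()).validate()
    entries = []
    failures = []
    for offset, candidate in enumerate(grid):
        # fixed per-candidate seed offsets keep the full run reproducible
        cand_config = dataclasses.replace(config, seed=config.seed + 1000 * offset)
        try:
            classifier = _train_candidate(candidate, train_records, cand_config)
        except NumericalError as exc:
            failures.append(f"{candidate.name}: {exc}")
            continue
        entries.append(
            LeaderboardEntry(
                candidate=candidate,
                val_error=classifier.val_error,
                classifier=classifier,
            )
        )
    if not entries:
        raise NumericalError(
            "every candidate failed to train: " + "; ".join(failures)
        )
    entries.sort(key=lambda e: e.val_error)
    return SelectionResult(best=entries[0].classifier, leaderboard=entries)


def evaluate(
    model: NetworkModel,
    test_records: Sequence[TimeSeriesRecord],
    standardizer: Standardizer,
) -> ClassificationReport:
    """Classify each test record and tabulate correct counts per true class."""
    test_records = list(test_records)
    if not test_records:
        raise ValidationError("test set must be non-empty")
    include_covariates = model.spec.n_inputs == 14
    X, y = build_feature_matrix(test_records, include_covariates)
    predictions = classify(model, apply_standardizer(standardizer, X))
    y = y.astype(int)
    neg = y == 0
    pos = y == 1
    return ClassificationReport(
        n_neg_correct=int(np.sum(predictions[neg] == 0)),
        n_neg_total=int(np.sum(neg)),
        n_pos_correct=int(np.sum(predictions[pos] == 1)),
        n_pos_total=int(np.sum(pos)),
    )


def evaluate_classifier(
    classifier: TrainedClassifier, test_records: Sequence[TimeSeriesRecord]
) -> ClassificationReport:
    return evaluate(classifier.model, test_records, classifier.standardizer)


def pooled_rate(reports: Iterable[ClassificationReport]) -> float:
    """Sample-weighted pooled success percentage across group reports:
    100 * (sum of correct) / (sum of tested)."""
    reports = list(reports)
    if not reports:
        raise ValidationError("pooled rate needs at least one report")
    correct = sum(r.n_correct for r in reports)
    total = sum(r.n_total for r in reports)
    return 100.0 * correct / total


# -- full protocol ------------------------------------------------------------


@dataclass
class GroupResult:
    group: str
    split: DatasetSplit
    selection: SelectionResult
    report: ClassificationReport

    @property
    def n_train(self) -> int:
        return int(self.train_size)

    @property
    def train_size(self) -> int:
        return self.split.train_indices.size


@dataclass
class ProtocolResult:
    groups: dict[str, GroupResult]
    pooled: float
    seed: int

    @property
    def reports(self) -> list[ClassificationReport]:
        return [g.report for g in self.groups.values()]

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "seed": self.seed,
            "groups": {
                name: {
                    "winner": g.selection.best.candidate.name,
                    "n_train": g.train_size,
                    "n_test": g.report.n_total,
                    "report": g.report.to_dict(),
                    "leaderboard": [
                        {"candidate": e.candidate.name, "val_error": e.val_error}
                        for e in g.selection.leaderboard
                    ],
                }
                for name, g in self.groups.items()
            },
            "pooled_rate": self.pooled,
            "pooled_n": sum(r.n_total for r in self.reports),
        }

    def render(self) -> str:
        lines = []
        for name, g in self.groups.items():
            lines.append(f"== {name} ==")
            lines.append(
                f"training size {g.train_size}, winner "
                f"{g.selection.best.candidate.name} "
                f"(val MSE {g.selection.best.val_error:.4f})"
            )
            lines.append(g.report.render())
            lines.append("")
        total = sum(r.n_total for r in self.reports)
        correct = sum(r.n_correct for r in self.reports)
        lines.append(
            f"Pooled overall success rate: {correct}/{total} ({self.pooled:.1f}%)"
        )
        return "\n".join(lines)


def protocol_train_config(seed: int = 0) -> TrainConfig:
    """Training configuration used by the full protocol run: modest restart
    and iteration counts keep the 18-candidate sweep tractable on one core."""
    return TrainConfig(
        max_iterations=80,
        patience=15,
        n_restarts=2,
        seed=seed,
    )


@dataclass
class CovariateBenefitResult:
    """Paired 12- vs 14-input test accuracies over several seeds."""

    accuracy_12: list[float]
    accuracy_14: list[float]

    @property
    def mean_12(self) -> float:
        return float(np.mean(self.accuracy_12))

    @property
    def mean_14(self) -> float:
        return float(np.mean(self.accuracy_14))

    @property
    def benefit(self) -> float:
        """Mean accuracy gain (percentage points) from adding the covariates."""
        return self.mean_14 - self.mean_12


def covariate_benefit_experiment(
    seeds: Sequence[int],
    sim_config: SimulatorConfig | None = None,
    group: str = "pyrethroid",
    n_control: int = 300,
    n_positive: int = 300,
    n_test_per_class: int = 30,
    train_config: TrainConfig | None = None,
) -> CovariateBenefitResult:
    """Measure the value of the cell age / generation inputs.

    For each seed, one covariate-modulated dataset is generated and split
    once; the best 12-input and best 14-input models are then selected from
    the same architecture grid on identical training records and evaluated on
    the identical test records, so the input set is the only difference.
    Defaults use :func:`covariate_benefit_config`, where the dose acts on the
    covariate-confounded amplitude channel (see its docstring).
    """
    sim_config = (sim_config or covariate_benefit_config()).validate()
    acc: dict[int, list[float]] = {12: [], 14: []}
    for seed in seeds:
        records = generate_sample_set(
            group, n_control, n_positive, sim_config, np.random.default_rng(seed)
        )
        split = split_dataset(records, n_test_per_class, seed=seed + 1)
        train_records = [records[i] for i in split.train_indices]
        test_records = [records[i] for i in split.test_indices]
        for n_inputs in (12, 14):
            cfg = train_config or protocol_train_config()
            cfg = dataclasses.replace(cfg, seed=seed + 2)
            selection = select_model(train_records, default_grid(n_inputs), cfg)
            report = evaluate_classifier(selection.best, test_records)
            acc[n_inputs].append(report.overall_rate)
    return CovariateBenefitResult(accuracy_12=acc[12], accuracy_14=acc[14])


def run_paper_protocol(
    sim_config: SimulatorConfig | None = None,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    grid: Sequence[Candidate] | None = None,
    include_covariates: bool = True,
) -> ProtocolResult:
    """Full pipeline on synthetic data: generate the three full-scale group
    datasets, hold out the per-group test sets, select a model per group from
    the candidate grid, evaluate, and pool the three reports.

    Per-group seeds are derived from the master ``seed`` by fixed offsets so
    the whole run is reproducible from one integer.
    """
    sim_config = (sim_config or SimulatorConfig()).validate()
    n_inputs = 14 if include_covariates else 12
    grid = list(grid) if grid is not None else default_grid(n_inputs)
    datasets = generate_paper_scale_datasets(sim_config, np.random.default_rng(seed))
    groups: dict[str, GroupResult] = {}
    for offset, group in enumerate(GROUPS):
        records = datasets[group]
        group_seed = seed + 10_000 * (offset + 1)
        try:
            split = split_dataset(
                records, PROTOCOL_TEST_PER_CLASS[group], seed=group_seed
            )
            cfg = train_config or protocol_train_config()
            cfg = dataclasses.replace(cfg, seed=group_seed)
            train_records = [records[i] for i in split.train_indices]
            selection = select_model(train_records, grid, cfg)
            report = evaluate_classifier(
                selection.best, [records[i] for i in split.test_indices]
            )
        except (ValidationError, NumericalError) as exc:
            raise type(exc)(f"protocol stage '{group}': {exc}") from exc
        groups[group] = GroupResult(
            group=group, split=split, selection=selection, report=report
        )
    return ProtocolResult(
        groups=groups,
        pooled=pooled_rate([g.report for g in groups.values()]),
        seed=seed,
    )
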