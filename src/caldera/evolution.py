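"""Evolving classifiers: AUC-driven CGP search and best-of-runs selection.

A candidate genome scores a movement segment by evaluating its expression
on every overlapping 32-sample window of the magnitude series and taking
the mean — the mean occurrence of the movement pattern the expression
describes.  Fitness is the AUC of those segment scores when discriminating
grade 3 and 4 dyskinesia segments from segments with no dyskinesia; items
with 0 < grade < 3 are excluded from training, which in practice yields
more robust classifiers than training across the clinically ambiguous
middle grades.

Training runs a generational EA (tournament selection, uniform node-wise
crossover, point mutation, single-genome elitism) and is repeated over
independent seeds; the deployment model is the run whose best genome has
the highest AUC on the held-aside test split.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import cgp
from .evaluation import auc
from .signal import (
    MagnitudeSeries,
    Recording,
    WINDOW_WIDTH,
    extract_windows,
    long_term_spectrum,
    magnitude,
    short_term_spectra,
)


class FeatureMode(str, Enum):
    """Input representation presented to the 32 expression terminals."""

    TIME = "time"
    SPECTRAL_LONG = "spectral_long"
    SPECTRAL_SHORT = "spectral_short"


@dataclass
class EvolutionConfig:
    """EA settings; defaults follow the deployed training protocol
    (population 200, generation limit 100) — scale down for quick runs."""

    population_size: int = 200
    generations: int = 100
    mutation_rate: float = 0.02
    crossover_prob: float = 0.9
    tournament_size: int = 4
    elitism: int = 1
    feature_mode: FeatureMode = FeatureMode.TIME
    seed: int = 0
    geometry: cgp.CgpGeometry = field(default_factory=cgp.CgpGeometry)

    def validate(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for p in (self.mutation_rate, self.crossover_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 1 <= self.tournament_size <= self.population_size:
            raise ValueError("tournament_size must lie in [1, population_size]")
        if not 0 <= self.elitism < self.population_size:
            raise ValueError("elitism must lie in [0, population_size)")


@dataclass
class ClassifierModel:
    """A trained classifier: genome, feature mode and (optionally) the
    fitted grade thresholds on its output range."""

    genome: cgp.CgpGenome
    feature_mode: FeatureMode
    thresholds: Optional[Dict[str, float]] = None
    provenance: Dict = field(default_factory=dict)


@dataclass
class SegmentItem:
    """A labelled movement sample ready for scoring: the magnitude series
    of one labelled interval, its (possibly fractional) grade and tags."""

    series: np.ndarray
    grade: float
    activity: str = ""
    item_id: str = ""
    sample_rate: float = 100.0


@dataclass
class TrainingSet:
    """Feature matrices for a list of segment items under one feature mode.

    ``matrix`` stacks every item's feature rows; ``row_item`` maps each row
    back to its item.  In time mode an item contributes its L - 31 windows;
    in spectral_short mode the per-window density vectors; in spectral_long
    mode a single 32-bin density row.
    """

    items: List[SegmentItem]
    feature_mode: FeatureMode
    matrix: np.ndarray
    row_item: np.ndarray

    @property
    def grades(self) -> np.ndarray:
        return np.array([it.grade for it in self.items])

    @property
    def activities(self) -> List[str]:
        return [it.activity for it in self.items]


def item_features(series: np.ndarray, feature_mode: FeatureMode, sample_rate: float = 100.0) -> np.ndarray:
    """Feature rows for one magnitude series under the given mode."""
    series = np.asarray(series, dtype=float)
    mode = FeatureMode(feature_mode)
    if mode is FeatureMode.TIME:
        return extract_windows(series).windows
    if mode is FeatureMode.SPECTRAL_SHORT:
        return short_term_spectra(extract_windows(series).windows, sample_rate)
    return long_term_spectrum(series, sample_rate).densities[None, :]


def build_training_set(
    items: Sequence[SegmentItem], feature_mode: FeatureMode
) -> TrainingSet:
    """Precompute and stack feature rows for a list of segment items."""
    mode = FeatureMode(feature_mode)
    blocks, owners = [], []
    for i, it in enumerate(items):
        feats = item_features(it.series, mode, it.sample_rate)
        blocks.append(feats)
        owners.append(np.full(feats.shape[0], i, dtype=np.int64))
    return TrainingSet(
        items=list(items),
        feature_mode=mode,
        matrix=np.vstack(blocks),
        row_item=np.concatenate(owners),
    )


def items_from_study(study, split: str, channel_group: str = "accel") -> List[SegmentItem]:
    """Segment items (magnitude series + labels) for one split of a
    generated synthetic study."""
    out = []
    for it in study.split(split):
        mag = magnitude(it.recording, channel_group)
        out.append(
            SegmentItem(
                series=mag.values,
                grade=it.label.grade,
                activity=it.label.activity,
                item_id=it.recording.recording_id,
                sample_rate=it.recording.sample_rate,
            )
        )
    return out


def segment_score(
    genome: cgp.CgpGenome,
    segment,
    feature_mode: FeatureMode = FeatureMode.TIME,
    sample_rate: float = 100.0,
) -> float:
    """Classifier output for one movement segment.

    Time / spectral_short: mean of the expression over all L - 31 windows
    (respectively their spectra); spectral_long: a single evaluation on the
    whole-segment density vector.

    Raises
    ------
    ValueError
        ``"no windows"`` if the segment is too short to yield one window.
    """
    if isinstance(segment, MagnitudeSeries):
        series, sample_rate = segment.values, segment.sample_rate
    elif isinstance(segment, SegmentItem):
        series, sample_rate = segment.series, segment.sample_rate
    else:
        series = np.asarray(segment, dtype=float)
    if series.shape[0] < WINDOW_WIDTH:
        raise ValueError("no windows: segment shorter than one window")
    feats = item_features(series, feature_mode, sample_rate)
    return float(cgp.evaluate_batch(genome, feats).mean())


def training_mask(grades: np.ndarray) -> np.ndarray:
    """True for items that enter fitness: grade exactly 0 or grade >= 3.

    Rater-averaged fractional grades strictly between 0 and 3 (e.g. 2.5)
    are excluded; 3.5 is included."""
    grades = np.asarray(grades, dtype=float)
    return (grades == 0.0) | (grades >= 3.0)


def _segment_scores_all(genome: cgp.CgpGenome, ts: TrainingSet) -> np.ndarray:
    """Per-item mean expression output, vectorised over the stacked rows."""
    outputs = cgp.evaluate_batch(genome, ts.matrix)
    sums = np.bincount(ts.row_item, weights=outputs, minlength=len(ts.items))
    counts = np.bincount(ts.row_item, minlength=len(ts.items))
    return sums / counts


def fitness(genome: cgp.CgpGenome, training_set: TrainingSet, feature_mode=None) -> float:
    """Training fitness: AUC of segment scores, grade 0 vs grade >= 3.

    Raises
    ------
    ValueError
        ``"degenerate training set"`` when either class is empty.
    """
    if feature_mode is not None and FeatureMode(feature_mode) != training_set.feature_mode:
        raise ValueError("feature_mode disagrees with the prepared training set")
    grades = training_set.grades
    mask = training_mask(grades)
    labels = (grades[mask] >= 3.0).astype(int)
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("degenerate training set: a grade class is empty")
    scores = _segment_scores_all(genome, training_set)[mask]
    return auc(scores, labels)


@dataclass
class RunResult:
    """Outcome of one evolutionary run."""

    best_genome: cgp.CgpGenome
    best_fitness: float
    best_fitness_history: List[float]
    seed: int
    test_auc: Optional[float] = None


def evolve(config: EvolutionConfig, training_set: TrainingSet) -> RunResult:
    """One generational evolutionary run; bit-reproducible under its seed.

    Each generation: elites carried over unchanged, then offspring bred by
    tournament selection, crossover with ``crossover_prob``, and per-gene
    mutation.  ``best_fitness_history`` records the best-so-far training
    AUC at generation 0 (the random population) and after each of the
    ``generations`` iterations; with elitism >= 1 it is non-decreasing.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pop = [cgp.random_genome(config.geometry, rng) for _ in range(config.population_size)]
    fits = np.array([fitness(g, training_set) for g in pop])
    history = [float(fits.max())]

    def tournament() -> int:
        idx = rng.integers(0, config.population_size, size=config.tournament_size)
        return int(idx[np.argmax(fits[idx])])

    for _gen in range(config.generations):
        order = np.argsort(fits)[::-1]
        new_pop: List[cgp.CgpGenome] = [pop[i].copy() for i in order[: config.elitism]]
        while len(new_pop) < config.population_size:
            p1 = pop[tournament()]
            if rng.random() < config.crossover_prob:
                child = cgp.crossover(p1, pop[tournament()], rng)
            else:
                child = p1.copy()
            new_pop.append(cgp.mutate(child, config.mutation_rate, rng))
        pop = new_pop
        fits = np.array([fitness(g, training_set) for g in pop])
        history.append(max(history[-1], float(fits.max())))

    best_idx = int(np.argmax(fits))
    # elitism guarantees the best-ever genome survives in the population
    return RunResult(
        best_genome=pop[best_idx],
        best_fitness=float(fits[best_idx]),
        best_fitness_history=history,
        seed=config.seed,
    )


def test_auc_of(genome: cgp.CgpGenome, test_set: TrainingSet) -> float:
    """AUC of a genome on a prepared evaluation split (grade 0 vs >= 3)."""
    return fitness(genome, test_set)


def multi_run_select(
    config: EvolutionConfig,
    training_set: TrainingSet,
    test_set: TrainingSet,
    n_runs: int,
    seeds: Optional[Sequence[int]] = None,
) -> Tuple[ClassifierModel, List[RunResult]]:
    """Repeat independent evolutionary runs and select the deployment model.

    Each run evolves against the training split; its best genome is then
    scored on the test split, and the genome with the highest test AUC is
    returned (ties broken toward the earlier seed).  The full per-run
    results provide the AUC distribution for box-plot style comparisons.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if seeds is None:
        seeds = [config.seed + i for i in range(n_runs)]
    seeds = list(seeds)
    if len(seeds) != n_runs or len(set(seeds)) != n_runs:
        raise ValueError("need n_runs distinct seeds")
    results: List[RunResult] = []
    for seed in seeds:
        run_cfg = dataclasses.replace(config, seed=int(seed))
        result = evolve(run_cfg, training_set)
        result.test_auc = test_auc_of(result.best_genome, test_set)
        results.append(result)
    best = max(results, key=lambda r: (r.test_auc, -seeds.index(r.seed)))
    model = ClassifierModel(
        genome=best.best_genome,
        feature_mode=training_set.feature_mode,
        provenance={
            "selected_seed": best.seed,
            "train_fitness": best.best_fitness,
            "test_auc": best.test_auc,
            "n_runs": n_runs,
            "seeds": seeds,
            "population_size": config.population_size,
            "generations": config.generations,
        },
    )
    return model, results
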