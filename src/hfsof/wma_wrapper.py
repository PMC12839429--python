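"""Wrapper feature-subset search over binary masks.

Individuals carry continuous positions in [0,1]^d that are thresholded at
1/2 into masks (repaired to keep >= 2 features). Fitness is the mean over
fixed stratified CV folds of the macro-F1 of an RBF SVM trained on the
masked columns, memoized by mask bits. Two optimizers share the encoding:
the whale-migration search (leaders take random exploratory steps, followers
move toward the leader mean and global best, greedy acceptance) and a
canonical global-best PSO baseline. An exhaustive enumerator serves as the
small-pool oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from hfsof.eval_metrics import OvrSvm, macro_f1_from_predictions

PSO_INERTIA = 0.729
PSO_COGNITIVE = 1.49445
PSO_SOCIAL = 1.49445
PSO_VELOCITY_CLAMP = 0.5


@dataclass
class FitnessSpec:
    """Everything a fitness evaluation needs, frozen once per run."""

    X: np.ndarray                 # training rows restricted to the candidate set
    y: np.ndarray
    svm_c: float = 100.0
    svm_gamma: float = 0.01
    k_fold: int = 3
    fold_seed: int = 0
    folds: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    cache: dict[bytes, float] = field(default_factory=dict)
    n_evaluations: int = 0
    n_cache_hits: int = 0
    use_cache: bool = True

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on sample count")
        if not self.folds:
            self.folds = self._build_folds()

    def _build_folds(self) -> list[tuple[np.ndarray, np.ndarray]]:
        counts = np.bincount(self.y)
        present = np.flatnonzero(counts)
        bad = [int(c) for c in present if counts[c] < self.k_fold]
        if bad:
            raise ValueError(
                f"classes {bad} have fewer than k_fold={self.k_fold} training "
                "samples; cannot build stratified folds"
            )
        skf = StratifiedKFold(
            n_splits=self.k_fold, shuffle=True, random_state=self.fold_seed
        )
        return [
            (train.copy(), test.copy()) for train, test in skf.split(self.X, self.y)
        ]

    @property
    def d(self) -> int:
        return int(self.X.shape[1])

    @property
    def n_classes(self) -> int:
        return int(self.y.max()) + 1


def binarize(position: np.ndarray) -> np.ndarray:
    """Strict threshold at 1/2; repaired so at least 2 features survive.

    Repair forces the two largest-position indices on (ties favor the lower
    index).
    """
    position = np.asarray(position, dtype=np.float64)
    mask = (position > 0.5).astype(np.int8)
    if mask.sum() < 2:
        # stable sort descending by value, ascending by index on ties
        order = np.lexsort((np.arange(position.shape[0]), -position))
        mask[order[:2]] = 1
    return mask


def evaluate_fitness(mask: np.ndarray, spec: FitnessSpec) -> float:
    """Mean stratified-CV macro-F1 of the SVM on the masked columns."""
    mask = np.asarray(mask, dtype=np.int8)
    if mask.sum() < 2:
        raise ValueError("mask must select at least 2 features")
    key = mask.tobytes()
    if spec.use_cache and key in spec.cache:
        spec.n_cache_hits += 1
        return spec.cache[key]
    cols = np.flatnonzero(mask)
    X_sub = spec.X[:, cols]
    n_classes = spec.n_classes
    scores = []
    for train_rows, val_rows in spec.folds:
        clf = OvrSvm(C=spec.svm_c, gamma=spec.svm_gamma)
        clf.fit(X_sub[train_rows], spec.y[train_rows])
        raw = clf.decision_matrix(X_sub[val_rows])
        y_pred = clf.classes_[np.argmax(raw, axis=1)]
        scores.append(macro_f1_from_predictions(spec.y[val_rows], y_pred, n_classes))
    value = float(np.mean(scores))
    spec.n_evaluations += 1
    if spec.use_cache:
        spec.cache[key] = value
    return value


@dataclass
class SearchTrace:
    best_fitness: list[float]
    mean_fitness: list[float]
    best_mask_history: list[np.ndarray]
    best_mask: np.ndarray
    best_position: np.ndarray
    best_fitness_final: float
    n_evaluations: int
    n_cache_hits: int

    @property
    def n_selected(self) -> int:
        return int(self.best_mask.sum())

    def save(self, path, delimiter: str = "\t") -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "iteration": np.arange(len(self.best_fitness)),
                "best_fitness": self.best_fitness,
                "mean_fitness": self.mean_fitness,
                "n_selected": [int(m.sum()) for m in self.best_mask_history],
            }
        ).to_csv(path, sep=delimiter, index=False)


def _initial_population(
    spec: FitnessSpec, n_pop: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pos = rng.uniform(0.0, 1.0, size=(n_pop, spec.d))
    masks = np.array([binarize(p) for p in pos])
    fitness = np.array([evaluate_fitness(m, spec) for m in masks])
    return pos, masks, fitness


def run_wma(spec: FitnessSpec, n_pop: int, T: int, seed: int) -> SearchTrace:
    """Whale-migration search with synchronous updates and greedy acceptance.

    Leaders (top ceil(n_pop/2) by fitness at the start of the iteration)
    move by ``p + u*v`` with u ~ U(-1,1), v ~ U(0,1); followers move by
    ``m + r1*(p_prev - p) + r2*(p_best - m)`` where ``m`` is the
    start-of-iteration mean leader position. Moves are clipped to [0,1] and
    accepted only on strict fitness improvement.
    """
    if n_pop < 2:
        raise ValueError("n_pop must be >= 2")
    if T < 1:
        raise ValueError("T must be >= 1")
    if spec.d < 2:
        raise ValueError("need >= 2 candidate features")
    rng = np.random.default_rng(seed)
    pos, masks, fitness = _initial_population(spec, n_pop, rng)
    prev_pos = pos.copy()

    best_idx = int(np.argmax(fitness))
    g_pos = pos[best_idx].copy()
    g_mask = masks[best_idx].copy()
    g_fit = float(fitness[best_idx])

    trace_best: list[float] = []
    trace_mean: list[float] = []
    trace_masks: list[np.ndarray] = []
    n_leaders = math.ceil(n_pop / 2)

    for _ in range(T):
        order = np.argsort(-fitness, kind="stable")
        leaders = set(order[:n_leaders].tolist())
        mean_leader = pos[order[:n_leaders]].mean(axis=0)
        iter_best = pos[order[0]].copy()
        old_pos = pos.copy()

        for i in range(n_pop):
            if i in leaders:
                u = rng.uniform(-1.0, 1.0, size=spec.d)
                v = rng.uniform(0.0, 1.0, size=spec.d)
                candidate = pos[i] + u * v
            else:
                r1 = rng.uniform(0.0, 1.0, size=spec.d)
                r2 = rng.uniform(0.0, 1.0, size=spec.d)
                candidate = (
                    mean_leader
                    + r1 * (prev_pos[i] - pos[i])
                    + r2 * (iter_best - mean_leader)
                )
            candidate = np.clip(candidate, 0.0, 1.0)
            cand_mask = binarize(candidate)
            cand_fit = evaluate_fitness(cand_mask, spec)
            if cand_fit > fitness[i]:  # strict improvement only
                pos[i] = candidate
                masks[i] = cand_mask
                fitness[i] = cand_fit
                if cand_fit > g_fit:
                    g_fit = float(cand_fit)
                    g_pos = candidate.copy()
                    g_mask = cand_mask.copy()
        prev_pos = old_pos

        trace_best.append(g_fit)
        trace_mean.append(float(fitness.mean()))
        trace_masks.append(g_mask.copy())

    return SearchTrace(
        best_fitness=trace_best,
        mean_fitness=trace_mean,
        best_mask_history=trace_masks,
        best_mask=g_mask,
        best_position=g_pos,
        best_fitness_final=g_fit,
        n_evaluations=spec.n_evaluations,
        n_cache_hits=spec.n_cache_hits,
    )


def run_pso(spec: FitnessSpec, n_pop: int, T: int, seed: int) -> SearchTrace:
    """Canonical global-best PSO baseline over the same [0,1]^d encoding."""
    if n_pop < 2:
        raise ValueError("n_pop must be >= 2")
    if T < 1:
        raise ValueError("T must be >= 1")
    if spec.d < 2:
        raise ValueError("need >= 2 candidate features")
    rng = np.random.default_rng(seed)
    pos, masks, fitness = _initial_population(spec, n_pop, rng)
    vel = np.zeros_like(pos)
    pbest_pos = pos.copy()
    pbest_fit = fitness.copy()

    best_idx = int(np.argmax(fitness))
    g_pos = pos[best_idx].copy()
    g_mask = masks[best_idx].copy()
    g_fit = float(fitness[best_idx])

    trace_best: list[float] = []
    trace_mean: list[float] = []
    trace_masks: list[np.ndarray] = []

    for _ in range(T):
        for i in range(n_pop):
            r1 = rng.uniform(0.0, 1.0, size=spec.d)
            r2 = rng.uniform(0.0, 1.0, size=spec.d)
            vel[i] = (
                PSO_INERTIA * vel[i]
                + PSO_COGNITIVE * r1 * (pbest_pos[i] - pos[i])
                + PSO_SOCIAL * r2 * (g_pos - pos[i])
            )
            vel[i] = np.clip(vel[i], -PSO_VELOCITY_CLAMP, PSO_VELOCITY_CLAMP)
            pos[i] = np.clip(pos[i] + vel[i], 0.0, 1.0)
            masks[i] = binarize(pos[i])
            fitness[i] = evaluate_fitness(masks[i], spec)
            if fitness[i] > pbest_fit[i]:
                pbest_fit[i] = fitness[i]
                pbest_pos[i] = pos[i].copy()
                if fitness[i] > g_fit:
                    g_fit = float(fitness[i])
                    g_pos = pos[i].copy()
                    g_mask = masks[i].copy()
        trace_best.append(g_fit)
        trace_mean.append(float(fitness.mean()))
        trace_masks.append(g_mask.copy())

    return SearchTrace(
        best_fitness=trace_best,
        mean_fitness=trace_mean,
        best_mask_history=trace_masks,
        best_mask=g_mask,
        best_position=g_pos,
        best_fitness_final=g_fit,
        n_evaluations=spec.n_evaluations,
        n_cache_hits=spec.n_cache_hits,
    )


def exhaustive_search(spec: FitnessSpec, d: int | None = None) -> tuple[np.ndarray, float]:
    """Enumerate all masks with >= 2 selected features; return the optimum.

    Ties resolve to the lexicographically smallest mask. Refuses d > 15.
    """
    if d is None:
        d = spec.d
    if d != spec.d:
        raise ValueError("d must equal the spec feature count")
    if d > 15:
        raise ValueError("exhaustive search limited to d <= 15")
    best_mask: np.ndarray | None = None
    best_fit = -np.inf
    for bits in itertools.product((0, 1), repeat=d):
        mask = np.array(bits, dtype=np.int8)
        if mask.sum() < 2:
            continue
        fit = evaluate_fitness(mask, spec)
        if fit > best_fit:  # lex order of enumeration makes ties keep the first
            best_fit = fit
            best_mask = mask
    assert best_mask is not None
    return best_mask, float(best_fit)
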