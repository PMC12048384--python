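"""Binary grey wolf optimizer (bGWO) for feature-subset search.

Candidate solutions are bit vectors over ``d`` features.  Each iteration
every wolf builds three binary candidates, one per leader (alpha, beta,
delta): the attraction step ``A * D`` (canonical grey-wolf coefficients,
``a`` decaying linearly from 2 to 0) is squashed by the sigmoid transfer
function ``cstep = 1 / (1 + exp(-10 (A*D - 0.5)))``, thresholded against
a fresh uniform draw into a binary step, and OR-ed with the leader's
bits.  The three candidates are then combined by a stochastic three-way
crossover that takes each bit from one of them with probability 1/3.

The wrapper fitness is ``lambda * (1 - CV accuracy) + (1 - lambda) *
(n_selected / d)`` (lower is better), with stratified cross-validation of
a fast inner classifier on the selected columns.

Randomness is fully reproducible from the seed with a documented draw
order -- per iteration, per wolf: for each of alpha, beta, delta the
coefficient draws r1 and r2 (each ``d`` uniforms), then the binary-step
draw (``d`` uniforms); then the crossover draws (``d`` uniforms); then,
only if the candidate came out all-zero, one integer draw for the repair
bit flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC


class CentroidClassifier:
    """Nearest class-centroid rule (Euclidean): a minimal linear model.

    Implemented directly because the wrapper objective refits it tens of
    thousands of times; the decision is argmax of ``x . mu_c - ||mu_c||^2
    / 2`` over class centroids, one matrix product per predict call.
    Zero-variance columns (common in sparse tripeptide data) need no
    special handling.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CentroidClassifier":
        self.classes_, codes = np.unique(y, return_inverse=True)
        k = len(self.classes_)
        centroids = np.zeros((k, X.shape[1]), dtype=np.float64)
        counts = np.bincount(codes, minlength=k).astype(np.float64)
        np.add.at(centroids, codes, X)
        centroids /= counts[:, None]
        self._centroids = centroids
        self._offset = 0.5 * (centroids ** 2).sum(axis=1)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = X @ self._centroids.T - self._offset
        return self.classes_[np.argmax(scores, axis=1)]


@dataclass(frozen=True)
class GWOCoefficients:
    """Attraction coefficients of one wolf-leader pair (per dimension)."""

    a: float
    A: np.ndarray
    C: np.ndarray
    D: np.ndarray


@dataclass
class BinarySolution:
    """A bit vector with its fitness (lower is better)."""

    bits: np.ndarray
    fitness: float

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())


@dataclass
class FitnessConfig:
    """Wrapper-fitness settings.

    ``lambda_weight`` trades classification error against subset size;
    at the default 0.99 one extra feature is only worth keeping if it
    changes cross-validated accuracy.  ``inner_classifier`` is the model
    refitted for every candidate subset -- ``"centroid"`` (a nearest
    class-centroid linear rule, the fastest option and the default),
    ``"logistic"``, ``"linear_svc"`` or ``"sgd"``.
    """

    lambda_weight: float = 0.99
    cv_folds: int = 3
    inner_classifier: str = "centroid"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.lambda_weight <= 1.0:
            raise ValueError("lambda_weight must be in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def _make_inner_classifier(name: str, seed: int):
    if name == "centroid":
        return CentroidClassifier()
    if name == "logistic":
        return LogisticRegression(max_iter=200, solver="liblinear",
                                  random_state=seed)
    if name == "linear_svc":
        return LinearSVC(random_state=seed)
    if name == "sgd":
        return SGDClassifier(random_state=seed)
    raise ValueError(f"unknown inner classifier {name!r}")


def update_coefficients(t: int, T: int, x_leader: np.ndarray,
                        x_wolf: np.ndarray,
                        rng: np.random.Generator) -> GWOCoefficients:
    """Draw the per-dimension attraction coefficients at iteration t.

    ``a`` decays linearly from 2 (t = 0) to 0 (t = T); per dimension
    ``A = 2 a r1 - a``, ``C = 2 r2`` and ``D = |C x_leader - x_wolf|``
    with r1, r2 fresh uniform [0, 1) draws.
    """
    if T <= 0:
        raise ValueError("total iterations T must be > 0")
    if not 0 <= t <= T:
        raise ValueError(f"iteration t={t} outside [0, {T}]")
    d = len(x_leader)
    if len(x_wolf) != d:
        raise ValueError("leader/wolf length mismatch")
    a = 2.0 * (1.0 - t / T)
    r1 = rng.random(d)
    r2 = rng.random(d)
    A = 2.0 * a * r1 - a
    C = 2.0 * r2
    D = np.abs(C * np.asarray(x_leader, dtype=np.float64)
               - np.asarray(x_wolf, dtype=np.float64))
    return GWOCoefficients(a=a, A=A, C=C, D=D)


def cstep(A, D):
    """Sigmoid transfer of the attraction step: 1/(1 + e^(-10 (A D - 0.5))).

    Strictly increasing in ``A * D``; equals 0.5 at ``A * D = 0.5``.
    """
    return expit(10.0 * (np.asarray(A, dtype=np.float64) * D - 0.5))


def bstep(cstep_value, rand):
    """Binary step: 1 where the sigmoid value reaches the uniform draw."""
    return (np.asarray(cstep_value) >= np.asarray(rand)).astype(np.int8)


def leader_candidate(leader_bits: np.ndarray,
                     bsteps: np.ndarray) -> np.ndarray:
    """Combine leader bits with binary steps: 1 iff their sum reaches 1.

    On binary inputs this is exactly the element-wise OR.
    """
    leader_bits = np.asarray(leader_bits)
    bsteps = np.asarray(bsteps)
    if leader_bits.shape != bsteps.shape:
        raise ValueError("length mismatch between leader bits and bsteps")
    return ((leader_bits.astype(np.int64) + bsteps.astype(np.int64)) >= 1
            ).astype(np.int8)


def crossover(x1: np.ndarray, x2: np.ndarray, x3: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    """Three-way stochastic crossover with equal source probabilities.

    Per dimension a fresh uniform draw picks the bit from ``x1`` if it is
    <= 1/3, from ``x2`` if in (1/3, 2/3], else from ``x3``.
    """
    x1, x2, x3 = (np.asarray(x, dtype=np.int8) for x in (x1, x2, x3))
    if not (x1.shape == x2.shape == x3.shape):
        raise ValueError("crossover parents must have equal length")
    r = rng.random(len(x1))
    out = np.where(r <= 1.0 / 3.0, x1, np.where(r <= 2.0 / 3.0, x2, x3))
    return out.astype(np.int8)


class WrapperFitness:
    """Cross-validated wrapper objective over a fixed data block.

    Folds are fixed once from the config seed so every candidate subset
    is scored on identical splits; the objective is deterministic given
    (bits, config).  An all-zero candidate never raises: it is assigned
    the worst error term, ``lambda_weight``, and flagged.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 config: FitnessConfig | None = None):
        self.config = config or FitnessConfig()
        self.X = np.ascontiguousarray(X, dtype=np.float64)
        self.y = np.asarray(y)
        self.d = self.X.shape[1]
        self.flagged_empty = 0
        _, counts = np.unique(self.y, return_counts=True)
        folds = min(self.config.cv_folds, int(counts.min()))
        if folds < 2:
            raise ValueError("need at least 2 samples of every class")
        splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                   random_state=self.config.seed)
        self._splits = list(splitter.split(self.X, self.y))

    def __call__(self, bits: np.ndarray) -> float:
        bits = np.asarray(bits, dtype=bool)
        lam = self.config.lambda_weight
        k = int(bits.sum())
        if k == 0:
            self.flagged_empty += 1
            return lam
        Xs = self.X[:, bits]
        accuracies = []
        for train_idx, test_idx in self._splits:
            clf = _make_inner_classifier(self.config.inner_classifier,
                                         self.config.seed)
            clf.fit(Xs[train_idx], self.y[train_idx])
            pred = clf.predict(Xs[test_idx])
            accuracies.append(float(np.mean(pred == self.y[test_idx])))
        cv_accuracy = float(np.mean(accuracies))
        return lam * (1.0 - cv_accuracy) + (1.0 - lam) * (k / self.d)


def fitness(bits: np.ndarray, X: np.ndarray, y: np.ndarray,
            config: FitnessConfig | None = None) -> float:
    """One-off wrapper fitness of a bit vector on a data block."""
    return WrapperFitness(X, y, config)(bits)


@dataclass
class OptimizerTrace:
    """Per-iteration alpha diagnostics (iteration, fitness, n bits)."""

    rows: list[tuple[int, float, int]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=[
            "iteration", "alpha_fitness", "alpha_n_selected"])


def optimize(d: int, fitness_fn: Callable[[np.ndarray], float],
             pop_size: int = 10, n_iterations: int = 30,
             seed: int = 0, repair: str = "flip",
             ) -> tuple[BinarySolution, OptimizerTrace]:
    """Run the binary grey wolf search and return the final alpha.

    The population starts from independent fair-coin bits.  Each
    iteration builds one candidate per leader via the sigmoid transfer
    and OR combination, merges them by three-way crossover, repairs
    all-zero candidates (``repair="flip"`` flips one uniformly chosen bit
    to 1; ``repair="worst"`` leaves the candidate and lets the fitness
    assign its defined worst value), evaluates, and updates the
    best-so-far alpha/beta/delta.  Alpha fitness is therefore
    non-increasing across iterations, and identical seeds give
    bit-identical trajectories.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if pop_size < 3:
        raise ValueError("pop_size must be >= 3 (three leaders)")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if repair not in ("flip", "worst"):
        raise ValueError(f"unknown repair mode {repair!r}")
    rng = np.random.default_rng(seed)

    positions = (rng.random((pop_size, d)) < 0.5).astype(np.int8)
    if repair == "flip":
        for i in range(pop_size):
            if not positions[i].any():
                positions[i, rng.integers(d)] = 1
    fitnesses = np.array([fitness_fn(positions[i].astype(bool))
                          for i in range(pop_size)])

    # Leaders are kept pairwise distinct as bit patterns: a duplicate
    # leader would contribute nothing to the three-way crossover, and a
    # fully collapsed leader triple can never shed a bit (the leader
    # step is an OR).  Preference order is fitness, then input order;
    # duplicates fill remaining slots only when the population has
    # fewer than three distinct patterns.
    order = np.argsort(fitnesses, kind="stable")
    chosen: list[int] = []
    for j in order:
        if len(chosen) == 3:
            break
        if not any(np.array_equal(positions[j], positions[i])
                   for i in chosen):
            chosen.append(int(j))
    for j in order:
        if len(chosen) == 3:
            break
        chosen.append(int(j))
    leaders = [positions[j].copy() for j in chosen]
    leader_fit = [float(fitnesses[j]) for j in chosen]

    trace = OptimizerTrace()
    trace.rows.append((0, leader_fit[0], int(leaders[0].sum())))

    for t in range(n_iterations):
        new_positions = np.empty_like(positions)
        for i in range(pop_size):
            candidates = []
            for leader in leaders:
                coef = update_coefficients(t, n_iterations, leader,
                                           positions[i], rng)
                cs = cstep(coef.A, coef.D)
                bs = bstep(cs, rng.random(d))
                candidates.append(leader_candidate(leader, bs))
            x_new = crossover(*candidates, rng)
            if repair == "flip" and not x_new.any():
                x_new[rng.integers(d)] = 1
            new_positions[i] = x_new
        positions = new_positions
        fitnesses = np.array([fitness_fn(positions[i].astype(bool))
                              for i in range(pop_size)])
        for i in range(pop_size):
            f = float(fitnesses[i])
            if any(np.array_equal(positions[i], led) for led in leaders):
                continue  # keep the leader triple pairwise distinct
            if f < leader_fit[0]:
                leaders = [positions[i].copy(), leaders[0], leaders[1]]
                leader_fit = [f, leader_fit[0], leader_fit[1]]
            elif f < leader_fit[1]:
                leaders = [leaders[0], positions[i].copy(), leaders[1]]
                leader_fit = [leader_fit[0], f, leader_fit[1]]
            elif f < leader_fit[2]:
                leaders[2] = positions[i].copy()
                leader_fit[2] = f
        trace.rows.append((t + 1, leader_fit[0], int(leaders[0].sum())))

    alpha = BinarySolution(bits=leaders[0].astype(bool),
                           fitness=leader_fit[0])
    return alpha, trace
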