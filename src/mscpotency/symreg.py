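"""Genetic-programming symbolic regression with complexity control.

Expression trees over {+, -, *, protected /, square} with feature and
constant leaves are evolved by multi-restart GP: ramped initialization,
tournament selection, subtree crossover and mutation, and a fitness equal to
the training R^2 (of the best affine rescaling of the tree output, so
structure — not constants — is what evolution must find) minus a small
parsimony penalty per node. Each restart archives its complexity/accuracy
Pareto front; "variable presence" statistics are counted over archived
expressions that clear an R^2 floor and a complexity ceiling.

Complexity is the node count of the tree. Protected division floors the
denominator magnitude at 1e-6. Everything is deterministic per seed.

Trees are plain nested tuples: ``("var", j)``, ``("const", c)``,
``("add"|"sub"|"mul"|"div", left, right)``, ``("sq", child)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CompositeScore, ValidationError, logger

BINARY_OPS = ("add", "sub", "mul", "div")
UNARY_OPS = ("sq",)
_DIV_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# tree primitives
# ---------------------------------------------------------------------------

def evaluate(tree: tuple, X: np.ndarray) -> np.ndarray:
    """Evaluate a tree on an (n_samples, n_features) matrix."""
    op = tree[0]
    if op == "var":
        return X[:, tree[1]].astype(float)
    if op == "const":
        return np.full(X.shape[0], float(tree[1]))
    if op == "sq":
        v = evaluate(tree[1], X)
        return v * v
    a = evaluate(tree[1], X)
    b = evaluate(tree[2], X)
    if op == "add":
        return a + b
    if op == "sub":
        return a - b
    if op == "mul":
        return a * b
    # protected division
    sign = np.where(b >= 0, 1.0, -1.0)
    return a / (sign * np.maximum(np.abs(b), _DIV_FLOOR))


def complexity(tree: tuple) -> int:
    """Node count."""
    op = tree[0]
    if op in ("var", "const"):
        return 1
    if op == "sq":
        return 1 + complexity(tree[1])
    return 1 + complexity(tree[1]) + complexity(tree[2])


def variables(tree: tuple) -> frozenset[int]:
    op = tree[0]
    if op == "var":
        return frozenset([tree[1]])
    if op == "const":
        return frozenset()
    if op == "sq":
        return variables(tree[1])
    return variables(tree[1]) | variables(tree[2])


def to_string(tree: tuple, names: Sequence[str] | None = None) -> str:
    op = tree[0]
    if op == "var":
        return names[tree[1]] if names is not None else f"x{tree[1]}"
    if op == "const":
        return f"{tree[1]:.4g}"
    if op == "sq":
        return f"({to_string(tree[1], names)})^2"
    sym = {"add": "+", "sub": "-", "mul": "*", "div": "/"}[op]
    return f"({to_string(tree[1], names)} {sym} {to_string(tree[2], names)})"


def _subtree_count(tree: tuple) -> int:
    return complexity(tree)


def _get_subtree(tree: tuple, idx: int) -> tuple:
    """Pre-order indexed subtree access (index 0 is the root)."""
    if idx == 0:
        return tree
    op = tree[0]
    idx -= 1
    children = tree[1:] if op in ("sq",) else (tree[1:3] if op in BINARY_OPS else ())
    for child in children:
        c = complexity(child)
        if idx < c:
            return _get_subtree(child, idx)
        idx -= c
    raise IndexError("subtree index out of range")


def _replace_subtree(tree: tuple, idx: int, new: tuple) -> tuple:
    if idx == 0:
        return new
    op = tree[0]
    idx -= 1
    if op in ("var", "const"):
        raise IndexError("subtree index out of range")
    children = list(tree[1:])
    for i, child in enumerate(children):
        c = complexity(child)
        if idx < c:
            children[i] = _replace_subtree(child, idx, new)
            return (op, *children)
        idx -= c
    raise IndexError("subtree index out of range")


# ---------------------------------------------------------------------------
# run containers
# ---------------------------------------------------------------------------

@dataclass
class SRExpression:
    """One archived expression with its fit statistics."""

    tree: tuple
    complexity: int
    r2_train: float
    variables: frozenset
    expr: str

    def loo_r2(self, X: np.ndarray, y: np.ndarray) -> float:
        """Refit the affine constants per leave-one-out fold on the
        tree-defined basis and pool the held-out predictions."""
        f = evaluate(self.tree, X)
        n = len(y)
        preds = np.empty(n)
        for i in range(n):
            m = np.arange(n) != i
            A = np.column_stack([np.ones(m.sum()), f[m]])
            coef, *_ = np.linalg.lstsq(A, y[m], rcond=None)
            preds[i] = coef[0] + coef[1] * f[i]
        sst = ((y - y.mean()) ** 2).sum()
        if sst == 0:
            raise ValidationError("response has zero variance")
        return float(1.0 - ((y - preds) ** 2).sum() / sst)


@dataclass
class SRSettings:
    population_size: int = 200
    generations: int = 50
    restarts: int = 30
    p_crossover: float = 0.7
    p_mutation: float = 0.25
    tournament_k: int = 3
    init_depth: tuple[int, int] = (1, 4)
    max_nodes: int = 60
    parsimony: float = 1e-3
    const_range: tuple[float, float] = (-3.0, 3.0)

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValidationError("population_size must be >= 4")
        if self.restarts < 1:
            raise ValidationError("restarts must be >= 1")


@dataclass
class SRRun:
    """Archived elite of a multi-restart GP run."""

    expressions: list[SRExpression]
    settings: SRSettings
    feature_names: list[str]
    seed: int


# ---------------------------------------------------------------------------
# GP engine
# ---------------------------------------------------------------------------

def _random_tree(rng: np.random.Generator, n_vars: int, depth: int,
                 settings: SRSettings, full: bool) -> tuple:
    if depth <= 0 or (not full and rng.random() < 0.3):
        if rng.random() < 0.8:
            return ("var", int(rng.integers(n_vars)))
        lo, hi = settings.const_range
        return ("const", float(np.round(rng.uniform(lo, hi), 4)))
    r = rng.random()
    if r < 0.15:
        return ("sq", _random_tree(rng, n_vars, depth - 1, settings, full))
    op = BINARY_OPS[int(rng.integers(len(BINARY_OPS)))]
    return (
        op,
        _random_tree(rng, n_vars, depth - 1, settings, full),
        _random_tree(rng, n_vars, depth - 1, settings, full),
    )


def _r2_affine(f: np.ndarray, y: np.ndarray) -> float:
    """R^2 of the best affine rescaling a + b*f of the tree output."""
    if not np.all(np.isfinite(f)):
        return 0.0
    vf = f.var()
    vy = y.var()
    if vf == 0 or vy == 0:
        return 0.0
    c = np.corrcoef(f, y)[0, 1]
    if not np.isfinite(c):
        return 0.0
    return float(c * c)


def _evolve_restart(
    X: np.ndarray,
    y: np.ndarray,
    settings: SRSettings,
    rng: np.random.Generator,
) -> list[tuple[tuple, float, int]]:
    """One GP restart; returns (tree, r2, complexity) for the final elite."""
    n_vars = X.shape[1]
    lo_d, hi_d = settings.init_depth
    pop: list[tuple] = []
    for i in range(settings.population_size):  # ramped half-and-half
        depth = lo_d + i % (hi_d - lo_d + 1)
        pop.append(_random_tree(rng, n_vars, depth, settings, full=i % 2 == 0))

    def fitness(tree: tuple) -> tuple[float, float, int]:
        c = complexity(tree)
        r2 = _r2_affine(evaluate(tree, X), y)
        return r2 - settings.parsimony * c, r2, c

    scored = [(t, *fitness(t)[1:]) for t in pop]
    fit = [r2 - settings.parsimony * c for _, r2, c in scored]

    best_seen: dict[tuple, tuple[float, int]] = {}

    def note(tree: tuple, r2: float, c: int) -> None:
        if tree not in best_seen:
            best_seen[tree] = (r2, c)

    for t, r2, c in scored:
        note(t, r2, c)

    for _ in range(settings.generations):
        order = np.argsort(fit)[::-1]
        new_pop: list[tuple] = [scored[order[0]][0]]  # elitism
        while len(new_pop) < settings.population_size:
            def pick() -> tuple:
                idx = rng.integers(len(scored), size=settings.tournament_k)
                best = max(idx, key=lambda i: fit[i])
                return scored[best][0]

            r = rng.random()
            if r < settings.p_crossover:
                a, b = pick(), pick()
                ia = int(rng.integers(complexity(a)))
                ib = int(rng.integers(complexity(b)))
                child = _replace_subtree(a, ia, _get_subtree(b, ib))
            elif r < settings.p_crossover + settings.p_mutation:
                a = pick()
                ia = int(rng.integers(complexity(a)))
                depth = int(rng.integers(1, 4))
                child = _replace_subtree(a, ia, _random_tree(rng, n_vars, depth,
                                                             settings, full=False))
            else:
                child = pick()
            if complexity(child) > settings.max_nodes:
                child = pick()
            new_pop.append(child)
        scored = []
        fit = []
        for t in new_pop:
            c = complexity(t)
            r2 = _r2_affine(evaluate(t, X), y)
            scored.append((t, r2, c))
            fit.append(r2 - settings.parsimony * c)
            note(t, r2, c)

    # Pareto front (min complexity, max r2) over everything this restart saw
    items = sorted(
        ((t, r2, c) for t, (r2, c) in best_seen.items()),
        key=lambda x: (x[2], -x[1]),
    )
    front: list[tuple[tuple, float, int]] = []
    best_r2 = -np.inf
    for t, r2, c in items:
        if r2 > best_r2 + 1e-12:
            front.append((t, r2, c))
            best_r2 = r2
    return front


def sr_fit(
    X: pd.DataFrame,
    y: CompositeScore | pd.Series,
    settings: SRSettings | None = None,
    seed: int = 0,
) -> SRRun:
    """Multi-restart GP fit; archives each restart's Pareto elite."""
    settings = settings or SRSettings()
    yv = (y.scores if isinstance(y, CompositeScore) else y).loc[X.index]
    yv = yv.to_numpy(dtype=float)
    Xv = X.to_numpy(dtype=float)
    if Xv.shape[0] < 4:
        raise ValidationError("sr_fit needs >= 4 samples")
    names = [str(c) for c in X.columns]

    seeds = np.random.SeedSequence(seed).spawn(settings.restarts)
    archive: list[SRExpression] = []
    seen: set[tuple] = set()
    for ss in seeds:
        rng = np.random.default_rng(ss)
        for tree, r2, c in _evolve_restart(Xv, yv, settings, rng):
            if tree in seen:
                continue
            seen.add(tree)
            archive.append(
                SRExpression(
                    tree=tree,
                    complexity=c,
                    r2_train=r2,
                    variables=frozenset(names[j] for j in variables(tree)),
                    expr=to_string(tree, names),
                )
            )
    logger.info("SR archived %d unique expressions from %d restarts",
                len(archive), settings.restarts)
    return SRRun(expressions=archive, settings=settings,
                 feature_names=names, seed=seed)


# ---------------------------------------------------------------------------
# variable-presence statistics
# ---------------------------------------------------------------------------

def qualifying_expressions(
    run: SRRun, r2_min: float = 0.90, complexity_max: int = 300
) -> list[SRExpression]:
    return [e for e in run.expressions
            if e.r2_train >= r2_min and e.complexity <= complexity_max]


def variable_presence(
    run: SRRun, r2_min: float = 0.90, complexity_max: int = 300
) -> dict[str, float]:
    """Fraction of qualifying archived models containing each feature."""
    qual = qualifying_expressions(run, r2_min, complexity_max)
    if not qual:
        logger.warning("no SR expressions qualify (R^2 >= %.2f, complexity <= %d)",
                       r2_min, complexity_max)
        return {f: 0.0 for f in run.feature_names}
    return {
        f: sum(1 for e in qual if f in e.variables) / len(qual)
        for f in run.feature_names
    }


def sr_important_features(
    run: SRRun,
    presence_min: float = 0.10,
    r2_min: float = 0.90,
    complexity_max: int = 300,
) -> set[str]:
    """Features present in >= ``presence_min`` of qualifying models
    (inclusive threshold)."""
    presence = variable_presence(run, r2_min, complexity_max)
    return {f for f, p in presence.items() if p >= presence_min}


def best_qualifying(
    run: SRRun, r2_min: float = 0.90, complexity_max: int = 300
) -> SRExpression | None:
    """Highest-R^2 qualifying expression (ties -> lower complexity)."""
    qual = qualifying_expressions(run, r2_min, complexity_max)
    if not qual:
        return None
    return max(qual, key=lambda e: (e.r2_train, -e.complexity))
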