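"""Independent reference implementations used to check the package.

These deliberately avoid the code paths they verify: the z-score oracle
works in exact rational arithmetic from the hypergeometric mean/variance,
the logic oracle evaluates Kleene truth tables over abstract skeleton
trees, and the expression fuzzer emits text for the parser round-trip.
"""

import itertools
import math
from fractions import Fraction

from pathora.criteria import (
    Abs,
    And,
    Cmp,
    ColumnRef,
    Criterion,
    Not,
    NumberLit,
    Or,
    StringLit,
)

# ---------------------------------------------------------------------------
# exact-rational hypergeometric z-score


def zscore_oracle(n, r, N, R):
    """Mean nR/N and variance n(R/N)(1-R/N)(N-n)/(N-1), exactly; None when
    the variance is zero."""
    if n == 0 or N < 2:
        return None
    p = Fraction(R, N)
    variance = n * p * (1 - p) * Fraction(N - n, N - 1)
    if variance == 0:
        return None
    mean = Fraction(n * R, N)
    return float(r - mean) / math.sqrt(float(variance))


# ---------------------------------------------------------------------------
# Kleene three-valued logic over skeleton trees
# skeletons: ("ATOM", i) | ("NOT", t) | ("AND", l, r) | ("OR", l, r)

_T, _F, _U = True, False, None


def kleene_eval(tree, assignment):
    kind = tree[0]
    if kind == "ATOM":
        return assignment[tree[1]]
    if kind == "NOT":
        v = kleene_eval(tree[1], assignment)
        return _U if v is _U else (not v)
    left = kleene_eval(tree[1], assignment)
    right = kleene_eval(tree[2], assignment)
    if kind == "AND":
        if left is _F or right is _F:
            return _F
        if left is _U or right is _U:
            return _U
        return _T
    if left is _T or right is _T:
        return _T
    if left is _U or right is _U:
        return _U
    return _F


def skeletons(depth, n_atoms):
    """All boolean trees of the given maximum depth over n_atoms leaves."""
    atoms = [("ATOM", i) for i in range(n_atoms)]
    if depth <= 1:
        return list(atoms)
    sub = skeletons(depth - 1, n_atoms)
    trees = list(atoms)
    trees += [("NOT", t) for t in sub]
    trees += [(op, a, b) for op in ("AND", "OR") for a, b in itertools.product(sub, sub)]
    return trees


def skeleton_to_ast(tree):
    """Realize a skeleton as a criterion AST with atom i == ``[c{i}] > 0``."""
    kind = tree[0]
    if kind == "ATOM":
        return Cmp(">", ColumnRef(f"c{tree[1]}"), NumberLit(0.0))
    if kind == "NOT":
        return Not(skeleton_to_ast(tree[1]))
    node = And if kind == "AND" else Or
    return node(skeleton_to_ast(tree[1]), skeleton_to_ast(tree[2]))


def assignment_to_row(assignment):
    """Atom tri-states to column values: True -> 1, False -> -1, U -> missing."""
    values = {}
    for i, v in enumerate(assignment):
        values[f"c{i}"] = None if v is _U else (1.0 if v else -1.0)
    return values


def all_assignments(n_atoms):
    return list(itertools.product([_T, _F, _U], repeat=n_atoms))


# ---------------------------------------------------------------------------
# random expression generation (full grammar) for parser round-trips


def random_value(rng, columns):
    roll = rng.random()
    if roll < 0.4:
        return ColumnRef(rng.choice(columns))
    if roll < 0.7:
        return NumberLit(float(rng.choice([-1, 0, 1])))
    if roll < 0.85:
        return StringLit(rng.choice(["up", "down", "flat"]))
    return Abs(random_value(rng, columns))


def random_bool(rng, columns, depth=3):
    if depth <= 0 or rng.random() < 0.35:
        op = rng.choice(["<", "<=", ">", ">=", "=", "<>"])
        return Cmp(op, random_value(rng, columns), random_value(rng, columns))
    roll = rng.random()
    if roll < 0.2:
        return Not(random_bool(rng, columns, depth - 1))
    node = And if roll < 0.6 else Or
    return node(
        random_bool(rng, columns, depth - 1), random_bool(rng, columns, depth - 1)
    )


def random_criterion_ast(rng, columns=("a", "b")):
    return random_bool(rng, list(columns))


def pretty(ast):
    return Criterion(source_text="", ast=ast).pretty()
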