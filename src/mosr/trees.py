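"""Expression trees for symbolic regression.

A genome is a rooted tree whose internal nodes are operators of fixed arity
and whose leaves are feature references or real constants.  Trees are plain
nested tuples — ``("const", 3.7)``, ``("feat", "bmi")`` or
``(op_name, child, ...)`` — which makes copying free and subtree surgery a
matter of rebuilding along one root-to-node path.

All operators are *protected*: for any finite input they return a finite
output.  Division by (near-)zero yields 1, the logarithm is taken of
``max(|x|, eps)``, the exponential input is clamped to ±50, and every node
output is clamped to ±1e100 so that no chain of multiplications can
overflow to infinity.
"""

from __future__ import annotations

import re
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "OPERATORS",
    "DEFAULT_OPERATORS",
    "evaluate_expression",
    "evaluate_matrix",
    "serialize_formula",
    "parse_formula",
    "FormulaSyntaxError",
    "tree_size",
    "tree_depth",
    "tree_features",
    "random_tree",
    "ramped_half_and_half",
    "subtree_crossover",
    "subtree_mutation",
    "point_mutation",
]

_EPS = 1e-12
_CLAMP = 1e100
_EXP_CLAMP = 50.0


def _clamp(x):
    return np.clip(x, -_CLAMP, _CLAMP)


def _p_div(a, b):
    b = np.asarray(b, dtype=float)
    safe = np.where(np.abs(b) > _EPS, b, 1.0)
    return _clamp(np.where(np.abs(b) > _EPS, np.asarray(a, float) / safe, 1.0))


def _p_log(x):
    return np.log(np.maximum(np.abs(x), _EPS))


def _p_exp(x):
    return np.exp(np.clip(x, -_EXP_CLAMP, _EXP_CLAMP))


def _if_greater(a, b, c, d):
    return np.where(np.asarray(a, float) > np.asarray(b, float), c, d)


# name -> (arity, vectorised implementation)
OPERATORS: dict[str, tuple[int, Callable]] = {
    "add": (2, lambda a, b: _clamp(np.add(a, b))),
    "sub": (2, lambda a, b: _clamp(np.subtract(a, b))),
    "mul": (2, lambda a, b: _clamp(np.multiply(a, b))),
    "div": (2, _p_div),
    "neg": (1, np.negative),
    "log": (1, _p_log),
    "exp": (1, _p_exp),
    "sqrt": (1, lambda a: np.sqrt(np.abs(a))),
    "min": (2, np.minimum),
    "max": (2, np.maximum),
    "if_greater": (4, _if_greater),
}

DEFAULT_OPERATORS: tuple[str, ...] = tuple(OPERATORS)


# ---------------------------------------------------------------------------
# evaluation


def _eval(tree, columns: Mapping[str, np.ndarray]):
    kind = tree[0]
    if kind == "const":
        return tree[1]
    if kind == "feat":
        try:
            return columns[tree[1]]
        except KeyError:
            raise KeyError(f"unresolved feature reference {tree[1]!r}") from None
    arity, fn = OPERATORS[kind]
    return fn(*(_eval(c, columns) for c in tree[1:]))


def evaluate_matrix(tree, columns: Mapping[str, np.ndarray], n_rows: int | None = None) -> np.ndarray:
    """Evaluate ``tree`` on column vectors; returns one raw score per row."""
    out = _eval(tree, columns)
    if np.ndim(out) == 0:
        if n_rows is None:
            for v in columns.values():
                n_rows = len(v)
                break
            else:
                n_rows = 1
        return np.full(n_rows, float(out))
    return np.asarray(out, dtype=float)


def evaluate_expression(tree, row: Mapping[str, float]) -> float:
    """Evaluate ``tree`` on a single record of feature values."""
    cols = {k: np.asarray([v], dtype=float) for k, v in row.items()}
    return float(evaluate_matrix(tree, cols, n_rows=1)[0])


def tree_size(tree) -> int:
    if tree[0] in ("const", "feat"):
        return 1
    return 1 + sum(tree_size(c) for c in tree[1:])


def tree_depth(tree) -> int:
    if tree[0] in ("const", "feat"):
        return 0
    return 1 + max(tree_depth(c) for c in tree[1:])


def tree_features(tree) -> set[str]:
    """The set of feature names the formula actually references."""
    if tree[0] == "feat":
        return {tree[1]}
    if tree[0] == "const":
        return set()
    out: set[str] = set()
    for c in tree[1:]:
        out |= tree_features(c)
    return out


def _subtrees(tree) -> Iterator:
    yield tree
    if tree[0] not in ("const", "feat"):
        for c in tree[1:]:
            yield from _subtrees(c)


def get_subtree(tree, index: int):
    for i, t in enumerate(_subtrees(tree)):
        if i == index:
            return t
    raise IndexError(index)


def replace_subtree(tree, index: int, new):
    """Return a copy of ``tree`` with the preorder-``index`` node replaced."""

    def rec(t, i):
        if i == 0:
            return new, -1
        if t[0] in ("const", "feat"):
            return t, i - 1
        i -= 1
        children = []
        for c in t[1:]:
            if i < 0:
                children.append(c)
            else:
                c2, i = rec(c, i)
                children.append(c2)
        return (t[0],) + tuple(children), i

    out, rest = rec(tree, index)
    if rest >= 0:
        raise IndexError(index)
    return out


# ---------------------------------------------------------------------------
# serialization: prefix grammar  op(arg, ...) | feature | decimal constant

_TOKEN = re.compile(r"\s*(?:(?P<num>[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)"
                    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
                    r"|(?P<punct>[(),]))")


class FormulaSyntaxError(ValueError):
    """Raised when a formula string does not follow the grammar."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def serialize_formula(tree) -> str:
    kind = tree[0]
    if kind == "const":
        return repr(float(tree[1]))
    if kind == "feat":
        return str(tree[1])
    return f"{kind}({', '.join(serialize_formula(c) for c in tree[1:])})"


def parse_formula(text: str, features: Sequence[str] | None = None):
    """Parse a prefix-notation formula into an expression tree.

    ``features``, when given, is the set of legal feature names; any other
    bare identifier is rejected.  Without it every non-operator identifier
    is accepted as a feature reference.
    """
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise FormulaSyntaxError(f"unexpected character {text[pos]!r}", pos)
        for group in ("num", "name", "punct"):
            val = m.group(group)
            if val is not None:
                tokens.append((group, val, m.start(group)))
                break
        pos = m.end()

    idx = 0

    def peek():
        return tokens[idx] if idx < len(tokens) else (None, None, len(text))

    def expect(value):
        nonlocal idx
        kind, val, p = peek()
        if val != value:
            raise FormulaSyntaxError(f"expected {value!r}, found {val!r}", p)
        idx += 1

    def parse_node():
        nonlocal idx
        kind, val, p = peek()
        if kind is None:
            raise FormulaSyntaxError("unexpected end of formula", p)
        if kind == "num":
            idx += 1
            return ("const", float(val))
        if kind == "name":
            idx += 1
            nk, nv, _ = peek()
            if nv == "(":
                if val not in OPERATORS:
                    raise FormulaSyntaxError(f"unknown operator {val!r}", p)
                arity = OPERATORS[val][0]
                expect("(")
                args = [parse_node()]
                while peek()[1] == ",":
                    expect(",")
                    args.append(parse_node())
                expect(")")
                if len(args) != arity:
                    raise FormulaSyntaxError(
                        f"operator {val!r} takes {arity} arguments, got {len(args)}", p)
                return (val,) + tuple(args)
            if features is not None and val not in features:
                raise FormulaSyntaxError(f"unknown feature name {val!r}", p)
            return ("feat", val)
        raise FormulaSyntaxError(f"unexpected token {val!r}", p)

    tree = parse_node()
    kind, val, p = peek()
    if kind is not None:
        raise FormulaSyntaxError(f"trailing input {val!r}", p)
    return tree


# ---------------------------------------------------------------------------
# random generation and variation

def _random_terminal(rng, features, const_range, p_feature=0.8):
    if features and rng.random() < p_feature:
        return ("feat", features[rng.integers(len(features))])
    lo, hi = const_range
    return ("const", float(np.round(rng.uniform(lo, hi), 6)))


def random_tree(rng, features, operators, const_range, max_depth, method="grow"):
    """Generate one random tree (``grow`` or ``full`` initialisation)."""
    if max_depth <= 0 or (method == "grow" and rng.random() < 0.3):
        return _random_terminal(rng, features, const_range)
    op = operators[rng.integers(len(operators))]
    arity = OPERATORS[op][0]
    children = tuple(
        random_tree(rng, features, operators, const_range, max_depth - 1, method)
        for _ in range(arity)
    )
    return (op,) + children


def ramped_half_and_half(rng, n, features, operators, const_range,
                         min_depth=2, max_depth=6):
    """Classic GP initialisation: depths ramped over [min, max], half the
    trees built with ``full`` and half with ``grow``."""
    pop = []
    depths = list(range(min_depth, max_depth + 1))
    for i in range(n):
        depth = depths[i % len(depths)]
        method = "full" if (i // len(depths)) % 2 == 0 else "grow"
        pop.append(random_tree(rng, features, operators, const_range, depth, method))
    return pop


def subtree_crossover(rng, a, b, max_depth):
    """Swap a random subtree of ``a`` with one of ``b``; offspring breaching
    the depth bound revert to their parent."""
    ia = int(rng.integers(tree_size(a)))
    ib = int(rng.integers(tree_size(b)))
    sub_a, sub_b = get_subtree(a, ia), get_subtree(b, ib)
    child_a = replace_subtree(a, ia, sub_b)
    child_b = replace_subtree(b, ib, sub_a)
    if tree_depth(child_a) > max_depth:
        child_a = a
    if tree_depth(child_b) > max_depth:
        child_b = b
    return child_a, child_b


def subtree_mutation(rng, tree, features, operators, const_range, max_depth):
    idx = int(rng.integers(tree_size(tree)))
    new = random_tree(rng, features, operators, const_range,
                      max_depth=int(rng.integers(1, 4)))
    child = replace_subtree(tree, idx, new)
    return child if tree_depth(child) <= max_depth else tree


def point_mutation(rng, tree, features, operators, const_range):
    """Replace one node in place: operator by a same-arity operator,
    constant by a perturbed constant, feature by another feature."""
    idx = int(rng.integers(tree_size(tree)))
    node = get_subtree(tree, idx)
    if node[0] == "const":
        lo, hi = const_range
        new = ("const", float(np.clip(node[1] + rng.normal(0, 0.1 * (hi - lo)), lo, hi)))
    elif node[0] == "feat":
        new = ("feat", features[rng.integers(len(features))]) if features else node
    else:
        arity = OPERATORS[node[0]][0]
        same = [o for o in operators if OPERATORS[o][0] == arity]
        new = (same[rng.integers(len(same))],) + node[1:]
    return replace_subtree(tree, idx, new)
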