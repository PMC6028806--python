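"""Model-vs-experiment scoring.

Each experiment file may carry its own scoring formula — an arithmetic
expression over the bound variables ``expt`` (experimental readout values),
``sim`` (simulated values at the same coordinates), ``sem`` (standard
errors, when present) and ``range`` (``max(expt) - min(expt)``, falling back
to ``max(abs(expt))`` when the readouts are flat).  The default formula is
the range-normalized RMS deviation::

    sqrt(mean(((expt - sim) / range) ** 2))

which is 0 for a perfect fit and scale-invariant.

Experiment files are untrusted input, so formulas are evaluated by a small
recursive-descent parser over a whitelisted grammar (numbers, the four
arithmetic operators, ``**``, comparisons, and the functions ``sum``,
``mean``, ``sqrt``, ``abs``, ``min``, ``max``) — never by general code
evaluation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScoreResult", "FormulaError", "DEFAULT_FORMULA",
           "parse_formula", "evaluate_score", "score_experiment",
           "aggregate_battery"]

DEFAULT_FORMULA = "sqrt(mean(((expt - sim) / range) ** 2))"


class FormulaError(ValueError):
    pass


@dataclass
class ScoreResult:
    """Scalar fit score for one experiment (0 = perfect) plus diagnostics."""

    experimentId: str
    score: float
    perPointResiduals: list[float] = field(default_factory=list)
    formulaUsed: str = DEFAULT_FORMULA
    weight: float = 1.0
    failed: bool = False
    message: str = ""


# --------------------------------------------------------------------------
# Tokenizer / parser -> AST of nested tuples
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"""
    \s*(?:
      (?P<num>\d+\.\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?|\d+(?:[eE][+-]?\d+)?)
    | (?P<name>[A-Za-z_][A-Za-z_0-9]*)
    | (?P<op>\*\*|<=|>=|==|!=|[-+*/(),<>])
    )""", re.VERBOSE)

_FUNCTIONS = {"sum", "mean", "sqrt", "abs", "min", "max"}
_VARIABLES = {"expt", "sim", "sem", "range"}


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise FormulaError(f"unexpected character {text[pos:].strip()[0]!r} "
                                   f"in formula at position {pos}")
            break
        pos = m.end()
        for kind in ("num", "name", "op"):
            if m.group(kind) is not None:
                tokens.append((kind, m.group(kind)))
                break
    tokens.append(("end", ""))
    return tokens


class _Parser:
    def __init__(self, tokens):
        self.toks = tokens
        self.i = 0

    def peek(self):
        return self.toks[self.i]

    def next(self):
        tok = self.toks[self.i]
        self.i += 1
        return tok

    def expect(self, value):
        kind, val = self.next()
        if val != value:
            raise FormulaError(f"expected {value!r}, got {val!r}")

    # comparison < additive < multiplicative < unary < power < atom
    def parse(self):
        node = self.comparison()
        if self.peek()[0] != "end":
            raise FormulaError(f"trailing input at token {self.peek()[1]!r}")
        return node

    def comparison(self):
        node = self.additive()
        while self.peek()[1] in ("<", ">", "<=", ">=", "==", "!="):
            op = self.next()[1]
            node = ("cmp", op, node, self.additive())
        return node

    def additive(self):
        node = self.multiplicative()
        while self.peek()[1] in ("+", "-"):
            op = self.next()[1]
            node = ("bin", op, node, self.multiplicative())
        return node

    def multiplicative(self):
        node = self.unary()
        while self.peek()[1] in ("*", "/"):
            op = self.next()[1]
            node = ("bin", op, node, self.unary())
        return node

    def unary(self):
        if self.peek()[1] == "-":
            self.next()
            return ("neg", self.unary())
        if self.peek()[1] == "+":
            self.next()
            return self.unary()
        return self.power()

    def power(self):
        base = self.atom()
        if self.peek()[1] == "**":
            self.next()
            return ("bin", "**", base, self.unary())
        return base

    def atom(self):
        kind, val = self.next()
        if kind == "num":
            return ("num", float(val))
        if kind == "name":
            if self.peek()[1] == "(":
                if val not in _FUNCTIONS:
                    raise FormulaError(f"unknown function {val!r} (allowed: "
                                       f"{sorted(_FUNCTIONS)})")
                self.next()
                args = [self.comparison()]
                while self.peek()[1] == ",":
                    self.next()
                    args.append(self.comparison())
                self.expect(")")
                return ("call", val, args)
            if val not in _VARIABLES:
                raise FormulaError(f"unbound name {val!r} (allowed: "
                                   f"{sorted(_VARIABLES)})")
            return ("var", val)
        if val == "(":
            node = self.comparison()
            self.expect(")")
            return node
        raise FormulaError(f"unexpected token {val!r}")


def parse_formula(text: str):
    """Parse a scoring formula into an AST; raises FormulaError on bad input."""
    return _Parser(_tokenize(text)).parse()


def _names_used(node, acc: set[str]) -> set[str]:
    tag = node[0]
    if tag == "var":
        acc.add(node[1])
    elif tag in ("bin", "cmp"):
        _names_used(node[2], acc)
        _names_used(node[3], acc)
    elif tag == "neg":
        _names_used(node[1], acc)
    elif tag == "call":
        for a in node[2]:
            _names_used(a, acc)
    return acc


def _eval(node, env):
    tag = node[0]
    if tag == "num":
        return node[1]
    if tag == "var":
        val = env.get(node[1])
        if val is None:
            raise FormulaError(f"variable {node[1]!r} is not available for "
                               "this experiment (no standard errors?)")
        return val
    if tag == "neg":
        return -_eval(node[1], env)
    if tag in ("bin", "cmp"):
        _, op, left, right = node
        a, b = _eval(left, env), _eval(right, env)
        if op == "+":
            return a + b
        if op == "-":
            return a - b
        if op == "*":
            return a * b
        if op == "/":
            with np.errstate(divide="raise", invalid="raise"):
                try:
                    return a / b
                except FloatingPointError:
                    raise FormulaError("division by zero in scoring formula") \
                        from None
        if op == "**":
            return a ** b
        return {"<": np.less, ">": np.greater, "<=": np.less_equal,
                ">=": np.greater_equal, "==": np.equal,
                "!=": np.not_equal}[op](a, b).astype(float)
    if tag == "call":
        name, args = node[1], [_eval(a, env) for a in node[2]]
        if name in ("sum", "mean", "sqrt", "abs"):
            if len(args) != 1:
                raise FormulaError(f"{name}() takes exactly one argument")
            fn = {"sum": np.sum, "mean": np.mean, "sqrt": np.sqrt,
                  "abs": np.abs}[name]
            return fn(args[0])
        # min/max: one arg reduces, several args combine elementwise
        fn1, fn2 = {"min": (np.min, np.minimum),
                    "max": (np.max, np.maximum)}[name]
        if len(args) == 1:
            return fn1(args[0])
        out = args[0]
        for a in args[1:]:
            out = fn2(out, a)
        return out
    raise FormulaError(f"bad AST node {tag!r}")


def evaluate_score(formula: str | None, expt, sim, sem=None) -> float:
    """Evaluate a scoring formula over matched experiment/simulation values.

    ``range`` is bound to ``max(expt) - min(expt)`` with fallback to
    ``max(abs(expt))`` for flat readouts; a formula using ``range`` when both
    are zero is an error.  The result must reduce to a non-negative scalar.
    """
    expt = np.asarray(expt, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if expt.shape != sim.shape:
        raise FormulaError(f"expt and sim lengths differ "
                           f"({expt.size} vs {sim.size})")
    if expt.size == 0:
        raise FormulaError("no readout points to score")
    ast = parse_formula(formula or DEFAULT_FORMULA)
    used = _names_used(ast, set())
    rng = float(np.max(expt) - np.min(expt))
    if rng == 0.0:
        rng = float(np.max(np.abs(expt)))
    if "range" in used and rng == 0.0:
        raise FormulaError("readout range is degenerate (all values zero); "
                           "the formula's 'range' variable is undefined")
    env = {"expt": expt, "sim": sim, "range": rng,
           "sem": None if sem is None else np.asarray(sem, dtype=float)}
    value = _eval(ast, env)
    value = np.asarray(value, dtype=float)
    if value.size != 1:
        raise FormulaError("scoring formula must reduce to a scalar "
                           f"(got {value.size} values); wrap it in mean()/sum()")
    score = float(value.reshape(()))
    if not np.isfinite(score):
        raise FormulaError(f"scoring formula produced {score}")
    if score < 0:
        raise FormulaError(f"scoring formula produced a negative score "
                           f"({score}); scores must be >= 0")
    return score


def _normalize(values: np.ndarray, mode: str) -> np.ndarray:
    if mode == "absolute":
        return values
    if mode == "foldChange":
        if values[0] == 0:
            raise FormulaError("foldChange normalization: first point is zero")
        return values / values[0]
    if mode == "percentOfMax":
        peak = np.max(np.abs(values))
        if peak == 0:
            raise FormulaError("percentOfMax normalization: all points zero")
        return 100.0 * values / peak
    raise FormulaError(f"unknown normalization {mode!r}")


def score_experiment(doc, output, experiment_id: str = "") -> ScoreResult:
    """Score one experiment document against its simulated output.

    Each readout entry is normalized (its declared mode applied to the
    experimental and the simulated series independently), the simulation is
    sampled at the readout coordinates (linear interpolation on the output
    grid; labelled outputs are matched by label), and all points feed the
    document's scoring formula.  Standard errors are bound to ``sem`` only
    when every point carries one.
    """
    expt_all, sim_all, sem_all = [], [], []
    have_sem = True
    for r in doc.readouts:
        coords = [p[0] for p in r.points]
        evals = np.array([p[1] for p in r.points], dtype=float)
        errs = [p[2] for p in r.points]
        series = np.asarray(output.trajectories[r.entityName], dtype=float)
        if output.labels is not None:
            pos = []
            for label in coords:
                if label not in output.labels:
                    raise FormulaError(f"readout label {label!r} missing "
                                       "from simulation output")
                pos.append(output.labels.index(label))
            svals = series[pos]
        else:
            coords = np.asarray(coords, dtype=float)
            t = np.asarray(output.times, dtype=float)
            span = 1e-9 * max(1.0, abs(t[-1]))
            if coords.min() < t[0] - span or coords.max() > t[-1] + span:
                raise FormulaError(
                    f"readout {r.entityName!r}: coordinate "
                    f"{coords.max():g} outside the simulated span "
                    f"[{t[0]:g}, {t[-1]:g}]")
            svals = np.interp(coords, t, series)
        expt_all.append(_normalize(evals, r.normalization))
        sim_all.append(_normalize(svals, r.normalization))
        if any(e is None for e in errs):
            have_sem = False
        else:
            sem_all.append(np.array(errs, dtype=float))
    expt = np.concatenate(expt_all)
    sim = np.concatenate(sim_all)
    sem = np.concatenate(sem_all) if (have_sem and sem_all) else None
    formula = doc.modelMap.scoringFormula or DEFAULT_FORMULA
    score = evaluate_score(formula, expt, sim, sem)
    return ScoreResult(experimentId=experiment_id, score=score,
                       perPointResiduals=list(expt - sim),
                       formulaUsed=formula, weight=doc.modelMap.weight)


def aggregate_battery(results: list[ScoreResult]) -> float:
    """Weighted mean of per-experiment scores: sum(w*s)/sum(w).

    Failed experiments are excluded from the aggregate; at least one scored
    result with positive total weight is required.
    """
    scored = [r for r in results if not r.failed]
    if not scored:
        raise ValueError("no successfully scored experiments to aggregate")
    wsum = sum(r.weight for r in scored)
    if wsum <= 0:
        raise ValueError("all experiment weights are zero")
    return sum(r.weight * r.score for r in scored) / wsum
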