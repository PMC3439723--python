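"""Core process-algebra model: activities, sequential components, system expressions.

A clinical-pathway model is a PEPA-style stochastic process algebra term.
Sequential components (patient states, resource states) are defined by
``Name = (action, rate).Next + ...;`` equations; the closed system is a
cooperation tree over replicated component instances, written
``system P[N] <a, b> (Q[M] || R);``.  Every activity carries an
exponential rate in units of 1/day; cooperation over a shared action
proceeds at the minimum of the two operands' apparent rates, split
equally over the enabled source combinations (the classic PEPA rule).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Optional, Sequence, Union

logger = logging.getLogger("cpepa")

__all__ = [
    "Activity",
    "Prefix",
    "Choice",
    "ConstantRef",
    "ComponentDef",
    "Instance",
    "Replication",
    "Cooperation",
    "CPPModel",
    "ModelError",
    "ModelSyntaxError",
    "ModelSemanticsError",
    "parse_model",
    "unparse",
    "derivative_set",
    "apparent_rate",
]


class ModelError(Exception):
    """Base class for model-language errors."""


class ModelSyntaxError(ModelError):
    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


class ModelSemanticsError(ModelError):
    pass


# ---------------------------------------------------------------------------
# Abstract syntax
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Activity:
    """An action label with an exponential rate (1/day).

    The rate is the reciprocal of the mean duration of the activity; a
    branch probability folded into the rate (``rho * rate``) is recorded
    in ``weight`` for round-tripping.
    """

    action: str
    rate: float
    weight: Optional[float] = None  # branch probability rho, if any

    def __post_init__(self):
        if not self.action:
            raise ModelSemanticsError("activity action label must be non-empty")
        if not (self.rate > 0) or not math.isfinite(self.rate):
            raise ModelSemanticsError(
                f"activity {self.action!r} has nonpositive rate {self.rate!r}"
            )


@dataclass(frozen=True)
class Prefix:
    activity: Activity
    continuation: "ConstantRef"


@dataclass(frozen=True)
class Choice:
    left: "ProcessExpr"
    right: "ProcessExpr"


@dataclass(frozen=True)
class ConstantRef:
    name: str


ProcessExpr = Union[Prefix, Choice, ConstantRef]


@dataclass(frozen=True)
class ComponentDef:
    name: str
    body: ProcessExpr
    kind: str = "state"  # "state" (patient) or "resource"


@dataclass(frozen=True)
class Instance:
    name: str


@dataclass(frozen=True)
class Replication:
    name: str
    copies: int

    def __post_init__(self):
        if self.copies < 1:
            raise ModelSemanticsError(
                f"replication {self.name}[{self.copies}]: copies must be >= 1"
            )


@dataclass(frozen=True)
class Cooperation:
    left: "SystemExpr"
    right: "SystemExpr"
    sync: frozenset  # empty set == parallel combinator ||


SystemExpr = Union[Instance, Replication, Cooperation]


@dataclass
class CPPModel:
    """A closed pathway model.

    ``definitions`` holds every sequential component equation; ``system``
    is the cooperation tree.  ``metadata`` carries builder-level hints
    (busy-state designations, discharge action, probe marks) that the
    analysis layers consume; it never affects the semantics.
    """

    definitions: dict[str, ComponentDef]
    system: SystemExpr
    rate_constants: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    # -- derived views ------------------------------------------------
    @property
    def states(self) -> list[ComponentDef]:
        return [d for d in self.definitions.values() if d.kind == "state"]

    @property
    def resources(self) -> list[ComponentDef]:
        return [d for d in self.definitions.values() if d.kind == "resource"]

    @property
    def activities(self) -> dict[str, set[float]]:
        """Every activity in the model, as action -> set of rates."""
        acts: dict[str, set[float]] = {}
        for d in self.definitions.values():
            for act, _tgt in iter_prefixes(d.body):
                acts.setdefault(act.action, set()).add(act.rate)
        return acts

    @property
    def constraints(self) -> dict[str, list[str]]:
        """Action -> resource components whose alphabet contains it."""
        cons: dict[str, list[str]] = {}
        for d in self.resources:
            for act, _ in iter_prefixes(d.body):
                cons.setdefault(act.action, []).append(d.name)
        return cons

    #: rate-determination rule for constrained (shared) activities; only the
    #: minimum-of-apparent-rates instance is implemented.
    rate_rule: str = "min-apparent"

    def validate(self) -> "CPPModel":
        validate_model(self)
        return self


# ---------------------------------------------------------------------------
# AST utilities
# ---------------------------------------------------------------------------


def iter_prefixes(expr: ProcessExpr) -> Iterator[tuple[Activity, str]]:
    """Yield (activity, continuation name) for every prefix in ``expr``.

    ConstantRef operands are not followed; see :func:`enabled_transitions`.
    """
    if isinstance(expr, Prefix):
        yield expr.activity, expr.continuation.name
    elif isinstance(expr, Choice):
        yield from iter_prefixes(expr.left)
        yield from iter_prefixes(expr.right)


def enabled_transitions(
    model: CPPModel, name: str, _seen: Optional[frozenset] = None
) -> list[tuple[Activity, str]]:
    """All (activity, target) moves enabled by local state ``name``.

    A bare constant on the right-hand side (``P = Q + (a,r).R``) is an
    alias: the referenced component's moves are enabled in its place.
    """
    if name not in model.definitions:
        raise ModelSemanticsError(f"unknown component {name!r}")
    seen = _seen or frozenset()
    if name in seen:
        raise ModelSemanticsError(f"unguarded recursion through {name!r}")
    out: list[tuple[Activity, str]] = []

    def walk(expr: ProcessExpr):
        if isinstance(expr, Prefix):
            out.append((expr.activity, expr.continuation.name))
        elif isinstance(expr, Choice):
            walk(expr.left)
            walk(expr.right)
        elif isinstance(expr, ConstantRef):
            out.extend(enabled_transitions(model, expr.name, seen | {name}))

    walk(model.definitions[name].body)
    return out


def derivative_set(model: CPPModel, name: str) -> list[str]:
    """All local states reachable from ``name`` (including itself).

    Returned in deterministic breadth-first order, which downstream
    layers use to index local states.
    """
    if name not in model.definitions:
        raise ModelSemanticsError(f"unknown component {name!r}")
    order = [name]
    seen = {name}
    queue = [name]
    while queue:
        current = queue.pop(0)
        for _act, target in enabled_transitions(model, current):
            if target not in seen:
                if target not in model.definitions:
                    raise ModelSemanticsError(
                        f"component {current!r} refers to undefined {target!r}"
                    )
                seen.add(target)
                order.append(target)
                queue.append(target)
    return order


def apparent_rate(expr, action: str, model: Optional[CPPModel] = None) -> float:
    """Total rate at which ``expr`` can perform ``action`` (0 if disabled).

    Accepts a ProcessExpr, or a SystemExpr when ``model`` is given (each
    instance contributes the apparent rate of its initial component; for
    a replication this is copies x the component's apparent rate, and a
    cooperation contributes min of both sides for shared actions).
    """
    if isinstance(expr, (Prefix, Choice, ConstantRef)):
        if isinstance(expr, Prefix):
            return expr.activity.rate if expr.activity.action == action else 0.0
        if isinstance(expr, Choice):
            return apparent_rate(expr.left, action, model) + apparent_rate(
                expr.right, action, model
            )
        if model is None:
            raise ModelSemanticsError(
                "apparent rate of a constant reference needs the model context"
            )
        return sum(
            act.rate
            for act, _ in enabled_transitions(model, expr.name)
            if act.action == action
        )
    # system expressions
    if model is None:
        raise ModelSemanticsError("apparent rate of a system expression needs the model")
    if isinstance(expr, Instance):
        return apparent_rate(ConstantRef(expr.name), action, model)
    if isinstance(expr, Replication):
        return expr.copies * apparent_rate(ConstantRef(expr.name), action, model)
    if isinstance(expr, Cooperation):
        left = apparent_rate(expr.left, action, model)
        right = apparent_rate(expr.right, action, model)
        if action in expr.sync:
            return min(left, right)
        return left + right
    raise TypeError(f"unsupported expression {expr!r}")


def system_leaves(system: SystemExpr) -> list[SystemExpr]:
    if isinstance(system, (Instance, Replication)):
        return [system]
    return system_leaves(system.left) + system_leaves(system.right)


def system_alphabet(model: CPPModel, name: str) -> set[str]:
    """Action alphabet of a sequential component (over its derivative set)."""
    acts: set[str] = set()
    for local in derivative_set(model, name):
        acts.update(a.action for a, _ in enabled_transitions(model, local))
    return acts


def validate_model(model: CPPModel) -> None:
    if model.system is None:
        raise ModelSemanticsError("model has no system expression")
    for leaf in system_leaves(model.system):
        derivative_set(model, leaf.name)  # raises on dangling references
    # components not in the system are still checked for dangling refs
    for name in model.definitions:
        derivative_set(model, name)

    def check(node: SystemExpr):
        if isinstance(node, Cooperation):
            left_alpha: set[str] = set()
            right_alpha: set[str] = set()
            for leaf in system_leaves(node.left):
                left_alpha |= system_alphabet(model, leaf.name)
            for leaf in system_leaves(node.right):
                right_alpha |= system_alphabet(model, leaf.name)
            for action in node.sync:
                if action not in left_alpha or action not in right_alpha:
                    raise ModelSemanticsError(
                        f"cooperation action {action!r} does not occur on both sides"
                    )
            check(node.left)
            check(node.right)

    check(model.system)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<comment>//[^\n]*|\#[^\n]*)
  | (?P<number>\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?)
  | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<op><|>|\|\||[()\[\].,;+*=])
    """,
    re.VERBOSE,
)


@dataclass
class _Token:
    kind: str
    text: str
    line: int
    col: int


def _tokenize(text: str) -> list[_Token]:
    tokens = []
    line, col = 1, 1
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise ModelSyntaxError(f"unexpected character {text[pos]!r}", line, col)
        value = m.group(0)
        kind = m.lastgroup
        if kind not in ("ws", "comment"):
            tokens.append(_Token(kind, value, line, col))
        newlines = value.count("\n")
        if newlines:
            line += newlines
            col = len(value) - value.rfind("\n")
        else:
            col += len(value)
        pos = m.end()
    tokens.append(_Token("eof", "", line, col))
    return tokens


class _Parser:
    """Recursive-descent parser for the pathway model language."""

    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.pos = 0

    # -- token helpers -------------------------------------------------
    def peek(self) -> _Token:
        return self.tokens[self.pos]

    def next(self) -> _Token:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, text: str) -> _Token:
        tok = self.next()
        if tok.text != text:
            raise ModelSyntaxError(
                f"expected {text!r}, found {tok.text or 'end of input'!r}",
                tok.line,
                tok.col,
            )
        return tok

    def error(self, message: str):
        tok = self.peek()
        raise ModelSyntaxError(message, tok.line, tok.col)

    # -- grammar -------------------------------------------------------
    def parse(self) -> tuple[dict, dict, Optional[SystemExpr]]:
        definitions: dict[str, tuple[ComponentDef, _Token]] = {}
        rate_constants: dict[str, float] = {}
        system: Optional[SystemExpr] = None
        while self.peek().kind != "eof":
            tok = self.peek()
            if tok.text == "system":
                self.next()
                if system is not None:
                    raise ModelSyntaxError("duplicate system line", tok.line, tok.col)
                system = self.parse_system()
                self.expect(";")
                continue
            if tok.kind != "name":
                self.error("expected a definition or a system line")
            name = self.next().text
            self.expect("=")
            if self.peek().kind == "number":
                # numeric rate-constant binding: r_name = 24;
                value = float(self.next().text)
                if name in rate_constants:
                    raise ModelSyntaxError(
                        f"duplicate rate constant {name!r}", tok.line, tok.col
                    )
                rate_constants[name] = value
            else:
                body = self.parse_process()
                if name in definitions:
                    raise ModelSyntaxError(
                        f"duplicate definition of {name!r}", tok.line, tok.col
                    )
                definitions[name] = (body, tok)
            self.expect(";")
        return definitions, rate_constants, system

    def parse_process(self):
        terms = [self.parse_prefix_term()]
        while self.peek().text == "+":
            self.next()
            terms.append(self.parse_prefix_term())
        expr = terms[0]
        for term in terms[1:]:
            expr = ("choice", expr, term)
        return expr

    def parse_prefix_term(self):
        tok = self.peek()
        if tok.text == "(":
            self.next()
            if self.peek().kind != "name":
                self.error("expected an action label")
            action = self.next().text
            self.expect(",")
            rate_expr = self.parse_rate_expr()
            self.expect(")")
            self.expect(".")
            cont_tok = self.peek()
            if cont_tok.kind != "name":
                self.error("expected a component name after '.'")
            cont = self.next().text
            return ("prefix", action, rate_expr, cont, tok)
        if tok.kind == "name":
            return ("const", self.next().text)
        self.error("expected '(' or a component name")

    def parse_rate_expr(self):
        factors = [self.parse_rate_factor()]
        while self.peek().text == "*":
            self.next()
            factors.append(self.parse_rate_factor())
        return factors

    def parse_rate_factor(self):
        tok = self.next()
        if tok.kind == "number":
            return ("num", float(tok.text), tok)
        if tok.kind == "name":
            return ("ref", tok.text, tok)
        raise ModelSyntaxError("expected a rate (number or constant)", tok.line, tok.col)

    def parse_system(self) -> SystemExpr:
        expr = self.parse_system_term()
        while True:
            tok = self.peek()
            if tok.text == "<":
                self.next()
                actions = []
                if self.peek().text != ">":
                    actions.append(self.expect_name())
                    while self.peek().text == ",":
                        self.next()
                        actions.append(self.expect_name())
                self.expect(">")
                right = self.parse_system_term()
                expr = Cooperation(expr, right, frozenset(actions))
            elif tok.text == "||":
                self.next()
                right = self.parse_system_term()
                expr = Cooperation(expr, right, frozenset())
            else:
                return expr

    def expect_name(self) -> str:
        tok = self.next()
        if tok.kind != "name":
            raise ModelSyntaxError("expected an action label", tok.line, tok.col)
        return tok.text

    def parse_system_term(self) -> SystemExpr:
        tok = self.peek()
        if tok.text == "(":
            self.next()
            inner = self.parse_system()
            self.expect(")")
            return inner
        if tok.kind != "name":
            self.error("expected a component name")
        name = self.next().text
        if self.peek().text == "[":
            self.next()
            count_tok = self.next()
            if count_tok.kind != "number" or "." in count_tok.text:
                raise ModelSyntaxError(
                    "replication count must be a positive integer",
                    count_tok.line,
                    count_tok.col,
                )
            self.expect("]")
            copies = int(count_tok.text)
            if copies < 1:
                raise ModelSyntaxError(
                    "replication count must be >= 1", count_tok.line, count_tok.col
                )
            return Replication(name, copies)
        return Instance(name)


def _resolve_rate(factors, rate_constants: Mapping[str, float]) -> tuple[float, Optional[float]]:
    """Evaluate a rate expression; returns (rate, weight) where weight is a
    literal branch probability when the expression is ``rho * name``."""
    value = 1.0
    weight = None
    if len(factors) == 2 and factors[0][0] == "num" and factors[1][0] == "ref":
        if 0 < factors[0][1] <= 1:
            weight = factors[0][1]
    for kind, payload, tok in factors:
        if kind == "num":
            value *= payload
        else:
            if payload not in rate_constants:
                raise ModelSyntaxError(
                    f"undefined rate constant {payload!r}", tok.line, tok.col
                )
            value *= rate_constants[payload]
    return value, weight


def _build_process(raw, rate_constants) -> ProcessExpr:
    if raw[0] == "const":
        return ConstantRef(raw[1])
    if raw[0] == "prefix":
        _, action, rate_expr, cont, tok = raw
        rate, weight = _resolve_rate(rate_expr, rate_constants)
        if not rate > 0:
            raise ModelSyntaxError(
                f"nonpositive rate for action {action!r}", tok.line, tok.col
            )
        return Prefix(Activity(action, rate, weight), ConstantRef(cont))
    if raw[0] == "choice":
        return Choice(
            _build_process(raw[1], rate_constants),
            _build_process(raw[2], rate_constants),
        )
    raise AssertionError(raw)


def parse_model(text: str, require_system: bool = True) -> CPPModel:
    """Parse a pathway model description into a validated :class:`CPPModel`.

    Raises :class:`ModelSyntaxError` with line/column on malformed input,
    and :class:`ModelSemanticsError` on dangling references or invalid
    cooperation sets.  With ``require_system=False`` a fragment without a
    system line is accepted (useful for inspecting single equations).
    """
    raw_defs, rate_constants, system = _Parser(text).parse()
    definitions = {}
    for name, (raw_body, _tok) in raw_defs.items():
        body = _build_process(raw_body, rate_constants)
        definitions[name] = ComponentDef(name, body, _infer_kind(name))
    if system is None:
        if require_system:
            raise ModelSemanticsError("model has no system line")
        if definitions:
            first = next(iter(definitions))
            system = Instance(first)
    model = CPPModel(definitions, system, rate_constants)
    validate_model(model)
    return model


def parse_component(text: str) -> ComponentDef:
    """Parse a single defining equation (no system line, no validation)."""
    raw_defs, rate_constants, _ = _Parser(text).parse()
    if len(raw_defs) != 1:
        raise ModelSemanticsError("expected exactly one defining equation")
    name, (raw_body, _) = next(iter(raw_defs.items()))
    # unbound rate names default to a placeholder of 1.0 so that fragments
    # with symbolic rates (r_do_FAST) remain inspectable
    class _Defaulting(dict):
        def __contains__(self, key):
            return True

        def __getitem__(self, key):
            return dict.get(self, key, 1.0)

    return ComponentDef(name, _build_process(raw_body, _Defaulting(rate_constants)), _infer_kind(name))


def _infer_kind(name: str) -> str:
    lowered = name.lower()
    if "_idle" in lowered or "_busy" in lowered:
        return "resource"
    return "state"


# ---------------------------------------------------------------------------
# Unparsing
# ---------------------------------------------------------------------------


def _format_rate(rate: float, weight: Optional[float]) -> str:
    if weight is not None:
        base = rate / weight
        return f"{_format_number(weight)}*{_format_number(base)}"
    return _format_number(rate)


def _format_number(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


def _unparse_process(expr: ProcessExpr) -> str:
    if isinstance(expr, Prefix):
        return (
            f"({expr.activity.action}, {_format_rate(expr.activity.rate, expr.activity.weight)})"
            f".{expr.continuation.name}"
        )
    if isinstance(expr, Choice):
        return f"{_unparse_process(expr.left)} + {_unparse_process(expr.right)}"
    return expr.name


def _unparse_system(expr: SystemExpr) -> str:
    if isinstance(expr, Instance):
        return expr.name
    if isinstance(expr, Replication):
        return f"{expr.name}[{expr.copies}]"
    left = _unparse_system(expr.left)
    right = _unparse_system(expr.right)
    if isinstance(expr.right, Cooperation):
        right = f"({right})"
    if isinstance(expr.left, Cooperation):
        left = f"({left})"
    if expr.sync:
        op = f"<{', '.join(sorted(expr.sync))}>"
    else:
        op = "||"
    return f"{left} {op} {right}"


def unparse(model: CPPModel) -> str:
    """Render a model back to its canonical textual form.

    Rate constants are folded into numeric literals, so
    ``parse . unparse`` is the identity on parsed models and
    ``unparse . parse`` is idempotent on text.
    """
    lines = [f"{d.name} = {_unparse_process(d.body)};" for d in model.definitions.values()]
    lines.append(f"system {_unparse_system(model.system)};")
    return "\n".join(lines) + "\n"
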