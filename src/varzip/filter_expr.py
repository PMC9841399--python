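"""Parse and evaluate ``-i`` include expressions.

Grammar (conventional precedence, all binary operators left-associative)::

    expr    := or
    or      := and ( '||' and )*
    and     := cmp ( '&&' cmp )*
    cmp     := add ( ('<'|'<='|'>'|'>='|'=='|'!=') add )*
    add     := mul ( ('+'|'-') mul )*
    mul     := unary ( ('*'|'/') unary )*
    unary   := ('!'|'-') unary | primary
    primary := NUMBER | STRING | IDENT | '(' expr ')'

Identifiers are field aliases supplied by the archives.  Arithmetic is
real-valued (``an / 2`` gives exact halves).  String-typed identifiers
support only ``==`` and ``!=`` against quoted literals.  The expression must
be boolean at the root — a bare numeric expression is a type error, not a
truthiness test.  ``&&``/``||`` short-circuit.  Division by zero is a
record-level :class:`EvaluationError`; the annotator treats such records as
not passing.  Missing values participate as their sentinel (-1 or ".") with
no special NA logic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import EvaluationError, ExpressionError

# --- AST -------------------------------------------------------------------


@dataclass(frozen=True)
class Num:
    value: float


@dataclass(frozen=True)
class Str:
    value: str


@dataclass(frozen=True)
class Ident:
    name: str


@dataclass(frozen=True)
class Unary:
    op: str
    operand: object


@dataclass(frozen=True)
class Binary:
    op: str
    left: object
    right: object


FilterAST = Num | Str | Ident | Unary | Binary

# --- tokenizer -------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<number>(\d+\.\d*|\.\d+|\d+)([eE][+-]?\d+)?)
  | (?P<ident>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<string>'[^']*'|"[^"]*")
  | (?P<op>\|\||&&|<=|>=|==|!=|[<>+\-*/!()])
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ExpressionError(
                f"syntax error at position {pos}: unexpected {text[pos]!r}"
            )
        kind = m.lastgroup
        if kind != "ws":
            tokens.append((kind, m.group(), pos))
        pos = m.end()
    tokens.append(("eof", "", len(text)))
    return tokens


# --- parser ----------------------------------------------------------------


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def fail(self, msg: str):
        kind, val, pos = self.peek()
        got = "end of expression" if kind == "eof" else repr(val)
        raise ExpressionError(f"syntax error at position {pos}: {msg}, got {got}")

    def _binary_level(self, sub, ops):
        node = sub()
        while self.peek()[0] == "op" and self.peek()[1] in ops:
            op = self.next()[1]
            node = Binary(op, node, sub())
        return node

    def parse(self) -> FilterAST:
        node = self.or_expr()
        if self.peek()[0] != "eof":
            self.fail("expected end of expression")
        return node

    def or_expr(self):
        return self._binary_level(self.and_expr, ("||",))

    def and_expr(self):
        return self._binary_level(self.cmp_expr, ("&&",))

    def cmp_expr(self):
        return self._binary_level(self.add_expr, ("<", "<=", ">", ">=", "==", "!="))

    def add_expr(self):
        return self._binary_level(self.mul_expr, ("+", "-"))

    def mul_expr(self):
        return self._binary_level(self.unary_expr, ("*", "/"))

    def unary_expr(self):
        kind, val, _ = self.peek()
        if kind == "op" and val in ("!", "-"):
            self.next()
            return Unary(val, self.unary_expr())
        return self.primary()

    def primary(self):
        kind, val, _ = self.next()
        if kind == "number":
            return Num(float(val))
        if kind == "string":
            return Str(val[1:-1])
        if kind == "ident":
            return Ident(val)
        if kind == "op" and val == "(":
            node = self.or_expr()
            k, v, _ = self.next()
            if not (k == "op" and v == ")"):
                self.i -= 1
                self.fail("expected ')'")
            return node
        self.i -= 1
        self.fail("expected a value")


def parse(expression_text: str) -> FilterAST:
    """Parse an include expression into an AST."""
    if not expression_text or not expression_text.strip():
        raise ExpressionError("empty filter expression")
    return _Parser(expression_text).parse()


# --- static checks ---------------------------------------------------------


def identifiers(ast: FilterAST) -> set[str]:
    """All field aliases referenced by the expression."""
    if isinstance(ast, Ident):
        return {ast.name}
    if isinstance(ast, Unary):
        return identifiers(ast.operand)
    if isinstance(ast, Binary):
        return identifiers(ast.left) | identifiers(ast.right)
    return set()


_CMP_OPS = ("<", "<=", ">", ">=")
_EQ_OPS = ("==", "!=")
_ARITH_OPS = ("+", "-", "*", "/")


def check_types(ast: FilterAST, types: dict[str, str]) -> str:
    """Type-check against alias types ('num' or 'str'); root must be 'bool'.

    Raises :class:`ExpressionError` on unknown identifiers or mismatches, so
    bad expressions fail before any record is processed.
    """
    t = _type_of(ast, types)
    if t != "bool":
        raise ExpressionError(
            f"filter must be a boolean expression, not {t!r} "
            "(compare against a threshold, e.g. 'af < 0.01')"
        )
    return t


def _type_of(ast, types) -> str:
    if isinstance(ast, Num):
        return "num"
    if isinstance(ast, Str):
        return "str"
    if isinstance(ast, Ident):
        t = types.get(ast.name)
        if t is None:
            raise ExpressionError(
                f"unknown field {ast.name!r} in filter; known fields: "
                + ", ".join(sorted(types)) if types else f"unknown field {ast.name!r}"
            )
        return t
    if isinstance(ast, Unary):
        t = _type_of(ast.operand, types)
        want = "bool" if ast.op == "!" else "num"
        if t != want:
            raise ExpressionError(f"operator {ast.op!r} needs a {want} operand, got {t}")
        return want
    lt = _type_of(ast.left, types)
    rt = _type_of(ast.right, types)
    op = ast.op
    if op in ("&&", "||"):
        if lt != "bool" or rt != "bool":
            raise ExpressionError(f"operator {op!r} needs boolean operands")
        return "bool"
    if op in _EQ_OPS:
        if lt != rt or lt == "bool":
            raise ExpressionError(f"operator {op!r} cannot compare {lt} with {rt}")
        return "bool"
    if op in _CMP_OPS:
        if lt != "num" or rt != "num":
            raise ExpressionError(f"operator {op!r} needs numeric operands")
        return "bool"
    if lt != "num" or rt != "num":
        raise ExpressionError(f"arithmetic {op!r} needs numeric operands, got {lt}, {rt}")
    return "num"


# --- evaluation ------------------------------------------------------------


def evaluate(ast: FilterAST, env: dict[str, object]) -> bool:
    """Evaluate against per-variant values; the result must be boolean."""
    result = _eval(ast, env)
    if not isinstance(result, bool):
        raise ExpressionError("filter did not evaluate to a boolean")
    return result


def _eval(ast, env):
    if isinstance(ast, Num):
        return ast.value
    if isinstance(ast, Str):
        return ast.value
    if isinstance(ast, Ident):
        try:
            v = env[ast.name]
        except KeyError:
            raise ExpressionError(f"unknown field {ast.name!r} in filter") from None
        return float(v) if isinstance(v, (int, float)) and not isinstance(v, bool) else v
    if isinstance(ast, Unary):
        v = _eval(ast.operand, env)
        if ast.op == "!":
            if not isinstance(v, bool):
                raise ExpressionError("'!' needs a boolean operand")
            return not v
        if not isinstance(v, float):
            raise ExpressionError("unary '-' needs a numeric operand")
        return -v
    op = ast.op
    if op == "&&":
        left = _eval(ast.left, env)
        if not isinstance(left, bool):
            raise ExpressionError("'&&' needs boolean operands")
        if not left:
            return False
        right = _eval(ast.right, env)
        if not isinstance(right, bool):
            raise ExpressionError("'&&' needs boolean operands")
        return right
    if op == "||":
        left = _eval(ast.left, env)
        if not isinstance(left, bool):
            raise ExpressionError("'||' needs boolean operands")
        if left:
            return True
        right = _eval(ast.right, env)
        if not isinstance(right, bool):
            raise ExpressionError("'||' needs boolean operands")
        return right
    left = _eval(ast.left, env)
    right = _eval(ast.right, env)
    if op in _EQ_OPS:
        if isinstance(left, bool) or isinstance(right, bool) or type(left) is not type(right):
            raise ExpressionError(f"operator {op!r} cannot compare these operand types")
        return (left == right) if op == "==" else (left != right)
    if not isinstance(left, float) or not isinstance(right, float):
        raise ExpressionError(f"operator {op!r} needs numeric operands")
    if op == "<":
        return left < right
    if op == "<=":
        return left <= right
    if op == ">":
        return left > right
    if op == ">=":
        return left >= right
    if op == "+":
        return left + right
    if op == "-":
        return left - right
    if op == "*":
        return left * right
    if op == "/":
        if right == 0.0:
            raise EvaluationError("division by zero in filter expression")
        return left / right
    raise ExpressionError(f"unknown operator {op!r}")
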