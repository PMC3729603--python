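"""The mapping/scoring expression mini-language.

Instruments bin raw response values and compute runtime scores with tiny
arithmetic expressions over a single variable named ``value``.  The grammar is
deliberately closed — numeric literals, ``value``, ``+ - * /``, unary minus
and parentheses — so a document can never smuggle in code:

    expr    := term (('+' | '-') term)*
    term    := factor (('*' | '/') factor)*
    factor  := '-' factor | primary
    primary := NUMBER | 'value' | '(' expr ')'

Any other identifier, function call or operator is a parse error with a
character position.  Evaluation is pure and raises only on division by zero.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import EvaluationError, ExpressionError

_OPS = {"+", "-", "*", "/"}


@dataclass(frozen=True)
class Node:
    """One node of a parsed expression tree."""

    kind: str  # "num" | "var" | "neg" | one of + - * /
    value: float | None = None
    left: "Node | None" = None
    right: "Node | None" = None


@dataclass(frozen=True)
class Expression:
    """A parsed arithmetic expression over the variable ``value``."""

    source: str
    root: Node

    def __call__(self, value: float) -> float:
        return evaluate(self, value)


@dataclass(frozen=True)
class _Token:
    kind: str  # "num" | "name" | "op" | "lparen" | "rparen"
    text: str
    pos: int


def _tokenize(source: str) -> list[_Token]:
    tokens: list[_Token] = []
    i, n = 0, len(source)
    while i < n:
        ch = source[i]
        if ch.isspace():
            i += 1
        elif ch.isdigit() or ch == ".":
            j = i
            seen_dot = False
            while j < n and (source[j].isdigit() or (source[j] == "." and not seen_dot)):
                seen_dot = seen_dot or source[j] == "."
                j += 1
            if source[i:j] == ".":
                raise ExpressionError("malformed number", i)
            tokens.append(_Token("num", source[i:j], i))
            i = j
        elif ch.isalpha() or ch == "_":
            j = i
            while j < n and (source[j].isalnum() or source[j] == "_"):
                j += 1
            tokens.append(_Token("name", source[i:j], i))
            i = j
        elif ch in _OPS:
            tokens.append(_Token("op", ch, i))
            i += 1
        elif ch == "(":
            tokens.append(_Token("lparen", ch, i))
            i += 1
        elif ch == ")":
            tokens.append(_Token("rparen", ch, i))
            i += 1
        else:
            raise ExpressionError(f"unexpected character {ch!r}", i)
    return tokens


class _Parser:
    def __init__(self, source: str):
        self.source = source
        self.tokens = _tokenize(source)
        self.index = 0

    def peek(self) -> _Token | None:
        return self.tokens[self.index] if self.index < len(self.tokens) else None

    def advance(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise ExpressionError("unexpected end of expression", len(self.source))
        self.index += 1
        return tok

    def parse(self) -> Node:
        node = self.expr()
        trailing = self.peek()
        if trailing is not None:
            raise ExpressionError(f"unexpected {trailing.text!r}", trailing.pos)
        return node

    def expr(self) -> Node:
        node = self.term()
        while (tok := self.peek()) is not None and tok.text in ("+", "-"):
            self.advance()
            node = Node(tok.text, left=node, right=self.term())
        return node

    def term(self) -> Node:
        node = self.factor()
        while (tok := self.peek()) is not None and tok.text in ("*", "/"):
            self.advance()
            node = Node(tok.text, left=node, right=self.factor())
        return node

    def factor(self) -> Node:
        tok = self.peek()
        if tok is not None and tok.text == "-":
            self.advance()
            return Node("neg", left=self.factor())
        return self.primary()

    def primary(self) -> Node:
        tok = self.advance()
        if tok.kind == "num":
            return Node("num", value=float(tok.text))
        if tok.kind == "name":
            if tok.text != "value":
                raise ExpressionError(
                    f"unknown identifier {tok.text!r}; only 'value' is allowed", tok.pos
                )
            nxt = self.peek()
            if nxt is not None and nxt.kind == "lparen":
                raise ExpressionError("function calls are not allowed", nxt.pos)
            return Node("var")
        if tok.kind == "lparen":
            node = self.expr()
            closing = self.advance()
            if closing.kind != "rparen":
                raise ExpressionError("expected ')'", closing.pos)
            return node
        raise ExpressionError(f"unexpected {tok.text!r}", tok.pos)


def parse_expression(source: str) -> Expression:
    """Parse *source* into an :class:`Expression`; reject anything beyond the grammar."""
    return Expression(source=source, root=_Parser(source).parse())


def _eval(node: Node, value: float) -> float:
    if node.kind == "num":
        return node.value  # type: ignore[return-value]
    if node.kind == "var":
        return value
    if node.kind == "neg":
        return -_eval(node.left, value)  # type: ignore[arg-type]
    left = _eval(node.left, value)  # type: ignore[arg-type]
    right = _eval(node.right, value)  # type: ignore[arg-type]
    if node.kind == "+":
        return left + right
    if node.kind == "-":
        return left - right
    if node.kind == "*":
        return left * right
    if node.kind == "/":
        if right == 0:
            raise EvaluationError(f"division by zero in {node.kind!r} expression")
        return left / right
    raise AssertionError(f"unknown node kind {node.kind!r}")


def evaluate(expr: Expression, value: float) -> float:
    """Evaluate *expr* with the variable ``value`` bound to *value*.  Pure."""
    return _eval(expr.root, value)
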