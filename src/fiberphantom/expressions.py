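"""Safe evaluation of parametric expressions in the single variable ``t``.

Fiber trajectories can be defined by textual expressions such as
``"50*sin(t*pi)"``.  The expressions are compiled through Python's ``ast``
module and restricted to a whitelist of arithmetic operators, elementary
functions and the constants ``pi`` and ``e``; no attribute access, no names
outside the whitelist, no calls to anything but the listed functions.  All
functions are the numpy ufuncs, so a compiled expression evaluates
vectorized over an array of ``t`` samples.
"""

from __future__ import annotations

import ast
from collections.abc import Callable

import numpy as np

from .errors import ExpressionError

_FUNCTIONS: dict[str, Callable] = {
    "sin": np.sin,
    "cos": np.cos,
    "tan": np.tan,
    "exp": np.exp,
    "log": np.log,
    "abs": np.abs,
    "sqrt": np.sqrt,
}

_CONSTANTS: dict[str, float] = {"pi": np.pi, "e": np.e}

_BINOPS = {
    ast.Add: np.add,
    ast.Sub: np.subtract,
    ast.Mult: np.multiply,
    ast.Div: np.divide,
    ast.Pow: np.power,
    ast.Mod: np.mod,
    ast.FloorDiv: np.floor_divide,
}

_UNARYOPS = {ast.UAdd: lambda x: x, ast.USub: np.negative}


def _check(node: ast.AST, source: str) -> None:
    if isinstance(node, ast.Expression):
        _check(node.body, source)
    elif isinstance(node, ast.BinOp):
        if type(node.op) not in _BINOPS:
            raise ExpressionError(
                f"operator {type(node.op).__name__!r} not allowed in {source!r}"
            )
        _check(node.left, source)
        _check(node.right, source)
    elif isinstance(node, ast.UnaryOp):
        if type(node.op) not in _UNARYOPS:
            raise ExpressionError(
                f"operator {type(node.op).__name__!r} not allowed in {source!r}"
            )
        _check(node.operand, source)
    elif isinstance(node, ast.Call):
        if not isinstance(node.func, ast.Name) or node.func.id not in _FUNCTIONS:
            token = getattr(node.func, "id", ast.dump(node.func))
            raise ExpressionError(f"unknown function {token!r} in {source!r}")
        if node.keywords or len(node.args) != 1:
            raise ExpressionError(
                f"function {node.func.id!r} takes exactly one argument in {source!r}"
            )
        _check(node.args[0], source)
    elif isinstance(node, ast.Name):
        if node.id != "t" and node.id not in _CONSTANTS:
            raise ExpressionError(f"unknown name {node.id!r} in {source!r}")
    elif isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise ExpressionError(f"non-numeric literal {node.value!r} in {source!r}")
    else:
        raise ExpressionError(
            f"syntax element {type(node).__name__!r} not allowed in {source!r}"
        )


def compile_expression(source: str) -> Callable[[np.ndarray], np.ndarray]:
    """Compile ``source`` into a vectorized function of ``t``.

    Raises
    ------
    ExpressionError
        If the expression cannot be parsed or references anything outside
        the whitelist; the message names the offending token.
    """
    try:
        tree = ast.parse(source, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"cannot parse {source!r}: {exc.msg}") from exc
    _check(tree, source)

    def _eval(node: ast.AST, t: np.ndarray):
        if isinstance(node, ast.Expression):
            return _eval(node.body, t)
        if isinstance(node, ast.BinOp):
            return _BINOPS[type(node.op)](_eval(node.left, t), _eval(node.right, t))
        if isinstance(node, ast.UnaryOp):
            return _UNARYOPS[type(node.op)](_eval(node.operand, t))
        if isinstance(node, ast.Call):
            return _FUNCTIONS[node.func.id](_eval(node.args[0], t))
        if isinstance(node, ast.Name):
            return t if node.id == "t" else _CONSTANTS[node.id]
        if isinstance(node, ast.Constant):
            return node.value
        raise AssertionError("unreachable")  # guarded by _check

    def func(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        with np.errstate(all="raise"):
            try:
                out = _eval(tree, t)
            except FloatingPointError as exc:
                raise ExpressionError(
                    f"evaluation of {source!r} failed: {exc}"
                ) from exc
        return np.broadcast_to(np.asarray(out, dtype=float), t.shape).copy()

    func.source = source  # type: ignore[attr-defined]
    return func
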