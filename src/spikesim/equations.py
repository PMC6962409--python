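"""Equation-set model definitions and exponential-Euler kernel generation.

A model is written in a minimal DSL, one ordinary differential equation per
line::

    dV/dt = (gL*(VL - V) + gE*(VE - V)) / CM
    dm/dt = alpha_m(V)*(1 - m) - beta_m(V)*m
    dgE/dt = -gE / tauE

Expressions may use +, -, *, /, ** and parentheses, the function ``exp``,
and the six built-in Hodgkin-Huxley rate curves ``alpha_m`` ... ``beta_n``
applied to another state variable.  Every ODE must be *conditionally
linear*: for each variable x the right-hand side must decompose as
``a + b*x`` where a and b may depend on the other state variables,
parameters and declared input terms, but not on x itself.  This is exactly
the class of systems the exponential-Euler scheme integrates by advancing
each variable with the closed-form solution of dx/dt = a + b*x over one
time step, with a and b frozen at their step-start values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .rates import RATE_FUNCTIONS

__all__ = [
    "ModelError",
    "ModelSyntaxError",
    "LinearityError",
    "UnresolvedSymbolError",
    "EquationSet",
    "parse_model",
    "ExponentialEulerKernel",
    "build_exponential_euler_kernel",
]


class ModelError(ValueError):
    """Base class for model-definition errors."""


class ModelSyntaxError(ModelError):
    """Malformed equation text."""


class LinearityError(ModelError):
    """An RHS is not decomposable as a + b*x for its own variable x."""


class UnresolvedSymbolError(ModelError):
    """An RHS references a symbol that is neither a state variable, a
    parameter nor a declared input term."""


_ODE_RE = re.compile(r"^\s*d([A-Za-z_]\w*)\s*/\s*dt\s*=\s*(.+?)\s*$")

# Function heads the DSL accepts, and their numeric implementations.
_FUNCTION_HEADS = {name: sp.Function(name) for name in RATE_FUNCTIONS}
_NUMERIC_FUNCTIONS = dict(RATE_FUNCTIONS)

# |b*dt| below this uses the series limit x + a*dt; avoids catastrophic
# cancellation in expm1(b*dt)/b.
_B_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class EquationSet:
    """A neuron or synapse model as conditionally linear ODEs.

    Attributes
    ----------
    state_variables : tuple of str
        Variable names in definition order.
    odes : dict
        Variable name -> sympy RHS expression.
    parameters : dict
        Name -> numeric value (in the caller's consistent unit system).
    input_terms : tuple of str
        Names of externally supplied quantities appearing in the RHSs.
    linear_coefficients : dict
        Variable name -> (a, b) sympy expressions with RHS == a + b*x.
    """

    state_variables: tuple
    odes: dict
    parameters: dict
    input_terms: tuple = ()
    linear_coefficients: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.linear_coefficients:
            coeffs = {}
            for name in self.state_variables:
                coeffs[name] = _decompose(name, self.odes[name])
            object.__setattr__(self, "linear_coefficients", coeffs)


def _decompose(name: str, rhs: sp.Expr):
    x = sp.Symbol(name)
    b = sp.diff(rhs, x)
    if b.has(x):
        raise LinearityError(
            f"RHS of d{name}/dt is not of the form a + b*{name}: "
            f"the coefficient of {name} still depends on {name}"
        )
    a = rhs.subs(x, 0)
    if a.has(x):  # pragma: no cover - subs removes all occurrences
        raise LinearityError(f"RHS of d{name}/dt could not be decomposed")
    return a, b


def parse_model(definition_text: str, parameters: dict, input_terms=()) -> EquationSet:
    """Parse DSL text into a validated :class:`EquationSet`.

    Raises :class:`ModelSyntaxError` for malformed lines,
    :class:`UnresolvedSymbolError` for free symbols not covered by the
    state variables, ``parameters`` or ``input_terms``, and
    :class:`LinearityError` when an RHS is not conditionally linear.
    """
    input_terms = tuple(input_terms)
    odes = {}
    order = []
    for lineno, raw in enumerate(definition_text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _ODE_RE.match(line)
        if m is None:
            raise ModelSyntaxError(f"line {lineno}: expected 'dX/dt = expr', got {raw!r}")
        name, expr_text = m.group(1), m.group(2)
        if name in odes:
            raise ModelSyntaxError(f"line {lineno}: duplicate equation for {name}")
        # pre-map every identifier to a plain Symbol so names like
        # "beta" or "gamma" are never read as sympy special functions
        local = {
            ident: sp.Symbol(ident)
            for ident in set(re.findall(r"[A-Za-z_]\w*", expr_text))
        }
        local.update({"exp": sp.exp, **_FUNCTION_HEADS})
        try:
            expr = sp.sympify(expr_text, locals=local)
        except (sp.SympifyError, SyntaxError, TypeError) as exc:
            raise ModelSyntaxError(f"line {lineno}: cannot parse {expr_text!r}: {exc}") from None
        odes[name] = expr
        order.append(name)
    if not order:
        raise ModelSyntaxError("empty model definition")

    known = set(order) | set(parameters) | set(input_terms)
    for name in order:
        for sym in odes[name].free_symbols:
            if sym.name not in known:
                raise UnresolvedSymbolError(
                    f"symbol {sym.name!r} in d{name}/dt is not a state variable, "
                    f"parameter or input term"
                )
    return EquationSet(
        state_variables=tuple(order),
        odes=odes,
        parameters=dict(parameters),
        input_terms=input_terms,
    )


class ExponentialEulerKernel:
    """Compiled one-step state updater for an :class:`EquationSet`.

    Each call advances every variable synchronously from step-start values
    by the closed form of dx/dt = a + b*x:

        x <- x + (x + a/b) * (e^{b*dt} - 1)

    with the analytic limit x <- x + a*dt when |b*dt| < 1e-12.  Pure decay
    equations (constant a, b) are therefore advanced exactly up to
    roundoff.  ``precision`` selects the dtype of all state arithmetic
    ("double" -> float64, "single" -> float32).
    """

    def __init__(self, equation_set: EquationSet, dt: float, precision: str = "double"):
        if dt <= 0:
            raise ValueError("dt must be positive")
        if precision not in ("single", "double"):
            raise ValueError("precision must be 'single' or 'double'")
        self.equation_set = equation_set
        self.dt = float(dt)
        self.precision = precision
        self.dtype = np.float32 if precision == "single" else np.float64

        args = [sp.Symbol(n) for n in equation_set.state_variables]
        args += [sp.Symbol(n) for n in equation_set.input_terms]
        subs = {sp.Symbol(k): sp.Float(v) for k, v in equation_set.parameters.items()}
        exprs = []
        for name in equation_set.state_variables:
            a, b = equation_set.linear_coefficients[name]
            exprs.append(a.xreplace(subs))
            exprs.append(b.xreplace(subs))
        self._coeff_fn = sp.lambdify(args, exprs, modules=[_NUMERIC_FUNCTIONS, "numpy"])

    @property
    def variables(self):
        return self.equation_set.state_variables

    def step(self, state: dict, inputs: dict | None = None) -> None:
        """Advance ``state`` (name -> array) one step of dt, in place.

        All coefficients are evaluated from step-start values, so the
        update has no within-step sequencing effects.
        """
        dtype = self.dtype
        names = self.equation_set.state_variables
        argvals = [state[n] for n in names]
        for term in self.equation_set.input_terms:
            argvals.append((inputs or {})[term])
        coeffs = self._coeff_fn(*argvals)
        dt = dtype(self.dt)
        for i, name in enumerate(names):
            a = np.asarray(coeffs[2 * i], dtype=dtype)
            b = np.asarray(coeffs[2 * i + 1], dtype=dtype)
            x = state[name]
            bdt = b * dt
            small = np.abs(bdt) < _B_ZERO_TOL
            b_safe = np.where(small, dtype(1.0), b)
            linear = x + a * dt
            exact = x + (x + a / b_safe) * np.expm1(bdt)
            state[name] = np.asarray(np.where(small, linear, exact), dtype=dtype)

    def advance(self, state: dict, n_steps: int, inputs: dict | None = None) -> dict:
        """Return a copy of ``state`` advanced by ``n_steps`` steps."""
        work = {k: np.array(v, dtype=self.dtype, ndmin=1) for k, v in state.items()}
        for _ in range(n_steps):
            self.step(work, inputs)
        return work


def build_exponential_euler_kernel(
    equation_set: EquationSet, dt: float, precision: str = "double"
) -> ExponentialEulerKernel:
    """Build a compiled exponential-Euler state updater."""
    return ExponentialEulerKernel(equation_set, dt, precision)
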