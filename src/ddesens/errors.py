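"""Exception hierarchy for ddesens.

Solver failures carry the last accepted time (and, when available, the partial
trajectory) so callers can diagnose where an integration broke down.
"""

from __future__ import annotations


class DDESensError(Exception):
    """Base class for all ddesens errors."""


class ExpressionSyntaxError(DDESensError):
    """Malformed expression text; ``position`` is a 0-based character offset."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class UndeclaredSymbolError(ExpressionSyntaxError):
    """An identifier does not resolve against the declared model symbols."""

    def __init__(self, name: str, position: int | None = None):
        self.name = name
        super().__init__(f"undeclared symbol '{name}'", position)


class EvaluationDomainError(DDESensError):
    """Evaluation left the real domain (log of non-positive, 0^negative,
    division by zero, negative base with fractional exponent, ...)."""


class ModelParseError(DDESensError):
    """Model file does not follow the sectioned format; carries a line number."""

    def __init__(self, message: str, line: int | None = None, section: str | None = None):
        self.line = line
        self.section = section
        where = []
        if section:
            where.append(f"section [{section}]")
        if line is not None:
            where.append(f"line {line}")
        if where:
            message = f"{message} ({', '.join(where)})"
        super().__init__(message)


class SolverError(DDESensError):
    """Base for runtime integration failures."""

    def __init__(self, message: str, time: float | None = None):
        self.time = time
        self.trajectory = None  # filled in by the driver loop when available
        if time is not None:
            message = f"{message} (last accepted time t={time:.6g})"
        super().__init__(message)


class StiffnessError(SolverError):
    """The Jacobian-norm bound mu satisfied mu * epsilon >= 1: the system is
    declared stiff and the explicit fixed-point scheme is abandoned."""

    def __init__(self, mu: float, epsilon: float, time: float | None = None):
        self.mu = mu
        self.epsilon = epsilon
        super().__init__(
            f"stiff system: mu={mu:.6g} with tolerance epsilon={epsilon:.6g} "
            f"gives mu*epsilon={mu * epsilon:.6g} >= 1", time,
        )


class ConvergenceError(SolverError):
    """Fixed-point corrector failed to converge within the iteration limit."""


class HistoryExtrapolationError(SolverError):
    """A history lookup was requested beyond the latest accepted node
    (signals a step-size bug, never expected during a healthy run)."""


class FixtureUnavailableError(DDESensError):
    """A model fixture whose source material is not bundled was requested."""
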