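"""Exception hierarchy shared across the package."""

from __future__ import annotations

from typing import Any


class ScsolError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ScsolError, ValueError):
    """An input violates a physical or mathematical precondition."""


class InputError(ScsolError, ValueError):
    """Malformed user-supplied data (bad CSV cell, missing column, ...)."""


class NumericalError(ScsolError, RuntimeError):
    """A numerical procedure failed (no fluid root, divergent iteration).

    Carries a ``payload`` dict with diagnostic state (the offending
    (T, P), parameters, last iterate, ...) so callers can report or
    penalize the failure instead of crashing an outer optimization.
    """

    def __init__(self, message: str, payload: dict[str, Any] | None = None):
        super().__init__(message)
        self.payload = payload or {}
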