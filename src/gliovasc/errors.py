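"""Exception types for configuration and integration failures."""

from __future__ import annotations

import numpy as np


class ConfigError(ValueError):
    """A scenario configuration violates its schema."""


class IntegrationError(RuntimeError):
    """The right-hand side produced a non-finite component."""

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class SolverError(RuntimeError):
    """The adaptive solver failed; carries the last good state and time."""

    def __init__(self, message: str, t_last: float,
                 state_last: np.ndarray):
        super().__init__(message)
        self.t_last = t_last
        self.state_last = state_last
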