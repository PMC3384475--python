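"""Shared helpers: errors, half-up rounding, seed derivation."""

from __future__ import annotations

import math

import numpy as np


class FormatError(ValueError):
    """A file does not conform to one of the on-disk formats."""


class EstimationError(ValueError):
    """A model fit was attempted on degenerate input."""


class ConfigError(ValueError):
    """A generator or pipeline configuration is inconsistent."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as report tables are formatted.

    Python's built-in round() is banker's rounding; occupancy and size
    reports need 99.05 -> 99.1, not 99.0.
    """
    if not math.isfinite(x):
        return x
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Independent generator derived from a base seed and an integer key path."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))
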