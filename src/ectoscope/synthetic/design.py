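"""Experimental-design and trait generation.

The emitted design is long format: one row per fish x acute test
temperature, with every fish appearing exactly twice (test temperature is
the repeated factor) and ``n_per_group`` fish per between-subject cell
(day length x thyroid x acclimation temperature). Trait values are additive
on the measurement scale:

    y = baseline + main-effect shifts + interaction shifts
        + fish intercept ~ N(0, within_fish_sd)  (shared across the two
          test-temperature rows of a fish)
        + residual ~ N(0, noise_sd)

which is exactly the structure the downstream factorial permutation
analysis assumes. With both SDs at zero the generated value is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from ..errors import InvalidSpecificationError
from ..factors import BETWEEN_FACTORS, LEVELS, WITHIN_FACTOR, code_level

#: Default fish per between-subject cell; the study's group sizes span
#: 13-21, so 16 is a representative middle value.
DEFAULT_N_PER_GROUP = 16


@dataclass(frozen=True)
class DesignSpec:
    n_per_group: int = DEFAULT_N_PER_GROUP
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise InvalidSpecificationError(
                f"n_per_group must be >= 1, got {self.n_per_group}"
            )


@dataclass
class EffectModel:
    """Additive ground-truth model for one trait.

    ``main_effects`` maps factor -> {level: shift}; ``interactions`` maps a
    tuple of (factor, level) pairs -> shift applied to rows matching all of
    them. Shifts attached to specific levels are convenient for scenario
    building; :func:`coded_interaction` builds the balanced +/- pattern of a
    pure sum-to-zero interaction coefficient.
    """

    baseline: float
    main_effects: dict[str, dict] = field(default_factory=dict)
    interactions: dict[tuple, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    within_fish_sd: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0 or self.within_fish_sd < 0:
            raise InvalidSpecificationError("standard deviations must be >= 0")
        for factor, shifts in self.main_effects.items():
            for level in shifts:
                if level not in LEVELS[factor]:
                    raise InvalidSpecificationError(
                        f"unknown level {level!r} for factor {factor!r}"
                    )
        for combo in self.interactions:
            for factor, level in combo:
                if level not in LEVELS[factor]:
                    raise InvalidSpecificationError(
                        f"unknown level {level!r} for factor {factor!r}"
                    )

    def mean_for(self, row: pd.Series | dict) -> float:
        """Expected trait value for one design row (no noise)."""
        y = self.baseline
        for factor, shifts in self.main_effects.items():
            y += shifts.get(row[factor], 0.0)
        for combo, shift in self.interactions.items():
            if all(row[factor] == level for factor, level in combo):
                y += shift
        return y


def coded_interaction(factors: tuple[str, ...], coefficient: float) -> dict[tuple, float]:
    """Level-shift table for a pure sum-to-zero interaction coefficient.

    Adds ``coefficient * prod(codes)`` to every cell, so the term's coded
    coefficient is exactly ``coefficient`` and all other terms (including
    the grand mean) are untouched. The difference between the +1-product
    and −1-product halves of the design is ``2 * coefficient``.
    """
    table: dict[tuple, float] = {}
    for levels in product(*(LEVELS[f] for f in factors)):
        combo = tuple(zip(factors, levels))
        sign = np.prod([code_level(f, l) for f, l in combo])
        table[combo] = coefficient * float(sign)
    return table


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Long-format design table: one row per fish x test temperature.

    Columns: fish_id, day_length, thyroid, acclimation_temp, test_temp.
    Deterministic given the spec (cell enumeration is lexicographic; fish
    IDs are sequential within cells).
    """
    rows = []
    fish_no = 0
    for levels in product(*(LEVELS[f] for f in BETWEEN_FACTORS)):
        for _ in range(spec.n_per_group):
            fish_no += 1
            fid = f"F{fish_no:04d}"
            for tt in LEVELS[WITHIN_FACTOR]:
                row = dict(zip(BETWEEN_FACTORS, levels))
                row["fish_id"] = fid
                row[WITHIN_FACTOR] = tt
                rows.append(row)
    cols = ["fish_id", *BETWEEN_FACTORS, WITHIN_FACTOR]
    return pd.DataFrame(rows, columns=cols)


def simulate_traits(
    design: pd.DataFrame,
    model: EffectModel,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Trait values for every design row under ``model``.

    The fish-level intercept is drawn once per fish (in order of first
    appearance) and shared across that fish's rows; residuals are i.i.d.
    Deterministic given the seed and the design row order.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = design.apply(model.mean_for, axis=1).to_numpy(dtype=float)
    fish_ids = design["fish_id"].to_numpy()
    uniq, first_idx = np.unique(fish_ids, return_index=True)
    # intercepts drawn in first-appearance order so row order does not
    # change which fish gets which draw
    order = np.argsort(first_idx)
    intercepts = dict(
        zip(uniq[order], rng.normal(0.0, model.within_fish_sd, size=uniq.size))
    )
    y = means + np.array([intercepts[f] for f in fish_ids])
    y += rng.normal(0.0, model.noise_sd, size=y.size)
    return y
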