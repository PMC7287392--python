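"""The 2x2x2x2 experimental design shared by simulation and inference.

Four two-level factors: photoperiod (day length), thyroid status,
acclimation temperature (chronic, weeks) and acute test temperature
(at measurement time). Test temperature is the repeated, within-fish
factor — every fish is measured at both 18 and 28 degC — while the other
three are between-fish. Sum-to-zero (+1/−1) codes use the level listed in
``POSITIVE_LEVEL`` as +1; thyroid codes normothyroid as +1 so that a
positive coefficient or effect size means a positive effect of thyroid
hormone.
"""

from __future__ import annotations

BETWEEN_FACTORS = ("day_length", "thyroid", "acclimation_temp")
WITHIN_FACTOR = "test_temp"
FACTORS = BETWEEN_FACTORS + (WITHIN_FACTOR,)

LEVELS: dict[str, tuple] = {
    "day_length": ("short", "long"),
    "thyroid": ("hypo", "normo"),
    "acclimation_temp": (18, 28),
    "test_temp": (18, 28),
}

POSITIVE_LEVEL: dict[str, object] = {
    "day_length": "long",
    "thyroid": "normo",
    "acclimation_temp": 28,
    "test_temp": 28,
}


def code_level(factor: str, level) -> float:
    """+1/−1 sum-to-zero code for a factor level."""
    if level not in LEVELS[factor]:
        raise KeyError(f"unknown level {level!r} for factor {factor!r}")
    return 1.0 if level == POSITIVE_LEVEL[factor] else -1.0


def term_name(factors: tuple[str, ...]) -> str:
    """Canonical 'a:b:c' name with factors in the global FACTORS order."""
    ordered = tuple(f for f in FACTORS if f in factors)
    if len(ordered) != len(factors):
        unknown = set(factors) - set(FACTORS)
        raise KeyError(f"unknown factors {unknown}")
    return ":".join(ordered)


def model_terms() -> list[tuple[str, ...]]:
    """The 14 tested terms: all mains, two-way and three-way interactions
    (the four-way is excluded)."""
    from itertools import combinations

    terms: list[tuple[str, ...]] = []
    for k in (1, 2, 3):
        terms.extend(combinations(FACTORS, k))
    return terms
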