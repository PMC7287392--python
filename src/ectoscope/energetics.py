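"""Whole-animal energetics: metabolic scope and ATP production scope.

Metabolic (oxygen consumption) scope is MO2max − MO2rest, the classical
proxy for aerobic energy available for activity. Because the ATP yield per
oxygen varies with mitochondrial efficiency, the scope of each fish is
calibrated by its own P:O ratio measured at the same acute test
temperature:

    ATP scope = MO2 scope * P:O * atom_factor

P:O is ATP per oxygen *atom* while MO2 is in O2 molecules, so the default
``atom_factor`` of 2 converts molecules to atoms; the unconverted product
(atom_factor=1) is also supported, and all group comparisons are invariant
to this constant. Groups can rank oppositely on MO2 scope and ATP scope
whenever P:O differences run against scope differences — oxygen consumption
alone does not predict ATP production.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidInputError, MissingPairError
from .respirometry import Mo2Measurement

#: O2 molecules -> oxygen atoms; multiply MO2 scope (per O2) by P:O (per O atom).
DEFAULT_ATOM_FACTOR = 2.0


@dataclass
class EnergeticsRecord:
    """Per-fish, per-test-temperature energetics summary."""

    fish_id: str
    test_temp_c: float
    mo2_rest: float
    mo2_max: float
    mo2_scope: float
    po_ratio: float = float("nan")
    atp_scope: float = float("nan")
    qc_flags: list[str] = field(default_factory=list)


def compute_scope(rest: Mo2Measurement, max_: Mo2Measurement) -> EnergeticsRecord:
    """MO2max − MO2rest for one fish at one acute test temperature.

    A non-positive scope is returned with a QC flag, never clipped: it is a
    real (if suspicious) observation that the permutation analysis can see.
    """
    if rest.fish_id != max_.fish_id or rest.test_temp_c != max_.test_temp_c:
        raise MissingPairError(
            f"cannot pair rest ({rest.fish_id}, {rest.test_temp_c}degC) with "
            f"max ({max_.fish_id}, {max_.test_temp_c}degC)"
        )
    if rest.phase != "rest" or max_.phase != "max":
        raise InvalidInputError("arguments must be a (rest, max) measurement pair")
    scope = max_.mo2_umol_g_min - rest.mo2_umol_g_min
    flags = []
    if scope <= 0:
        flags.append("non_positive_scope")
    return EnergeticsRecord(
        fish_id=rest.fish_id,
        test_temp_c=rest.test_temp_c,
        mo2_rest=rest.mo2_umol_g_min,
        mo2_max=max_.mo2_umol_g_min,
        mo2_scope=scope,
        qc_flags=flags,
    )


def compute_atp_scope(
    record: EnergeticsRecord,
    po_ratio: float | None = None,
    atom_factor: float = DEFAULT_ATOM_FACTOR,
) -> EnergeticsRecord:
    """Fill in ``atp_scope = mo2_scope * po_ratio * atom_factor``.

    The P:O ratio must come from the same individual at the same acute test
    temperature; passing it explicitly overrides ``record.po_ratio``.
    """
    po = record.po_ratio if po_ratio is None else po_ratio
    if po is None or pd.isna(po):
        raise MissingPairError(
            f"no P:O ratio for fish {record.fish_id} at {record.test_temp_c}degC"
        )
    record.po_ratio = float(po)
    record.atp_scope = record.mo2_scope * record.po_ratio * atom_factor
    return record


def build_energetics_table(
    mo2: pd.DataFrame,
    mito: pd.DataFrame,
    atom_factor: float = DEFAULT_ATOM_FACTOR,
) -> pd.DataFrame:
    """Join MO2 and mitochondrial tables into one row per fish x test temp.

    ``mo2`` needs columns fish_id, test_temp_c, phase, mo2_umol_g_min (long
    format, rest and max rows); ``mito`` needs fish_id, test_temp_c,
    po_ratio. Any fish x temperature combination missing its rest/max pair
    or its P:O raises :class:`MissingPairError` naming the offender — no
    imputation.
    """
    wide = mo2.pivot_table(
        index=["fish_id", "test_temp_c"],
        columns="phase",
        values="mo2_umol_g_min",
        aggfunc="first",
    )
    for ph in ("rest", "max"):
        if ph not in wide.columns or wide[ph].isna().any():
            missing = (
                wide.index.tolist()
                if ph not in wide.columns
                else wide.index[wide[ph].isna()].tolist()
            )
            raise MissingPairError(f"missing {ph!r} MO2 measurement for {missing[:5]}")
    wide = wide.rename(columns={"rest": "mo2_rest", "max": "mo2_max"}).reset_index()
    wide["mo2_scope"] = wide["mo2_max"] - wide["mo2_rest"]

    merged = wide.merge(
        mito[["fish_id", "test_temp_c", "po_ratio"]],
        on=["fish_id", "test_temp_c"],
        how="left",
    )
    if merged["po_ratio"].isna().any():
        bad = merged.loc[
            merged["po_ratio"].isna(), ["fish_id", "test_temp_c"]
        ].to_records(index=False)
        raise MissingPairError(f"no P:O ratio for {list(bad)[:5]}")
    merged["atp_scope"] = merged["mo2_scope"] * merged["po_ratio"] * atom_factor
    return merged
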