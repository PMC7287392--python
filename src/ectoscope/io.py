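"""CSV / NPZ readers and writers for the pipeline's exchange formats.

All tabular exchange is plain CSV. Trace files carry only (time, O2)
columns; per-trace metadata (chamber volume, fish mass, protein, ADP)
lives in sidecar meta CSVs keyed by fish/sample ID so that a directory of
traces plus one meta table fully reconstructs the input objects. Climate
stacks travel as NumPy ``.npz`` archives with keys tmin_monthly,
tmax_monthly and warming.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .climate import ClimateStack
from .errors import InvalidInputError
from .mito import MitoTrace
from .respirometry import RespirometryTrace
from .swim import SwimProtocol, SwimTrialRecord

TRIAL_COLUMNS = [
    "fish_id",
    "test_temp_c",
    "last_completed_speed_ms",
    "time_at_final_speed_min",
    "standard_length_m",
]


def write_design_csv(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, index=False)


def read_design_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# --- respirometry -----------------------------------------------------------


def trace_filename(fish_id: str, phase: str, test_temp_c: float) -> str:
    return f"{fish_id}_{phase}_{test_temp_c:g}C.csv"


def write_respirometry_trace(trace: RespirometryTrace, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / trace_filename(trace.fish_id, trace.phase, trace.test_temp_c)
    pd.DataFrame(
        {"time_min": trace.time_min, "o2_umol_per_l": trace.o2_umol_per_l}
    ).to_csv(path, index=False)
    return path


def respirometry_meta_row(trace: RespirometryTrace) -> dict:
    return {
        "fish_id": trace.fish_id,
        "phase": trace.phase,
        "test_temp_c": trace.test_temp_c,
        "chamber_volume_l": trace.chamber_volume_l,
        "fish_mass_g": trace.fish_mass_g,
        "trace_file": trace_filename(trace.fish_id, trace.phase, trace.test_temp_c),
    }


def read_respirometry_traces(
    directory: str | Path, meta: pd.DataFrame
) -> list[RespirometryTrace]:
    """Load every trace listed in the meta table from ``directory``."""
    directory = Path(directory)
    traces = []
    for row in meta.itertuples(index=False):
        df = pd.read_csv(directory / row.trace_file)
        traces.append(
            RespirometryTrace(
                time_min=df["time_min"].to_numpy(),
                o2_umol_per_l=df["o2_umol_per_l"].to_numpy(),
                chamber_volume_l=row.chamber_volume_l,
                fish_mass_g=row.fish_mass_g,
                test_temp_c=row.test_temp_c,
                phase=row.phase,
                fish_id=row.fish_id,
            )
        )
    return traces


# --- swim trials ------------------------------------------------------------


def write_trials_csv(records: list[SwimTrialRecord], path: str | Path) -> None:
    rows = [
        {
            "fish_id": r.fish_id,
            "test_temp_c": r.test_temp_c,
            "last_completed_speed_ms": r.last_completed_speed_ms,
            "time_at_final_speed_min": r.time_at_final_speed_min,
            "standard_length_m": r.standard_length_m,
            "initial_speed_ms": r.protocol.initial_speed_ms,
            "initial_duration_min": r.protocol.initial_duration_min,
            "increment_ms": r.protocol.increment_ms,
            "interval_min": r.protocol.interval_min,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trials_csv(path: str | Path) -> list[SwimTrialRecord]:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"trials CSV missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        proto = SwimProtocol(
            initial_speed_ms=getattr(row, "initial_speed_ms", 0.06),
            initial_duration_min=getattr(row, "initial_duration_min", 20.0),
            increment_ms=getattr(row, "increment_ms", 0.02),
            interval_min=getattr(row, "interval_min", 5.0),
        )
        records.append(
            SwimTrialRecord(
                fish_id=row.fish_id,
                test_temp_c=row.test_temp_c,
                last_completed_speed_ms=row.last_completed_speed_ms,
                time_at_final_speed_min=row.time_at_final_speed_min,
                standard_length_m=row.standard_length_m,
                protocol=proto,
            )
        )
    return records


# --- mitochondrial traces ---------------------------------------------------


def mito_filenames(sample_id: str, test_temp_c: float) -> tuple[str, str]:
    stem = f"{sample_id}_{test_temp_c:g}C"
    return f"{stem}_trace.csv", f"{stem}_events.csv"


def write_mito_trace(trace: MitoTrace, directory: str | Path) -> tuple[Path, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    trace_name, events_name = mito_filenames(trace.sample_id, trace.test_temp_c)
    pd.DataFrame(
        {"time_min": trace.time_min, "o2_nmol_per_ml": trace.o2_nmol_per_ml}
    ).to_csv(directory / trace_name, index=False)
    pd.DataFrame(
        [{"event": e, "time_min": t} for e, t in sorted(trace.events.items(), key=lambda kv: kv[1])]
    ).to_csv(directory / events_name, index=False)
    return directory / trace_name, directory / events_name


def mito_meta_row(trace: MitoTrace) -> dict:
    trace_name, events_name = mito_filenames(trace.sample_id, trace.test_temp_c)
    return {
        "sample_id": trace.sample_id,
        "test_temp_c": trace.test_temp_c,
        "chamber_volume_ml": trace.chamber_volume_ml,
        "protein_mg_per_ml": trace.protein_mg_per_ml,
        "adp_mM": trace.adp_mM,
        "trace_file": trace_name,
        "events_file": events_name,
    }


def read_mito_traces(directory: str | Path, meta: pd.DataFrame) -> list[MitoTrace]:
    directory = Path(directory)
    traces = []
    for row in meta.itertuples(index=False):
        df = pd.read_csv(directory / row.trace_file)
        ev = pd.read_csv(directory / row.events_file)
        traces.append(
            MitoTrace(
                time_min=df["time_min"].to_numpy(),
                o2_nmol_per_ml=df["o2_nmol_per_ml"].to_numpy(),
                events=dict(zip(ev["event"], ev["time_min"])),
                chamber_volume_ml=row.chamber_volume_ml,
                protein_mg_per_ml=row.protein_mg_per_ml,
                adp_mM=row.adp_mM,
                sample_id=row.sample_id,
                test_temp_c=row.test_temp_c,
            )
        )
    return traces


# --- climate ----------------------------------------------------------------


def write_climate_stack(stack: ClimateStack, path: str | Path) -> None:
    np.savez_compressed(
        path,
        tmin_monthly=stack.tmin_monthly,
        tmax_monthly=stack.tmax_monthly,
        warming=stack.warming,
    )


def read_climate_stack(path: str | Path) -> ClimateStack:
    with np.load(path) as z:
        return ClimateStack(
            tmin_monthly=z["tmin_monthly"],
            tmax_monthly=z["tmax_monthly"],
            warming=z["warming"],
        )


def index_to_csv(index: np.ndarray, path: str | Path) -> None:
    """Flatten an index grid to (row, col, index) CSV, valid cells only."""
    rows, cols = np.nonzero(np.isfinite(index))
    pd.DataFrame(
        {"row": rows, "col": cols, "index": index[rows, cols]}
    ).to_csv(path, index=False)
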