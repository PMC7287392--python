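"""End-to-end pipeline orchestration with reproducible seeding.

A run either consumes file inputs written by the individual subcommands or
generates a fully synthetic study from a ground-truth scenario. Every
stage draws its randomness from a named substream of one master seed, so
stage outputs are reproducible independently of execution order, and a
run's YAML config plus code version reproduces the whole bundle.

The default synthetic scenario mirrors the study's headline structure:
acute warming raises all whole-animal rates; cold acclimation raises
oxygen-consumption scope while *lowering* mitochondrial efficiency (P:O),
so ATP production scope ranks the acclimation groups opposite to MO2
scope; a three-way acclimation x day-length x thyroid interaction drives
swimming performance.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .energetics import build_energetics_table
from .errors import PipelineError
from .mito import analyze_mito_trace
from .permstats import (
    ModelSpec,
    mismatch_effect_size,
    permutation_test,
)
from .respirometry import compute_mo2
from .swim import compute_ucrit
from .synthetic import (
    DesignSpec,
    EffectModel,
    generate_design,
    simulate_climate_rasters,
    simulate_mito_trace,
    simulate_respirometry_trace,
    simulate_swim_trial,
    simulate_traits,
)
from .climate import mismatch_index

def _merge(*tables: dict) -> dict:
    out: dict = {}
    for t in tables:
        for k, v in t.items():
            out[k] = out.get(k, 0.0) + v
    return out


from .synthetic.design import coded_interaction  # noqa: E402

#: Ground-truth scenario used when no scenario is supplied. Trait units:
#: ucrit_ms in m s⁻¹, MO2 in μmol O2 g⁻¹ min⁻¹, P:O in ATP per O atom.
DEFAULT_SCENARIO: dict = {
    "ucrit_ms": {
        "baseline": 0.11,
        "main_effects": {"test_temp": {28: 0.008}},
        "interactions": _merge(
            # cold-acclimated fish swim better at the cold test temperature
            coded_interaction(("acclimation_temp", "test_temp"), 0.004),
            # short days enhance cold acclimation of swimming
            coded_interaction(("day_length", "acclimation_temp"), 0.004),
            # at the cold test temperature fish swim better on short days
            coded_interaction(("day_length", "test_temp"), 0.004),
            # thyroid hormone helps cold acclimation on short days and
            # hinders it on long days
            coded_interaction(
                ("day_length", "thyroid", "acclimation_temp"), 0.006
            ),
        ),
        "noise_sd": 0.010,
        "within_fish_sd": 0.008,
    },
    "state3": {
        # nmol O2 min⁻¹ mg⁻¹; State 3 peaks when acclimation mismatches
        # photoperiod (warm/short and cold/long), and its thermal
        # sensitivity is larger on long days
        "baseline": 50.0,
        "main_effects": {"day_length": {"long": 2.0}},
        "interactions": _merge(
            coded_interaction(("day_length", "acclimation_temp"), -3.0),
            coded_interaction(("day_length", "test_temp"), 3.0),
        ),
        "noise_sd": 5.0,
        "within_fish_sd": 3.0,
    },
    "mo2_rest": {
        "baseline": 0.10,
        "main_effects": {
            "test_temp": {28: 0.04},
            "acclimation_temp": {18: 0.012},
        },
        "noise_sd": 0.012,
        "within_fish_sd": 0.008,
    },
    "mo2_scope": {
        "baseline": 0.25,
        "main_effects": {
            "test_temp": {28: 0.08},
            "acclimation_temp": {18: 0.04},
        },
        "noise_sd": 0.035,
        "within_fish_sd": 0.02,
    },
    "po_ratio": {
        "baseline": 1.30,
        "main_effects": {"acclimation_temp": {28: 0.35}},
        # weak modulation of thermal sensitivity by day length and thyroid
        "interactions": coded_interaction(
            ("day_length", "thyroid", "test_temp"), 0.03
        ),
        "noise_sd": 0.12,
        "within_fish_sd": 0.08,
    },
}

RESPONSES = [
    "ucrit_bl_s",
    "mo2_rest",
    "mo2_max",
    "mo2_scope",
    "state3",
    "state4",
    "po_ratio",
    "atp_scope",
]


@dataclass
class RunConfig:
    """Fully serialisable configuration of one pipeline run."""

    n_per_group: int = 16
    seed: int = 0
    scenario: dict = field(default_factory=lambda: DEFAULT_SCENARIO)
    fish_mass_g: float = 0.5
    body_length_m: float = 0.025
    respirometry_noise_sd: float = 1.0  # μmol O2 / L
    mito_noise_sd: float = 1.0  # nmol O2 / ml
    swim_jitter_sd_min: float = 0.1
    n_permutations: int = 999
    n_boot: int = 2000
    atom_factor: float = 2.0
    responses: list = field(default_factory=lambda: list(RESPONSES))
    climate_shape: tuple = (36, 72)
    seasonality_definition: str = "annual_range"
    outdir: str = "ectoscope_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "scenario" in raw:
            raw["scenario"] = _parse_scenario(raw["scenario"])
        if "climate_shape" in raw:
            raw["climate_shape"] = tuple(raw["climate_shape"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dict(self.__dict__)
        data["scenario"] = _serialise_scenario(self.scenario)
        data["climate_shape"] = list(self.climate_shape)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _parse_scenario(raw: dict) -> dict:
    """YAML-friendly scenario: interaction keys as 'factor=level,factor=level'."""
    out = {}
    for trait, cfg in raw.items():
        cfg = dict(cfg)
        inter = {}
        for key, shift in (cfg.get("interactions") or {}).items():
            if isinstance(key, str):
                combo = tuple(
                    (f, _maybe_int(l))
                    for f, l in (pair.split("=") for pair in key.split(","))
                )
            else:
                combo = tuple((f, _maybe_int(l)) for f, l in key)
            inter[combo] = shift
        if inter:
            cfg["interactions"] = inter
        else:
            cfg.pop("interactions", None)
        main = {}
        for f, shifts in (cfg.get("main_effects") or {}).items():
            main[f] = {_maybe_int(l): s for l, s in shifts.items()}
        if main:
            cfg["main_effects"] = main
        else:
            cfg.pop("main_effects", None)
        out[trait] = cfg
    return out


def _serialise_scenario(scenario: dict) -> dict:
    out = {}
    for trait, cfg in scenario.items():
        cfg = dict(cfg)
        if cfg.get("interactions"):
            cfg["interactions"] = {
                ",".join(f"{f}={l}" for f, l in combo): shift
                for combo, shift in cfg["interactions"].items()
            }
        else:
            cfg.pop("interactions", None)
        out[trait] = cfg
    return out


def _maybe_int(v):
    try:
        return int(v)
    except (TypeError, ValueError):
        return v


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Named substream: stable across runs and stage execution order."""
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])
    )


def stage_seed(master_seed: int, stage: str) -> int:
    """31-bit integer seed derived from the named substream."""
    ss = np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_study(config: RunConfig) -> dict:
    """Generate design, true traits and all raw measurement objects."""
    design = generate_design(DesignSpec(n_per_group=config.n_per_group))
    truths = {}
    for trait, cfg in config.scenario.items():
        model = EffectModel(**cfg)
        truths[trait] = simulate_traits(
            design, model, stage_rng(config.seed, f"traits:{trait}")
        )
    truth = design.copy()
    for trait, vals in truths.items():
        truth[f"true_{trait}"] = vals
    truth["true_mo2_max"] = truth["true_mo2_rest"] + truth["true_mo2_scope"]

    resp_rng = stage_rng(config.seed, "respirometry")
    swim_rng = stage_rng(config.seed, "swim")
    mito_rng = stage_rng(config.seed, "mito")
    resp_traces, swim_records, mito_traces = [], [], []
    for row in truth.itertuples(index=False):
        common = dict(fish_id=row.fish_id, test_temp_c=float(row.test_temp))
        resp_traces.append(
            simulate_respirometry_trace(
                true_mo2=row.true_mo2_rest,
                mass_g=config.fish_mass_g,
                volume_l=0.027,
                duration_min=30.0,
                noise_sd=config.respirometry_noise_sd,
                seed=resp_rng,
                phase="rest",
                **common,
            )
        )
        resp_traces.append(
            simulate_respirometry_trace(
                true_mo2=row.true_mo2_max,
                mass_g=config.fish_mass_g,
                volume_l=0.130,
                duration_min=10.0,
                noise_sd=config.respirometry_noise_sd,
                seed=resp_rng,
                phase="max",
                **common,
            )
        )
        swim_records.append(
            simulate_swim_trial(
                true_ucrit_ms=row.true_ucrit_ms,
                body_length_m=config.body_length_m,
                jitter_sd_min=config.swim_jitter_sd_min,
                seed=swim_rng,
                allow_initial_failure=True,
                **common,
            )
        )
        # State 3 varies per fish; State 2/4 stay at the leak baseline and
        # the uncoupled rate tracks electron-transport capacity
        s3 = float(max(getattr(row, "true_state3", 50.0), 15.0))
        mito_traces.append(
            simulate_mito_trace(
                state_rates={
                    "state2": 10.0,
                    "state3": s3,
                    "state4": 10.0,
                    "fccp": 1.2 * s3,
                },
                target_po=row.true_po_ratio,
                noise_sd=config.mito_noise_sd,
                seed=mito_rng,
                sample_id=row.fish_id,
                test_temp_c=float(row.test_temp),
            )
        )
    return {
        "design": design,
        "truth": truth,
        "respirometry": resp_traces,
        "swim": swim_records,
        "mito": mito_traces,
    }


def analyze_study(study: dict, config: RunConfig) -> dict:
    """Run every analysis stage on raw measurement objects."""
    mo2_rows = []
    for trace in study["respirometry"]:
        try:
            m = compute_mo2(trace)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise PipelineError("mo2", f"{trace.fish_id}/{trace.phase}", str(exc))
        mo2_rows.append(
            {
                "fish_id": m.fish_id,
                "test_temp_c": m.test_temp_c,
                "phase": m.phase,
                "mo2_umol_g_min": m.mo2_umol_g_min,
                "fit_r2": m.fit_r2,
                "qc_flags": ";".join(m.qc_flags),
            }
        )
    mo2 = pd.DataFrame(mo2_rows)

    ucrit_rows = []
    for rec in study["swim"]:
        u = compute_ucrit(rec)
        ucrit_rows.append(
            {
                "fish_id": u.fish_id,
                "test_temp_c": u.test_temp_c,
                "ucrit_ms": u.ucrit_ms,
                "ucrit_bl_s": u.ucrit_bl_s,
                "qc_flags": ";".join(u.qc_flags),
            }
        )
    ucrit = pd.DataFrame(ucrit_rows)

    mito_rows = []
    for trace in study["mito"]:
        try:
            r = analyze_mito_trace(trace)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("mito", trace.sample_id, str(exc))
        mito_rows.append(
            {
                "fish_id": r.sample_id,
                "test_temp_c": r.test_temp_c,
                "state2": r.state2,
                "state3": r.state3,
                "state4": r.state4,
                "fccp": r.fccp,
                "state4_onset_min": r.state4_onset_min,
                "po_ratio": r.po_ratio,
                "rcr": r.rcr,
                "qc_flags": ";".join(r.qc_flags),
            }
        )
    mito = pd.DataFrame(mito_rows)

    energetics = build_energetics_table(mo2, mito, atom_factor=config.atom_factor)
    responses = (
        study["design"]
        .merge(
            energetics.merge(
                mito[["fish_id", "test_temp_c", "state3", "state4", "rcr"]],
                on=["fish_id", "test_temp_c"],
            ),
            left_on=["fish_id", "test_temp"],
            right_on=["fish_id", "test_temp_c"],
        )
        .merge(
            ucrit[["fish_id", "test_temp_c", "ucrit_ms", "ucrit_bl_s"]],
            on=["fish_id", "test_temp_c"],
        )
        .drop(columns=["test_temp_c"])
    )
    return {
        "mo2": mo2,
        "ucrit": ucrit,
        "mito": mito,
        "energetics": energetics,
        "responses": responses,
    }


def run_statistics(responses: pd.DataFrame, config: RunConfig) -> dict:
    """Permutation ANOVA per response plus warming-mismatch effect sizes."""
    anova = {}
    for resp in config.responses:
        spec = ModelSpec(
            response=resp,
            n_permutations=config.n_permutations,
            seed=stage_seed(config.seed, f"anova:{resp}"),
        )
        res = permutation_test(responses, spec)
        anova[resp] = {
            row["term"]: row["p_perm"] for _, row in res.table.iterrows()
        }
    effect_sizes = {}
    for resp in ("ucrit_bl_s", "po_ratio", "atp_scope"):
        es = mismatch_effect_size(
            responses,
            resp,
            n_boot=config.n_boot,
            seed=stage_seed(config.seed, f"mismatch:{resp}"),
        )
        effect_sizes[resp] = {
            "cohens_d": es.cohens_d,
            "ci_low": es.ci_low,
            "ci_high": es.ci_high,
            "n_a": es.n_a,
            "n_b": es.n_b,
        }
    return {"anova_p": anova, "mismatch_effect_sizes": effect_sizes}


def run_pipeline(config: RunConfig) -> dict:
    """Execute a fully synthetic end-to-end run and write the bundle.

    Returns the in-memory results; the bundle directory contains the
    design, per-stage CSVs, statistics JSON, climate index CSV + NPZ, the
    resolved config and a timestamped log.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger = logging.getLogger("ectoscope.pipeline")
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("run started at %s", datetime.now(timezone.utc).isoformat())
        logger.info("master seed %d, n_per_group %d", config.seed, config.n_per_group)

        study = simulate_study(config)
        logger.info(
            "simulated %d fish (%d rows)",
            study["design"]["fish_id"].nunique(),
            len(study["design"]),
        )
        tables = analyze_study(study, config)
        n_flagged = int((tables["mo2"]["qc_flags"] != "").sum()) + int(
            (tables["mito"]["qc_flags"] != "").sum()
        )
        logger.info("analysis complete; %d QC-flagged measurements", n_flagged)
        stats_out = run_statistics(tables["responses"], config)
        logger.info("statistics complete (B=%d)", config.n_permutations)

        stack = simulate_climate_rasters(
            shape=config.climate_shape,
            seed=stage_rng(config.seed, "climate"),
        )
        grid = mismatch_index(stack, config.seasonality_definition)
        logger.info(
            "climate index over %d cells (definition=%s)",
            grid.provenance["n_valid_cells"],
            config.seasonality_definition,
        )

        eio.write_design_csv(study["design"], outdir / "design.csv")
        for name in ("mo2", "ucrit", "mito", "energetics", "responses"):
            tables[name].to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "stats.json", "w") as fh:
            json.dump(stats_out, fh, indent=2)
        eio.write_climate_stack(stack, outdir / "climate_stack.npz")
        np.savez_compressed(outdir / "climate_index.npz", index=grid.index)
        eio.index_to_csv(grid.index, outdir / "climate_index.csv")
        config.to_yaml(outdir / "config.yaml")
        logger.info("bundle written to %s", outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return {**tables, "stats": stats_out, "climate_index": grid}
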