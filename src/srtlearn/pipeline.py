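"""Orchestration and I/O: trial tables, per-stage analyses, report bundle.

The trial-table dialect is a long-format CSV/TSV with one row per cued
keypress (columns: subject, day, block_index, block_type, trial_index,
cue_key, pressed_key, rt_ms, correct, response_window_ms); missing RTs and
presses are empty fields, trial indices are 1-based within block.  All
analyses consume only the two daily probe blocks; training blocks are kept
in the tables for generator realism.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .chunking import AcfProfile, N_ACF_LAGS, acf31, build_null, chunk_size, preprocess_probe
from .error_response import N_ERF_LAGS, error_response_function
from .metrics import fit_learning_rate, rt_variability, sequence_specific_rt
from .state_space import LdsParams, build_inputs, em_fit
from .task_model import BlockType, SubjectConfig, TrialRecord, default_cohort, simulate_cohort

logger = logging.getLogger("srtlearn")

__all__ = [
    "COLUMNS",
    "RunConfig",
    "read_trials",
    "write_trials",
    "records_to_frame",
    "frame_to_records",
    "probe_series",
    "fit_probe_block",
    "run_pipeline",
]

COLUMNS = [
    "subject",
    "day",
    "block_index",
    "block_type",
    "trial_index",
    "cue_key",
    "pressed_key",
    "rt_ms",
    "correct",
    "response_window_ms",
]

_BLOCK_TYPES = {b.value for b in BlockType}
ALL_STAGES = ("metrics", "erf", "chunking", "lds", "binding_sim")


@dataclass
class RunConfig:
    """End-to-end run settings for :func:`run_pipeline`."""

    cohort: Union[Sequence[SubjectConfig], str, Path, None] = None
    stages: tuple[str, ...] = ("metrics", "erf", "chunking")
    alpha: float = 0.05
    out_dir: Union[str, Path] = "srtlearn_out"
    seed: int = 0
    n_subjects: int = 23
    lds_days: Optional[tuple[int, ...]] = None  # None = all days
    lds_max_iter: int = 100

    def __post_init__(self):
        if not self.stages:
            raise ValueError("stages must be nonempty")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = [
        {
            "subject": r.subject,
            "day": r.day,
            "block_index": r.block_index,
            "block_type": r.block_type.value,
            "trial_index": r.trial_index,
            "cue_key": r.cue_key,
            "pressed_key": r.pressed_key,
            "rt_ms": r.rt_ms,
            "correct": r.correct,
            "response_window_ms": r.response_window_ms,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    records = []
    for row in df.itertuples(index=False):
        records.append(
            TrialRecord(
                subject=str(row.subject),
                day=int(row.day),
                block_index=int(row.block_index),
                block_type=BlockType(row.block_type),
                trial_index=int(row.trial_index),
                cue_key=int(row.cue_key),
                pressed_key=None if pd.isna(row.pressed_key) else int(row.pressed_key),
                rt_ms=None if pd.isna(row.rt_ms) else float(row.rt_ms),
                correct=bool(row.correct),
                response_window_ms=float(row.response_window_ms),
            )
        )
    return records


def write_trials(records_or_frame, path: Union[str, Path]) -> None:
    """Write a trial table (CSV, or TSV for .tsv paths); empty field = missing."""
    df = (
        records_or_frame
        if isinstance(records_or_frame, pd.DataFrame)
        else records_to_frame(records_or_frame)
    )
    sep = "\t" if str(path).endswith(".tsv") else ","
    df.to_csv(path, sep=sep, index=False)


def _validate_trials(df: pd.DataFrame, path) -> pd.DataFrame:
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        if row.block_type not in _BLOCK_TYPES:
            raise ValueError(f"{path} row {i}: unknown block_type {row.block_type!r}")
        if not 1 <= int(row.cue_key) <= 8:
            raise ValueError(f"{path} row {i}: cue_key out of range")
        if not pd.isna(row.pressed_key) and not 1 <= int(row.pressed_key) <= 8:
            raise ValueError(f"{path} row {i}: pressed_key out of range")
        rt = None if pd.isna(row.rt_ms) else float(row.rt_ms)
        ok = (
            not pd.isna(row.pressed_key)
            and int(row.pressed_key) == int(row.cue_key)
            and rt is not None
            and rt <= float(row.response_window_ms)
        )
        if bool(row.correct) != ok:
            raise ValueError(f"{path} row {i}: correct flag inconsistent with press/RT/window")
    return df


def read_trials(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a trial table; raises with the offending row number."""
    sep = "\t" if str(path).endswith(".tsv") else ","
    # round_trip parsing keeps write->read lossless to the last ulp
    df = pd.read_csv(path, sep=sep, dtype={"subject": str}, float_precision="round_trip")
    df["correct"] = df["correct"].astype(bool)
    return _validate_trials(df, path)


def probe_series(df: pd.DataFrame, subject: str, day: int, block_type: BlockType) -> pd.DataFrame:
    sel = df[
        (df["subject"] == subject)
        & (df["day"] == day)
        & (df["block_type"] == block_type.value)
    ]
    return sel.sort_values("trial_index")


def fit_probe_block(
    block: pd.DataFrame, max_iter: int = 100, b_input: str = "binary"
) -> tuple[LdsParams, float, dict]:
    """EM-fit the preparedness LDS to one probe block.

    The block's RTs are centered before fitting (state mean and D trade
    off otherwise); the returned D adds the block mean back so biases stay
    in raw ms.  Returns (params, loglik, diagnostics).
    """
    rt = block["rt_ms"].to_numpy(dtype=float)
    block_mean = float(np.nanmean(rt))
    y = rt - block_mean
    inputs = build_inputs(
        block["cue_key"].to_numpy(),
        block["pressed_key"].to_numpy(dtype=float),
        (~block["correct"].to_numpy(dtype=bool)).astype(float),
        rts=rt,
        b_input=b_input,
    )
    result = em_fit(y, inputs, max_iter=max_iter)
    params = result.params
    from dataclasses import replace

    params = replace(params, d=params.d + block_mean)
    diag = {
        "n_iter": result.n_iter,
        "converged": result.converged,
        "loglik_path": result.loglik_path.tolist(),
        "block_mean_ms": block_mean,
        "b_input": b_input,
    }
    return params, float(result.loglik_path[-1]), diag


def _metrics_stage(df: pd.DataFrame, subjects, days) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    for s in subjects:
        for day in days:
            rand = probe_series(df, s, day, BlockType.RANDOM_PROBE)["rt_ms"].to_numpy(float)
            seq_block = probe_series(df, s, day, BlockType.SEQUENCE_PROBE)
            seq = seq_block["rt_ms"].to_numpy(float)
            rows.append(
                {
                    "subject": s,
                    "day": day,
                    "seq_rt_z": sequence_specific_rt(rand, seq),
                    "accuracy_pct": 100.0 * seq_block["correct"].mean(),
                    "rt_sd_seq": rt_variability(seq),
                    "rt_sd_rand": rt_variability(rand),
                }
            )
    per_day = pd.DataFrame(rows)
    lam_rows = []
    for s in subjects:
        sub = per_day[per_day["subject"] == s].sort_values("day")
        lr_rt = fit_learning_rate(sub["seq_rt_z"].to_numpy())
        lr_acc = fit_learning_rate(sub["accuracy_pct"].to_numpy())
        lam_rows.append(
            {
                "subject": s,
                "lambda_rt": lr_rt.lam,
                "model_rt": lr_rt.model,
                "lr_test_p_rt": lr_rt.lr_test_p,
                "lambda_acc": lr_acc.lam,
                "model_acc": lr_acc.model,
                "lr_test_p_acc": lr_acc.lr_test_p,
            }
        )
    return per_day, pd.DataFrame(lam_rows)


def _erf_stage(df: pd.DataFrame, subjects, days) -> pd.DataFrame:
    rows = []
    for s in subjects:
        for day in days:
            for bt in (BlockType.RANDOM_PROBE, BlockType.SEQUENCE_PROBE):
                block = probe_series(df, s, day, bt)
                rt = block["rt_ms"].to_numpy(float)
                is_err = ~block["correct"].to_numpy(bool)
                erf = error_response_function(
                    rt, is_err, float(np.nanmean(rt)), block_type=bt.value
                )
                if erf is None:
                    logger.warning("no errors for %s day %d %s; ERF absent", s, day, bt.value)
                    continue
                for lag in range(N_ERF_LAGS):
                    rows.append(
                        {
                            "subject": s,
                            "day": day,
                            "block_type": bt.value,
                            "lag": lag + 1,
                            "mean_ms": erf.lag_means_ms[lag],
                            "n_contributions": int(erf.n_contributions[lag]),
                        }
                    )
    return pd.DataFrame(rows)


def _chunking_stage(
    df: pd.DataFrame, subjects, days, alpha: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    acf_rows, chunk_rows = [], []
    for day in days:
        profiles: dict[str, dict[str, AcfProfile]] = {}
        for s in subjects:
            profiles[s] = {}
            for bt in (BlockType.RANDOM_PROBE, BlockType.SEQUENCE_PROBE):
                block = probe_series(df, s, day, bt)
                detr = preprocess_probe(block["rt_ms"].to_numpy(float))
                prof = acf31(detr, block_type=bt.value)
                profiles[s][bt.value] = prof
                for lag in range(N_ACF_LAGS):
                    acf_rows.append(
                        {
                            "subject": s,
                            "day": day,
                            "block_type": bt.value,
                            "lag": lag + 1,
                            "rho": prof.rho[lag],
                        }
                    )
        null = build_null([profiles[s][BlockType.RANDOM_PROBE.value] for s in subjects])
        for s in subjects:
            est = chunk_size(profiles[s][BlockType.SEQUENCE_PROBE.value], null, alpha=alpha)
            chunk_rows.append(
                {
                    "subject": s,
                    "day": day,
                    "chunk_size": est.size,
                    "alpha_corrected": est.alpha_corrected,
                }
            )
    return pd.DataFrame(acf_rows), pd.DataFrame(chunk_rows)


def _lds_stage(df: pd.DataFrame, subjects, days, max_iter: int) -> pd.DataFrame:
    rows = []
    for s in subjects:
        for day in days:
            block = probe_series(df, s, day, BlockType.SEQUENCE_PROBE)
            params, loglik, diag = fit_probe_block(block, max_iter=max_iter)
            row = {
                "subject": s,
                "day": day,
                "A": params.a,
                "F": params.f,
                "Q": params.q,
                "R": params.r,
                "loglik": loglik,
                "n_iter": diag["n_iter"],
                "converged": diag["converged"],
            }
            row.update({f"B{k + 1}": params.b[k] for k in range(8)})
            row.update({f"D{k + 1}": params.d[k] for k in range(8)})
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages end to end and write the report bundle.

    Returns the manifest dictionary; per-stage tables are written as CSV
    under ``config.out_dir`` together with ``manifest.json``.  Idempotent
    given the seed: the same config writes byte-identical tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.cohort is None:
        cohort = default_cohort(n_subjects=config.n_subjects, seed=config.seed)
    elif isinstance(config.cohort, (str, Path)):
        cohort = None
    else:
        cohort = list(config.cohort)

    if cohort is not None:
        df = records_to_frame(simulate_cohort(cohort))
        write_trials(df, out / "trials.csv")
    else:
        df = read_trials(config.cohort)

    subjects = sorted(df["subject"].unique())
    days = sorted(df["day"].unique())
    manifest = {
        "srtlearn_version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "stages": list(config.stages),
        "n_subjects": len(subjects),
        "days": [int(d) for d in days],
        "analysis_blocks": "probes_only",
        "acf_normalization": "biased_1_over_n",
        "chunk_test_reference": "t_df_nsubjects_minus_1",
        "lr_test_alpha_note": "per-subject, uncorrected across subjects",
        "outputs": {},
    }

    if "metrics" in config.stages:
        per_day, lambdas = _metrics_stage(df, subjects, days)
        per_day.to_csv(out / "metrics.csv", index=False)
        lambdas.to_csv(out / "learning_rates.csv", index=False)
        manifest["outputs"]["metrics"] = ["metrics.csv", "learning_rates.csv"]
        logger.info("metrics stage: %d subject-days", len(per_day))
    if "erf" in config.stages:
        erf = _erf_stage(df, subjects, days)
        erf.to_csv(out / "erf.csv", index=False)
        manifest["outputs"]["erf"] = ["erf.csv"]
        logger.info("erf stage: %d rows", len(erf))
    if "chunking" in config.stages:
        acf, chunks = _chunking_stage(df, subjects, days, config.alpha)
        acf.to_csv(out / "acf.csv", index=False)
        chunks.to_csv(out / "chunks.csv", index=False)
        manifest["outputs"]["chunking"] = ["acf.csv", "chunks.csv"]
        logger.info("chunking stage: %d chunk estimates", len(chunks))
    if "lds" in config.stages:
        lds_days = list(config.lds_days) if config.lds_days else days
        lds = _lds_stage(df, subjects, lds_days, config.lds_max_iter)
        lds.to_csv(out / "lds_params.csv", index=False)
        manifest["outputs"]["lds"] = ["lds_params.csv"]
        logger.info("lds stage: %d fits", len(lds))
    if "binding_sim" in config.stages:
        from .binding_sim import BindingConfig, mean_block_acf, simulate_binding

        rows = []
        for alpha in (0.0, 0.25, 0.5, 0.75):
            y = simulate_binding(BindingConfig(alpha=alpha, seed=config.seed))
            acf = mean_block_acf(y, n_lags=10)
            rows += [
                {"alpha": alpha, "lag": lag + 1, "rho": acf[lag]} for lag in range(10)
            ]
        pd.DataFrame(rows).to_csv(out / "binding_acf.csv", index=False)
        manifest["outputs"]["binding_sim"] = ["binding_acf.csv"]

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
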