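"""File I/O, run configuration and the end-to-end quantification pipeline.

Three plain-CSV dialects form the package boundary (image preprocessing and
ROI extraction happen upstream):

* **TAC CSV** — ``frame_start_s, frame_end_s`` followed by one activity
  column per region (kBq/ml); the header row carries the region names.
* **blood CSV** — ``time_min, whole_blood_kBq_ml, plasma_kBq_ml,
  parent_fraction, site``; ``parent_fraction`` may be empty per row.
* **input-function CSV** — ``time_min, whole_blood_kBq_ml,
  plasma_parent_kBq_ml`` (the parent column may be absent for a raw
  whole-blood IDIF).

:func:`run_quantification` chains blood-model fitting, optional IDIF
scaling, metabolite correction, truncation, the SIME joint fit and the
per-region fixed-V_ND refits, and writes a per-region parameter table plus
a machine-readable run record.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .blood import (
    BloodSample,
    InputFunction,
    fit_bpr,
    fit_parent_fraction,
    metabolite_correct,
    scale_idif,
)
from .exceptions import ParseError, SimepetError
from .frames import FrameSchedule, TimeActivityCurve
from .models import SIMEResults, TwoTissueResults, refit_fixed_vnd, sime_joint_fit, truncate_tac

__all__ = [
    "read_tacs",
    "write_tacs",
    "read_blood",
    "write_blood",
    "read_input",
    "write_input",
    "RunConfig",
    "QuantificationReport",
    "run_quantification",
]

logger = logging.getLogger("simepet")


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: not parseable as CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    return df


def read_tacs(path) -> list[TimeActivityCurve]:
    """Read regional TACs; one column per region after the frame bounds."""
    df = _read_csv(path, ["frame_start_s", "frame_end_s"])
    start = df["frame_start_s"].to_numpy(float)
    end = df["frame_end_s"].to_numpy(float)
    if (np.diff(start) <= 0).any():
        row = int(np.argmax(np.diff(start) <= 0)) + 1
        raise ParseError(f"{path}: frame_start_s not strictly increasing at row {row}")
    if (end <= start).any():
        row = int(np.argmax(end <= start))
        raise ParseError(f"{path}: frame_end_s <= frame_start_s at row {row}")
    try:
        schedule = FrameSchedule(start, end, label=Path(path).stem)
    except SimepetError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    regions = [c for c in df.columns if c not in ("frame_start_s", "frame_end_s")]
    if not regions:
        raise ParseError(f"{path}: no region activity columns")
    tacs = []
    for region in regions:
        act = df[region].to_numpy(float)
        if not np.isfinite(act).all():
            row = int(np.argmax(~np.isfinite(act)))
            raise ParseError(f"{path}: non-finite activity in column {region!r} row {row}")
        tacs.append(TimeActivityCurve(region, schedule, act))
    return tacs


def write_tacs(path, tacs: Sequence[TimeActivityCurve]) -> None:
    schedule = tacs[0].schedule
    data = {
        "frame_start_s": schedule.frame_start,
        "frame_end_s": schedule.frame_end,
    }
    for tac in tacs:
        data[tac.region] = tac.activity
    pd.DataFrame(data).to_csv(path, index=False)


def read_blood(path) -> list[BloodSample]:
    """Read manual blood samples (parent_fraction and site optional per row)."""
    df = _read_csv(path, ["time_min", "whole_blood_kBq_ml", "plasma_kBq_ml"])
    samples = []
    for i, row in df.iterrows():
        pf = row.get("parent_fraction", np.nan)
        site = row.get("site", "venous")
        if isinstance(site, float) and np.isnan(site):
            site = "venous"
        try:
            samples.append(
                BloodSample(
                    time=float(row["time_min"]),
                    whole_blood=float(row["whole_blood_kBq_ml"]),
                    plasma=float(row["plasma_kBq_ml"]),
                    parent_fraction=None if pd.isna(pf) else float(pf),
                    site=str(site),
                )
            )
        except SimepetError as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from exc
    return samples


def write_blood(path, samples: Sequence[BloodSample]) -> None:
    pd.DataFrame(
        {
            "time_min": [s.time for s in samples],
            "whole_blood_kBq_ml": [s.whole_blood for s in samples],
            "plasma_kBq_ml": [s.plasma for s in samples],
            "parent_fraction": [s.parent_fraction for s in samples],
            "site": [s.site for s in samples],
        }
    ).to_csv(path, index=False)


def read_input(path, provenance: str = "AIF") -> InputFunction:
    """Read an input-function curve (plasma-parent column optional)."""
    df = _read_csv(path, ["time_min", "whole_blood_kBq_ml"])
    t = df["time_min"].to_numpy(float)
    if (np.diff(t) <= 0).any():
        row = int(np.argmax(np.diff(t) <= 0)) + 1
        raise ParseError(f"{path}: time_min not strictly increasing at row {row}")
    wb = df["whole_blood_kBq_ml"].to_numpy(float)
    if (wb < 0).any():
        row = int(np.argmax(wb < 0))
        raise ParseError(f"{path}: negative whole_blood_kBq_ml at row {row}")
    pp = None
    if "plasma_parent_kBq_ml" in df.columns:
        pp = df["plasma_parent_kBq_ml"].to_numpy(float)
    try:
        return InputFunction(t, wb, pp, provenance=provenance)
    except SimepetError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_input(path, inp: InputFunction) -> None:
    data = {"time_min": inp.time, "whole_blood_kBq_ml": inp.whole_blood}
    if inp.plasma_parent is not None:
        data["plasma_parent_kBq_ml"] = inp.plasma_parent
    pd.DataFrame(data).to_csv(path, index=False)


class RunConfig(BaseModel):
    """Validated configuration of a quantification run.

    Paths are resolved at run time; ``input_provenance`` decides whether the
    whole-blood curve is treated as an AIF (used as-is) or an IDIF (scaled to
    venous whole-blood samples at ``scaling_times`` before metabolite
    correction).
    """

    tac_csv: Path
    blood_csv: Path
    input_csv: Path
    output_dir: Path = Path("simepet_out")
    input_provenance: Literal["AIF", "IDIF"] = "AIF"
    vb: float = Field(default=0.05, ge=0.0, lt=1.0)
    scan_duration_min: float | None = Field(default=None, gt=0.0)
    weights: str = "frame_duration"
    sime_weights: str | None = None
    method: Literal["optimizer", "simplex", "grid"] = "optimizer"
    n_starts: int = Field(default=3, ge=1)
    scaling_times: list[float] = Field(default_factory=lambda: [45.0, 60.0, 90.0])
    seed: int = 0

    @field_validator("weights")
    @classmethod
    def _check_weights(cls, v: str) -> str:
        if v not in ("frame_duration", "uniform"):
            raise ValueError(f"weights must be frame_duration|uniform, got {v!r}")
        return v

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON ({exc})") from exc
        return cls.model_validate(payload)


@dataclass
class QuantificationReport:
    """Outputs of :func:`run_quantification`."""

    sime: SIMEResults
    refits: dict[str, TwoTissueResults]
    scale_factor: float | None
    table: pd.DataFrame
    run_record: dict
    output_dir: Path


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name prefixed."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise type(exc)(f"{name}: {exc}") from exc
            return False

    return _Ctx()


def run_quantification(config: RunConfig) -> QuantificationReport:
    """Run the full minimally invasive quantification chain.

    blood-model fits -> (IDIF scaling) -> metabolite correction ->
    truncation -> SIME joint fit -> per-region fixed-V_ND refits; writes
    ``parameters.csv``, ``refit_parameters.csv`` and ``run_record.json``
    into ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("read_tacs"):
        tacs = read_tacs(config.tac_csv)
    with _stage("read_blood"):
        blood = read_blood(config.blood_csv)
    with _stage("read_input"):
        inp = read_input(config.input_csv, provenance=config.input_provenance)

    with _stage("fit_bpr"):
        bpr = fit_bpr(blood)
    with _stage("fit_parent_fraction"):
        hill = fit_parent_fraction(blood)

    scale_factor = None
    if config.input_provenance == "IDIF":
        with _stage("scale_idif"):
            venous = [s for s in blood if s.site == "venous"]
            if not venous:
                raise SimepetError("no venous samples")
            inp, scale_factor = scale_idif(inp, venous, config.scaling_times)

    with _stage("metabolite_correct"):
        inp = metabolite_correct(inp, bpr, hill)

    if config.scan_duration_min is not None:
        with _stage("truncate"):
            tacs = [truncate_tac(t, config.scan_duration_min) for t in tacs]

    with _stage("sime_joint_fit"):
        sime = sime_joint_fit(
            tacs, inp, vb=config.vb, weights=config.sime_weights,
            n_starts=config.n_starts, seed=config.seed,
        )
        logger.info(
            "SIME: V_ND=%.4f cost=%.4g converged=%s",
            sime.V_ND_common, sime.total_cost, sime.converged,
        )

    refits: dict[str, TwoTissueResults] = {}
    with _stage("refit_fixed_vnd"):
        for tac in tacs:
            refits[tac.region] = refit_fixed_vnd(
                tac, inp, sime.V_ND_common, vb=config.vb,
                weights=config.weights, seed=config.seed,
            )

    table = sime.to_frame()
    run_record = {
        "config": json.loads(config.model_dump_json()),
        "scale_factor": scale_factor,
        "bpr": {"A1": bpr.A1, "A2": bpr.A2, "lam1": bpr.lam1, "lam2": bpr.lam2},
        "hill": {"a": hill.a, "b": hill.b, "c": hill.c},
        "n_frames": tacs[0].schedule.n_frames,
        "V_ND": sime.V_ND_common,
        "sime_converged": sime.converged,
        "sime_failed": sime.failed,
        "weights_mode": {"2tcm": config.weights, "sime": config.sime_weights or "uniform"},
        "versions": {
            "simepet": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }

    table.to_csv(outdir / "parameters.csv")
    refit_table = pd.DataFrame(
        {region: res.summary()["value"] for region, res in refits.items()}
    ).T.rename_axis("region")
    refit_table.to_csv(outdir / "refit_parameters.csv")
    (outdir / "run_record.json").write_text(json.dumps(run_record, indent=2))

    return QuantificationReport(
        sime=sime,
        refits=refits,
        scale_factor=scale_factor,
        table=table,
        run_record=run_record,
        output_dir=outdir,
    )
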