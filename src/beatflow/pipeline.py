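"""End-to-end orchestration: flow -> beats -> spectrum -> convergence, and
the field-potential batch path, with reproducibility metadata.

Runs are single-threaded and deterministic: the run record echoes every
parameter and carries SHA-256 checksums of inputs and outputs, so a rerun
with the same config and inputs produces byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .beats import beat_pattern, dominant_frequency, frame_motion, power_spectrum
from .convergence import convergence_series, locate_centers
from .errors import InputError
from .flow import ImageSequence, compute_flow
from .fpmetrics import compute_metrics, drug_contrast
from . import io as bfio

__all__ = ["RunConfig", "RunRecord", "run_contractility", "run_fp"]


@dataclass
class RunConfig:
    """All parameters of a pipeline run; defaults follow the two-stage
    64/32-px tile scheme with a 4-px fine search radius."""

    input_path: str | None = None
    output_dir: str = "beatflow_out"
    frame_rate: float = 30.0
    reference_index: int | str = "auto"
    tile_size: int = 64
    fine_tile: int = 32
    step: int | None = None
    fine_step: int | None = None
    search_radius: int = 16
    fine_radius: int = 4
    regularization: float | str = "gcv"
    min_freq: float = 0.05
    center_threshold: float | None = None
    min_separation: float = 32.0
    presmooth_convergence: bool = True
    # field-potential side
    manifest: str | None = None
    trace_sampling_rate: float | None = None
    prominence_frac: float = 0.3
    refractory: float = 0.2
    cv_threshold: float = 0.15
    baseline_well: str | None = None
    treated_well: str | None = None
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class RunRecord:
    config: dict
    version: str
    timings: dict[str, float] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_contractility(
    config: RunConfig, sequence: ImageSequence | None = None
) -> RunRecord:
    """Full contractility analysis of one recording.

    Stages run in order: reference selection -> flow -> beat pattern ->
    power spectrum -> convergence maps and center calls.  All intermediate
    artifacts are written under ``config.output_dir``; a stage failure
    aborts with a stage-tagged error while earlier outputs are preserved.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = RunRecord(config=asdict(config), version=__version__)

    if sequence is None:
        if config.input_path is None:
            raise InputError("run_contractility needs an input stack or sequence")
        sequence = bfio.read_stack(config.input_path, 1.0 / config.frame_rate)
        record.checksums["input"] = _sha256(Path(config.input_path))

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        record.timings[name] = time.perf_counter() - t0
        return result

    if config.reference_index == "auto":
        motion = _stage(
            "reference",
            lambda: frame_motion(
                sequence,
                tile_size=config.tile_size,
                step=config.step,
                search_radius=config.search_radius,
            ),
        )
        ref = motion.t_star
        pd.DataFrame({"frame": np.arange(len(motion.values)), "V_px": motion.values}).to_csv(
            out / "motion.csv", index=False
        )
    else:
        ref = int(config.reference_index)

    fields = _stage(
        "flow",
        lambda: compute_flow(
            sequence,
            ref,
            tile_size=config.tile_size,
            fine_tile=config.fine_tile,
            step=config.step,
            fine_step=config.fine_step,
            search_radius=config.search_radius,
            fine_radius=config.fine_radius,
            regularization=config.regularization,
        ),
    )
    bfio.write_fields_csv(out / "flow.csv", fields)
    bfio.write_fields_npz(out / "flow.npz", fields)

    trace = _stage("beats", lambda: beat_pattern(fields, sequence.frame_interval))
    pd.DataFrame(
        {"frame": np.arange(trace.values.size), "time_s": trace.times, "D_px": trace.values}
    ).to_csv(out / "beats.csv", index=False)

    spectrum = _stage("spectrum", lambda: power_spectrum(trace))
    f_dom = dominant_frequency(spectrum, config.min_freq)
    pd.DataFrame({"freq_hz": spectrum.frequencies, "power": spectrum.power}).to_csv(
        out / "spectrum.csv", index=False
    )

    maps, strength = _stage(
        "convergence",
        lambda: convergence_series(
            fields, presmooth=config.regularization if config.presmooth_convergence else None
        ),
    )
    conv_rows = []
    for m in maps:
        rr, cc = np.meshgrid(m.grid.row_centers, m.grid.col_centers, indexing="ij")
        conv_rows.append(
            pd.DataFrame(
                {
                    "t": m.t,
                    "row": rr.ravel(),
                    "col": cc.ravel(),
                    "convergence": m.values.ravel(),
                    "flagged": m.flagged.ravel().astype(int),
                }
            )
        )
    pd.concat(conv_rows, ignore_index=True).to_csv(out / "convergence.csv", index=False)
    calls = locate_centers(maps, config.center_threshold, config.min_separation)

    record.summary = {
        "t_star": int(ref),
        "n_frames": len(sequence),
        "f_dominant_hz": f_dom,
        "peak_power": float(spectrum.power.max()),
        "max_D_px": float(np.nanmax(trace.values)),
        "max_convergence": float(np.nanmax(strength)),
        "n_centers": len(calls),
        "centers": [
            {
                "row": c.position[0],
                "col": c.position[1],
                "peak_convergence": c.peak_convergence,
                "frame_of_peak": c.frame_of_peak,
            }
            for c in calls
        ],
    }
    bfio.write_json(out / "summary.json", record.summary)
    for name in ("flow.csv", "beats.csv", "spectrum.csv", "convergence.csv", "summary.json"):
        record.checksums[name] = _sha256(out / name)
    bfio.write_json(out / "run_record.json", record)
    return record


def run_fp(config: RunConfig) -> RunRecord:
    """Batch field-potential metrics over a manifest of wells.

    The manifest CSV has columns ``well_id, file, condition`` (extra
    columns pass through).  A missing or unreadable trace does not abort
    the run: the well is flagged failed and the batch continues.  If
    ``baseline_well`` and ``treated_well`` are set, a drug-contrast record
    is computed for that pair.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = RunRecord(config=asdict(config), version=__version__)
    if config.manifest is None:
        raise InputError("run_fp needs a manifest CSV")
    manifest = pd.read_csv(config.manifest)
    if not {"well_id", "file"} <= set(manifest.columns):
        raise InputError("manifest needs columns well_id, file")

    results: dict[str, dict] = {}
    metrics_by_well = {}
    rows = []
    t0 = time.perf_counter()
    for _, entry in manifest.iterrows():
        well = str(entry["well_id"])
        try:
            trace = bfio.read_trace_csv(entry["file"], config.trace_sampling_rate)
            m = compute_metrics(
                trace,
                prominence_frac=config.prominence_frac,
                refractory=config.refractory,
                cv_threshold=config.cv_threshold,
            )
            metrics_by_well[well] = m
            results[well] = {**m.as_dict(), "condition": entry.get("condition", "")}
            for key, value in m.as_dict().items():
                rows.append(
                    {
                        "well_id": well,
                        "condition": entry.get("condition", ""),
                        "metric": key,
                        "value": value,
                    }
                )
        except Exception as exc:
            results[well] = {"status": "failed", "error": str(exc)}
    record.timings["metrics"] = time.perf_counter() - t0

    if config.baseline_well and config.treated_well:
        b = metrics_by_well.get(config.baseline_well)
        t = metrics_by_well.get(config.treated_well)
        if b is not None and t is not None:
            record.summary["contrast"] = drug_contrast(b, t).as_dict()

    record.summary["wells"] = results
    bfio.write_json(out / "fp_metrics.json", results)
    pd.DataFrame(rows).to_csv(out / "fp_metrics.csv", index=False)
    record.checksums["fp_metrics.json"] = _sha256(out / "fp_metrics.json")
    bfio.write_json(out / "fp_run_record.json", record)
    return record
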