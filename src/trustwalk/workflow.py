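"""End-to-end run: simulate a session, compare the models, run the ERP stage.

Every artifact of a run lands in one directory together with the resolved
configuration and a log of the stage seeds, so a run is exactly
reproducible from its own output.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, save_config
from .erp import average_by_condition, baseline_correct, peak_latency, reject_trials
from .evaluation import compare_models
from .io import save_epochs, write_ratings_csv
from .simulate import generate_epochs, generate_rating_trajectory, generate_session

__all__ = ["run_all", "stage_seed", "erp_stage", "P3_WINDOW_MS"]

#: Latency window for the oddball (P3-like) peak summary, ms post feedback.
P3_WINDOW_MS = (300.0, 500.0)


def stage_seed(master_seed: int, section_seed: int) -> int:
    """Deterministic per-stage seed mixing the run seed with a section seed."""
    ss = np.random.SeedSequence([int(master_seed), int(section_seed)])
    return int(ss.generate_state(1)[0] % 2**31)


def erp_stage(epochs, settings, region_map=None) -> dict:
    """Reject, baseline-correct, and average one epoch set.

    Returns the ErpResult plus the rejection/baseline logs and the peak
    summary of the central region in the 300-500 ms window.
    """
    kept, rejection_log = reject_trials(
        epochs,
        voltage_limit_uv=settings.voltage_limit_uv,
        rt_limit_s=settings.rt_limit_s,
    )
    corrected, baseline_log = baseline_correct(kept)
    result = average_by_condition(corrected, region_map=region_map)
    central = result.region_averages["central"]
    peaks = {
        cond: dataclasses.asdict(
            peak_latency(central[cond], result.times_ms, P3_WINDOW_MS, "positive")
        )
        for cond in ("match", "mismatch")
    }
    peaks["difference"] = dataclasses.asdict(
        peak_latency(central["difference"], result.times_ms, P3_WINDOW_MS, "negative")
    )
    return {
        "result": result,
        "rejection_log": rejection_log,
        "baseline_log": baseline_log,
        "peaks_central_300_500": peaks,
    }


def _region_frame(result) -> pd.DataFrame:
    rows = []
    for region, waves in result.region_averages.items():
        for cond, wave in waves.items():
            for t, v in zip(result.times_ms, wave):
                rows.append(
                    {"region": region, "condition": cond, "time_ms": t, "amplitude_uv": v}
                )
    return pd.DataFrame(rows)


def run_all(config: RunConfig, output_dir=None) -> Path:
    """Execute simulate -> compare -> erp and write every artifact.

    Returns the run directory.  Stage failures are re-raised with the stage
    name prefixed.
    """
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(config, outdir / "config_resolved.yaml")

    seeds = {
        "session": stage_seed(config.seed, config.session.seed),
        "ratings": stage_seed(config.seed, config.ratings.seed),
        "epochs": stage_seed(config.seed, config.ratings.seed + 1),
    }

    try:
        session = generate_session(
            dataclasses.replace(config.session, seed=seeds["session"])
        )
        session.to_frame().to_csv(outdir / "trials.csv", index=False)
        session.manifest.to_csv(outdir / "manifest.csv", index=False)

        observations = generate_rating_trajectory(
            dataclasses.replace(config.ratings, seed=seeds["ratings"]),
            n_blocks=config.session.n_blocks,
        )
        write_ratings_csv(observations, outdir / "ratings.csv")

        epochs = generate_epochs(
            session,
            noise_sd_uv=config.erp.noise_sd_uv,
            sampling_rate=config.erp.sampling_rate,
            tmin_ms=config.erp.tmin_ms,
            tmax_ms=config.erp.tmax_ms,
            seed=seeds["epochs"],
        )
        save_epochs(epochs, outdir / "epochs.h5")
    except Exception as exc:
        raise RuntimeError(f"simulate stage failed: {exc}") from exc

    try:
        comparison = compare_models(
            observations,
            markov_params=config.markov,
            quantum_params=config.quantum,
            space=config.space,
            time_scale=config.time_scale,
            trials_per_block=config.session.trials_per_block,
            init=config.initial_state,
        )
        comparison.markov_trajectory.to_frame().to_csv(
            outdir / "trajectory_markov.csv", index=False
        )
        comparison.quantum_trajectory.to_frame().to_csv(
            outdir / "trajectory_quantum.csv", index=False
        )
        (outdir / "comparison.json").write_text(
            json.dumps(comparison.to_dict(), indent=2)
        )
    except Exception as exc:
        raise RuntimeError(f"compare stage failed: {exc}") from exc

    try:
        erp_out = erp_stage(epochs, config.erp)
        _region_frame(erp_out["result"]).to_csv(outdir / "erp_waveforms.csv", index=False)
        summary = {
            "n_trials_used": erp_out["result"].n_trials_used,
            "n_rejected": int(len(erp_out["rejection_log"])),
            "n_baseline_dropped": int(len(erp_out["baseline_log"])),
            "peaks_central_300_500": erp_out["peaks_central_300_500"],
        }
        (outdir / "erp_summary.json").write_text(json.dumps(summary, indent=2))
    except Exception as exc:
        raise RuntimeError(f"erp stage failed: {exc}") from exc

    log_lines = [
        f"trustwalk {__version__}",
        f"python {platform.python_version()}",
        f"numpy {np.__version__}",
        f"master seed: {config.seed}",
    ] + [f"{stage} seed: {s}" for stage, s in seeds.items()]
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir
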