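"""End-to-end runs: configuration, stage orchestration, manifests.

A run simulates (or loads) one movie per condition, tracks it, computes
diffusion/dwell statistics, compares conditions, and writes a manifest
with the seed, parameters, package version and SHA-256 checksum of every
output so a run is verifiably reproducible: identical seeds give
bit-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .compare import compare_conditions
from .dwell import (dwell_from_trajectories, estimate_dwell_mean,
                    records_to_dataframe, summarize_dwell)
from .dynamics import analyze_trajectories, fit_population_peak
from .errors import FitError, RefusalError
from .io import ImageStack, write_json, write_table
from .simulate import TirfSimParams, simulate_tirf_movie
from .tracking import track_movie, trajectories_to_dataframe

log = logging.getLogger("pmspt")


@dataclass
class RunConfig:
    """Everything a reproducible two-or-more-condition run needs."""

    seed: int = 0
    out_dir: str = "pmspt_run"
    conditions: list[dict] = field(default_factory=list)
    tracking: dict = field(default_factory=dict)
    dynamics: dict = field(default_factory=dict)
    dwell: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _condition_seeds(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute simulate -> track -> dynamics/dwell -> compare and manifest.

    Pre-flight checks that every referenced input path exists; a stage
    failure aborts with the failing stage and condition named (partial
    outputs are kept on disk).
    """
    if not config.conditions:
        raise RefusalError("config lists no conditions")
    out = Path(out_dir if out_dir is not None else config.out_dir)
    missing = [c["movie"] for c in config.conditions
               if "movie" in c and not Path(c["movie"]).exists()]
    if missing:
        raise RefusalError("missing input path(s): " + ", ".join(map(str, missing)))
    out.mkdir(parents=True, exist_ok=True)

    seeds = _condition_seeds(config.seed, len(config.conditions))
    track_kw = dict(psf_sigma_px=1.2, snr_threshold=5.0, max_disp_px=3.0,
                    max_gap_frames=1, min_length=5)
    track_kw.update(config.tracking)
    n_lags = int(config.dynamics.get("n_lags", 4))
    threshold_frac = float(config.dwell.get("threshold_frac", 0.5))

    files: list[Path] = []
    d_by_cond: dict[str, list[float]] = {}
    dwell_by_cond: dict[str, list[float]] = {}
    summaries: dict[str, dict] = {}
    for cond, child_seed in zip(config.conditions, seeds):
        label = str(cond.get("label", "condition"))
        cdir = out / label
        cdir.mkdir(exist_ok=True)
        stage = "simulate"
        try:
            if "movie" in cond:
                stack = ImageStack.load(cond["movie"])
            else:
                params = TirfSimParams(**{**cond.get("tirf", {}),
                                          "seed": child_seed})
                stack, truth = simulate_tirf_movie(params)
                stack.save(cdir / "movie.tif")
                truth.save(cdir)
                files += [cdir / "movie.tif", cdir / "truth_particles.csv",
                          cdir / "truth_positions.csv", cdir / "sim_params.json"]

            stage = "track"
            trajs = track_movie(stack, **track_kw)
            write_table(cdir / "trajectories.csv",
                        trajectories_to_dataframe(trajs))
            files.append(cdir / "trajectories.csv")

            stage = "dynamics"
            per_traj = analyze_trajectories(trajs, stack.frame_interval_s,
                                            n_lags=n_lags)
            write_table(cdir / "dynamics.csv", per_traj)
            files.append(cdir / "dynamics.csv")
            d_values = per_traj["D_um2_s"].tolist()
            d_by_cond[label] = d_values
            try:
                pop = fit_population_peak(d_values, "diffusion_coefficient")
                d_summary = {"ghat_um2_s": pop.peak, "sigma": pop.width_sigma,
                             "n": pop.n_values, "estimator": "gaussian_peak"}
            except (RefusalError, FitError) as exc:
                d_summary = {"mean_um2_s": float(np.mean(d_values)) if d_values else None,
                             "n": len(d_values), "estimator": "mean",
                             "note": str(exc)}

            stage = "dwell"
            records = dwell_from_trajectories(trajs, stack.n_frames,
                                              stack.frame_interval_s,
                                              threshold_frac)
            write_table(cdir / "dwell.csv", records_to_dataframe(records))
            files.append(cdir / "dwell.csv")
            dsum = summarize_dwell(records, label)
            dwell_by_cond[label] = [r.dwell_s for r in records if not r.censored]
            try:
                corrected = estimate_dwell_mean(
                    records, stack.frame_interval_s,
                    min_frames=max(2, track_kw["min_length"]))
            except RefusalError:
                corrected = None
            summaries[label] = {
                "n_trajectories": len(trajs),
                "diffusion": d_summary,
                "dwell": {"mean_s": dsum.mean_s, "sd_s": dsum.sd_s,
                          "n": dsum.n, "n_censored": dsum.n_censored,
                          "corrected_mean_s": corrected},
            }
        except Exception as exc:
            raise RefusalError(
                f"stage {stage!r} failed for condition {label!r}: {exc}"
            ) from exc

    comparison = {}
    if len([v for v in d_by_cond.values() if len(v) >= 2]) >= 2:
        comparison["diffusion"] = compare_conditions(d_by_cond).to_dict()
    if len([v for v in dwell_by_cond.values() if len(v) >= 2]) >= 2:
        comparison["dwell"] = compare_conditions(dwell_by_cond).to_dict()
    write_json(out / "summary.json", summaries)
    write_json(out / "comparison.json", comparison)
    files += [out / "summary.json", out / "comparison.json"]

    manifest = {
        "pmspt_version": __version__,
        "seed": config.seed,
        "condition_seeds": seeds,
        "config": config.to_dict(),
        "checksums": {str(f.relative_to(out)): _sha256(f)
                      for f in sorted(set(files))},
    }
    write_json(out / "manifest.json", manifest)
    log.info("run complete: %d conditions, manifest at %s",
             len(config.conditions), out / "manifest.json")
    return manifest
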