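"""End-to-end orchestration: simulate -> track -> profile -> compare.

``run_full_pipeline`` executes the whole organelle-trafficking analysis on a
synthetic experiment: for every condition cell (line x treatment x marker x
position) it generates seeded movies from a scenario parameter table, tracks
them, assembles per-line HC profiles against the untreated-control proximal
baseline, pools them, and runs the profile ANOVA. Every stage writes CSV; a
manifest records the configuration and the per-condition seed trail so a
rerun with the same design reproduces all outputs bit-identically.

The scenario table expresses biology as generator parameters only (e.g. a
distal speed deficit of the mutant pool and its rescue at 10 Hz); the
pipeline itself is condition-agnostic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from .core import Calibration
from .profiling import ConditionKey, condition_summary, pool_profiles, profile_anova, zscore_profile
from .synthetic import OrganelleSceneConfig, generate_organelle_movie
from .tracking import track_movie

__all__ = ["ExperimentDesign", "default_scenario", "run_full_pipeline"]

logger = logging.getLogger("axoquant.pipeline")

TREATMENTS = ("untreated", "2Hz", "10Hz", "10/2Hz")
POSITIONS = ("distal", "proximal")
MARKERS = ("mito", "lyso")


@dataclass
class ExperimentDesign:
    """Lines, conditions and replication of a (synthetic) experiment.

    The replication defaults mirror the study design (>= 45 movies per
    condition from >= 3 independent experiments; 10 images per condition);
    scaled-down designs are appropriate for desk-scale runs.
    """

    lines: Mapping[str, str] = field(
        default_factory=lambda: {"Ctrl1": "Ctrl", "Ctrl2": "Ctrl", "FUS1": "mutantFUS", "FUS2": "mutantFUS"}
    )
    treatments: tuple[str, ...] = TREATMENTS
    positions: tuple[str, ...] = POSITIONS
    markers: tuple[str, ...] = MARKERS
    movies_per_condition: int = 45
    n_experiments: int = 3
    images_per_condition: int = 10
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValueError("need at least one line")
        if self.movies_per_condition < 1:
            raise ValueError("movies_per_condition must be >= 1")
        for t in self.treatments:
            if t not in TREATMENTS:
                raise ValueError(f"unknown treatment {t!r}")

    def condition_seed(self, line: str, treatment: str, marker: str, position: str, movie: int) -> int:
        """Deterministic per-movie seed derived from the master seed."""
        key = f"{self.master_seed}|{line}|{treatment}|{marker}|{position}|{movie}"
        digest = hashlib.sha256(key.encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2**31 - 1)


def default_scenario(
    n_organelles: int = 40,
    base_speed: float = 0.8,
    base_moving_fraction: float = 0.4,
) -> pd.DataFrame:
    """Scenario table encoding a distal-only mutant deficit rescued at 10 Hz.

    One row per (genotype pool, treatment, position) with the organelle
    generator parameters of that condition. The untreated mutant pool runs at
    about 60% of the control distal speed and moving fraction; 10 Hz and
    10/2 Hz restore control levels; 2 Hz does not. Proximal conditions are
    physiological everywhere, matching the observed distal-specific deficit.
    """
    rows = []
    for genotype in ("Ctrl", "mutantFUS"):
        for treatment in TREATMENTS:
            for position in POSITIONS:
                speed, frac = base_speed, base_moving_fraction
                deficient = genotype == "mutantFUS" and position == "distal" and treatment in ("untreated", "2Hz")
                if deficient:
                    speed, frac = 0.6 * base_speed, 0.6 * base_moving_fraction
                rows.append((genotype, treatment, position, n_organelles, speed, 0.15 * speed, frac))
    return pd.DataFrame(
        rows,
        columns=[
            "genotype", "treatment", "position",
            "n_organelles", "speed_mean_um_s", "speed_sd_um_s", "moving_fraction",
        ],
    )


def _movie_config(row: pd.Series, marker: str, design_seed: int, n_frames: int, frame_px: int) -> OrganelleSceneConfig:
    kind = "mitochondrion" if marker == "mito" else "lysosome"
    return OrganelleSceneConfig(
        organelle_kind=kind,
        n_organelles=int(row.n_organelles),
        moving_fraction=float(row.moving_fraction),
        speed_mean_um_s=float(row.speed_mean_um_s),
        speed_sd_um_s=float(row.speed_sd_um_s),
        n_frames=n_frames,
        width=frame_px,
        height=frame_px,
        seed=design_seed,
    )


def run_full_pipeline(
    design: ExperimentDesign,
    scenario: pd.DataFrame | None = None,
    out_dir: str | Path = "axoquant_run",
    calib: Calibration | None = None,
    n_frames: int = 60,
    frame_px: int = 192,
    run_anova: bool = True,
) -> dict:
    """Run simulate -> track -> profile (-> ANOVA) and write all outputs.

    Returns a result bundle dict with the movie-summary table, per-line
    profiles, pooled pool profiles, the comparison table (or None) and the
    manifest. ``n_frames``/``frame_px`` size the synthetic movies; the study
    acquisition (400 frames, 512 px) is reproduced by passing those values.
    """
    t0 = time.time()
    scenario = default_scenario() if scenario is None else scenario
    calib = calib or Calibration()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    required = {"genotype", "treatment", "position", "n_organelles",
                "speed_mean_um_s", "speed_sd_um_s", "moving_fraction"}
    missing = required - set(scenario.columns)
    if missing:
        raise ValueError(f"scenario table missing columns: {sorted(missing)}")

    summaries = []
    seed_trail = []
    for line, pool in design.lines.items():
        for treatment in design.treatments:
            for marker in design.markers:
                for position in design.positions:
                    sel = scenario[
                        (scenario.genotype == pool)
                        & (scenario.treatment == treatment)
                        & (scenario.position == position)
                    ]
                    if len(sel) == 0:
                        raise ValueError(
                            f"stage 'simulate': scenario row missing for "
                            f"({pool}, {treatment}, {position})"
                        )
                    row = sel.iloc[0]
                    for movie in range(design.movies_per_condition):
                        seed = design.condition_seed(line, treatment, marker, position, movie)
                        seed_trail.append(
                            {"line": line, "treatment": treatment, "marker": marker,
                             "position": position, "movie": movie, "seed": seed}
                        )
                        cfg = _movie_config(row, marker, seed, n_frames, frame_px)
                        stack, _ = generate_organelle_movie(cfg, calib)
                        _, _, summary = track_movie(
                            stack.data, calib, marker,
                            metadata={
                                "line": line, "genotype": pool, "treatment": treatment,
                                "marker": marker, "position": position, "movie": movie,
                            },
                        )
                        summaries.append(summary)
                    logger.info("tracked %s/%s/%s/%s", line, treatment, marker, position)
    summary_df = pd.DataFrame(summaries)
    summary_df.to_csv(out / "movie_summaries.csv", index=False)

    # per-line profiles, baselines from the pooled untreated-Ctrl proximal movies
    baseline_tables = {
        marker: condition_summary(
            summary_df, ConditionKey("Ctrl", "untreated", marker, "proximal")
        )
        for marker in design.markers
    }
    profiles: dict[tuple[str, str], pd.DataFrame] = {}
    for line, pool in design.lines.items():
        for treatment in design.treatments:
            cond_tables = {}
            for marker in design.markers:
                for position in design.positions:
                    sel = summary_df[
                        (summary_df.line == line)
                        & (summary_df.treatment == treatment)
                        & (summary_df.marker == marker)
                        & (summary_df.position == position)
                    ]
                    cond_tables[(marker, position)] = sel
            profiles[(line, treatment)] = zscore_profile(cond_tables, baseline_tables)
    prof_rows = []
    for (line, treatment), prof in profiles.items():
        p = prof.reset_index()
        p.insert(0, "line", line)
        p.insert(1, "treatment", treatment)
        prof_rows.append(p)
    pd.concat(prof_rows, ignore_index=True).to_csv(out / "hc_profiles.csv", index=False)

    pools = sorted(set(design.lines.values()))
    pooled = {}
    by_condition: dict[str, list[pd.DataFrame]] = {}
    for pool in pools:
        pool_lines = [ln for ln, p in design.lines.items() if p == pool]
        for treatment in design.treatments:
            name = f"{pool} {treatment}"
            profs = [profiles[(ln, treatment)] for ln in pool_lines]
            pooled[name] = pool_profiles(profs)
            by_condition[name] = profs
    pd.concat(
        [p.reset_index().assign(condition=name) for name, p in pooled.items()], ignore_index=True
    ).to_csv(out / "pooled_profiles.csv", index=False)

    comparisons = None
    if run_anova and all(len(v) >= 2 for v in by_condition.values()):
        comparisons = profile_anova(by_condition)
        comparisons.to_csv(out / "profile_comparisons.csv", index=False)

    manifest = {
        "design": {**asdict(design), "lines": dict(design.lines)},
        "scenario_sha256": hashlib.sha256(
            scenario.to_csv(index=False).encode()
        ).hexdigest(),
        "n_frames": n_frames,
        "frame_px": frame_px,
        "calibration": asdict(calib),
        "n_movies": len(summary_df),
    }
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    pd.DataFrame(seed_trail).to_csv(out / "seed_trail.csv", index=False)

    return {
        "summaries": summary_df,
        "profiles": profiles,
        "pooled": pooled,
        "comparisons": comparisons,
        "manifest": manifest,
    }
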