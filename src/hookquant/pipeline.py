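"""End-to-end orchestration: images + landmarks + metadata → CSV bundles.

The quantify pipeline chains, per seedling: signal conversion →
bisector ray → tissue chord → chord sampling → normalization → per-
seedling area/ARDI, then aggregates ensembles per genotype × day and
runs ANOVA/Tukey comparisons of ARDI and area per day.

Policy on real-world batches: a seedling whose landmarks are missing or
whose chord cannot be found is skipped and recorded in the run log; the
exit status distinguishes clean (0) from partial (3) runs.  All CSV
outputs are deterministic (fixed column order, fixed float formatting),
so identical configurations yield byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import HookQuantError, ValidationError
from .geometry import (
    SeedlingLandmarks,
    bisector_ray,
    hook_angle,
    read_landmarks_json,
    tissue_chord,
    write_landmarks_json,
)
from .profile import (
    ensemble_mean_sd,
    normalize_resample,
    plot_ensembles,
    profiles_to_frame,
    read_image,
    sample_chord,
    to_signal,
)
from .stats import (
    dose_response_slope,
    minimum_effective_concentration,
    one_way_anova_tukey,
    read_angle_table,
    summarize_profiles,
    two_way_anova_tukey,
)
from .synthetic import (
    SCENARIOS,
    render_hook_image,
    sample_scenario_specs,
    write_image,
)

__all__ = [
    "RunConfig",
    "load_config",
    "run_quantify",
    "run_simulate",
    "run_angles",
    "run_dose_response",
    "EXIT_CLEAN",
    "EXIT_PARTIAL",
]

EXIT_CLEAN = 0
EXIT_PARTIAL = 3

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Configuration shared by the pipeline subcommands."""

    images_dir: Optional[str] = None
    landmarks_path: Optional[str] = None
    metadata_path: Optional[str] = None
    out_dir: str = "hookquant_out"
    polarity: str = "stain_dark"
    n_points: int = 101
    step: float = 0.5
    alpha: float = 0.05
    threshold: object = "auto"
    seed: int = 0
    scenario: Optional[str] = None
    n_seedlings: int = 30
    noise_sd: Optional[float] = None
    plot: bool = False

    def __post_init__(self):
        if self.n_points < 2:
            raise ValidationError("n_points must be >= 2")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.step <= 0:
            raise ValidationError("step must be > 0")
        if self.polarity not in ("stain_dark", "stain_bright"):
            raise ValidationError(f"unknown polarity {self.polarity!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Explicit keyword arguments (CLI flags) take precedence over the file.
    """
    values: dict = {}
    if path is not None:
        with open(path) as f:
            loaded = yaml.safe_load(f) or {}
        if not isinstance(loaded, dict):
            raise ValidationError("config file must contain a key: value mapping")
        unknown = set(loaded) - {f.name for f in dataclasses.fields(RunConfig)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _write_log(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        json.dump(payload, f, indent=1, sort_keys=True, default=str)


def measure_seedling(
    image: np.ndarray,
    landmarks: SeedlingLandmarks,
    polarity: str = "stain_dark",
    n_points: int = 101,
    step: float = 0.5,
    threshold="auto",
    seedling_id: str = "",
    metadata: Optional[dict] = None,
):
    """Run the single-seedling measurement chain.

    Returns ``(profile, chord, angle_deg)``.
    """
    signal = to_signal(image, polarity=polarity)
    ray = bisector_ray(landmarks)
    chord = tissue_chord(signal, ray, background_threshold=threshold, step=step)
    pos, vals = sample_chord(signal, chord, step=step)
    prof = normalize_resample(
        pos, vals, n_points=n_points, seedling_id=seedling_id, metadata=metadata
    )
    return prof, chord, hook_angle(landmarks)


@dataclass
class QuantifyResult:
    profiles: pd.DataFrame
    summaries: pd.DataFrame
    ensembles: pd.DataFrame
    comparisons: pd.DataFrame
    failures: dict
    exit_code: int


def run_quantify(config: RunConfig) -> QuantifyResult:
    """Quantify a directory of seedling images.

    Expects ``images_dir`` with one PNG/TIFF per seedling (file stem =
    seedling_id), a landmarks JSON mapping seedling_id → landmarks, and a
    metadata CSV with columns seedling_id, genotype, day, treatment.
    """
    for name in ("images_dir", "landmarks_path", "metadata_path"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise ValidationError(f"{name} does not exist: {p!r}")
    out = Path(config.out_dir)
    images = sorted(
        p
        for p in Path(config.images_dir).iterdir()
        if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not images:
        raise ValidationError(f"no images found in {config.images_dir!r}")
    landmarks = read_landmarks_json(config.landmarks_path)
    meta = pd.read_csv(config.metadata_path, dtype={"seedling_id": str})
    required = {"seedling_id", "genotype", "day", "treatment"}
    if not required.issubset(meta.columns):
        raise ValidationError(
            f"metadata must have columns {sorted(required)}"
        )
    meta = meta.set_index("seedling_id")

    profiles, failures, angle_rows = [], {}, []
    for img_path in images:
        sid = img_path.stem
        try:
            if sid not in landmarks:
                raise ValidationError("no landmarks for this seedling")
            if sid not in meta.index:
                raise ValidationError("no metadata for this seedling")
            row = meta.loc[sid]
            md = {
                "genotype": str(row["genotype"]),
                "day": int(row["day"]),
                "treatment": str(row["treatment"]),
            }
            prof, chord, angle = measure_seedling(
                read_image(img_path),
                landmarks[sid],
                polarity=config.polarity,
                n_points=config.n_points,
                step=config.step,
                threshold=config.threshold,
                seedling_id=sid,
                metadata=md,
            )
            profiles.append(prof)
            angle_rows.append(
                {"seedling_id": sid, "hook_angle_deg": angle,
                 "chord_length_px": chord.length}
            )
        except HookQuantError as e:
            failures[sid] = str(e)
    if not profiles:
        raise ValidationError("no seedling could be quantified; see failures")

    summaries = summarize_profiles(profiles)
    summ_df = pd.DataFrame(
        [
            {
                "seedling_id": s.seedling_id,
                "genotype": s.metadata["genotype"],
                "day": s.metadata["day"],
                "treatment": s.metadata["treatment"],
                "area": s.area,
                "ardi": s.ardi,
            }
            for s in summaries
        ]
    ).sort_values("seedling_id", kind="stable", ignore_index=True)
    summ_df = summ_df.merge(pd.DataFrame(angle_rows), on="seedling_id", how="left")

    # per genotype x day ensemble mean +- SD
    ens_rows = []
    ens_by_group = {}
    groups = {}
    for p in profiles:
        key = (p.metadata["genotype"], p.metadata["day"])
        groups.setdefault(key, []).append(p)
    for (genotype, day), plist in sorted(groups.items()):
        summ = ensemble_mean_sd(plist)
        ens_by_group[f"{genotype} {day}dD"] = summ
        for s_pos, m, sd in zip(summ.positions, summ.mean_values, summ.sd_values):
            ens_rows.append(
                {
                    "genotype": genotype,
                    "day": day,
                    "s": s_pos,
                    "mean": m,
                    "sd": sd,
                    "n": summ.n,
                }
            )
    ens_df = pd.DataFrame(ens_rows)

    # ANOVA/Tukey of ARDI and area across genotypes, per day
    comp_rows = []
    for day, day_df in summ_df.groupby("day", sort=True):
        counts = day_df.groupby("genotype").size()
        if len(counts) < 2 or (counts < 2).any():
            continue
        for metric in ("ardi", "area"):
            res = one_way_anova_tukey(
                day_df.rename(columns={metric: "value"}),
                alpha=config.alpha,
                value_col="value",
                group_col="genotype",
            )
            p_omni = float(res.anova["p"].iloc[0])
            for g in res.groups:
                comp_rows.append(
                    {
                        "day": day,
                        "metric": metric,
                        "genotype": g,
                        "n": res.n_per_group[g],
                        "mean": res.means[g],
                        "letters": res.letters[g],
                        "anova_p": p_omni,
                    }
                )
    comp_df = pd.DataFrame(
        comp_rows,
        columns=["day", "metric", "genotype", "n", "mean", "letters", "anova_p"],
    )

    _write_csv(profiles_to_frame(profiles), out / "profiles.csv")
    _write_csv(summ_df, out / "gradient_summaries.csv")
    _write_csv(ens_df, out / "ensemble_summaries.csv")
    _write_csv(comp_df, out / "comparisons.csv")
    if config.plot:
        plot_ensembles(ens_by_group, out / "ensemble_profiles.png")
    exit_code = EXIT_PARTIAL if failures else EXIT_CLEAN
    _write_log(
        out / "run_log.json",
        {
            "command": "quantify",
            "hookquant_version": __version__,
            "config": config.to_dict(),
            "config_digest": config.digest(),
            "n_quantified": len(profiles),
            "failures": failures,
            "exit_code": exit_code,
        },
    )
    return QuantifyResult(
        profiles=profiles_to_frame(profiles),
        summaries=summ_df,
        ensembles=ens_df,
        comparisons=comp_df,
        failures=failures,
        exit_code=exit_code,
    )


def run_simulate(config: RunConfig) -> Path:
    """Write a self-consistent synthetic fixture directory.

    Layout: ``images/<id>.png``, ``landmarks.json``, ``truth.json``,
    ``metadata.csv`` — directly consumable by :func:`run_quantify`
    (with ``polarity="stain_bright"``).
    """
    if config.scenario is None:
        raise ValidationError(
            "scenario is required; registered: " + ", ".join(sorted(SCENARIOS))
        )
    specs = sample_scenario_specs(
        config.scenario, config.n_seedlings, seed=config.seed,
        noise_sd=config.noise_sd,
    )
    out = Path(config.out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    landmarks, truths, meta_rows = {}, {}, []
    for i, spec in enumerate(specs):
        sid = f"{config.scenario}_{i:03d}"
        img, truth, lm = render_hook_image(spec)
        write_image(out / "images" / f"{sid}.png", img)
        landmarks[sid] = lm
        truths[sid] = {**truth.to_dict(), "spec": dataclasses.asdict(spec)}
        meta_rows.append(
            {
                "seedling_id": sid,
                "genotype": config.scenario,
                "day": 2,
                "treatment": "mock",
            }
        )
    write_landmarks_json(out / "landmarks.json", landmarks)
    _write_log(out / "truth.json", truths)
    _write_csv(pd.DataFrame(meta_rows), out / "metadata.csv")
    _write_log(
        out / "run_log.json",
        {
            "command": "simulate",
            "hookquant_version": __version__,
            "config": config.to_dict(),
            "config_digest": config.digest(),
            "n_seedlings": len(specs),
        },
    )
    return out


def run_angles(config: RunConfig, table_path) -> pd.DataFrame:
    """Group summaries + one-way ANOVA letters for an angle table.

    For every (day, concentration) cell with >= 2 genotypes the angle
    distributions are compared across genotypes; output rows carry group
    means, SD, n and compact letters.
    """
    table = read_angle_table(table_path)
    out = Path(config.out_dir)
    rows = []
    for (day, conc), sub in table.groupby(["day", "concentration_uM"], sort=True):
        counts = sub.groupby("genotype").size()
        sds = sub.groupby("genotype")["angle_deg"].std(ddof=1)
        if len(counts) < 2 or (counts < 2).any():
            continue
        res = one_way_anova_tukey(
            sub.rename(columns={"angle_deg": "value"}),
            alpha=config.alpha,
            value_col="value",
            group_col="genotype",
        )
        for g in res.groups:
            rows.append(
                {
                    "day": day,
                    "concentration_uM": conc,
                    "genotype": g,
                    "n": res.n_per_group[g],
                    "mean_angle_deg": res.means[g],
                    "sd_angle_deg": float(sds[g]),
                    "letters": res.letters[g],
                    "anova_p": float(res.anova["p"].iloc[0]),
                }
            )
    df = pd.DataFrame(rows)
    _write_csv(df, out / "angle_comparisons.csv")
    _write_log(
        out / "run_log.json",
        {
            "command": "angles",
            "hookquant_version": __version__,
            "config": config.to_dict(),
            "config_digest": config.digest(),
            "table": str(table_path),
        },
    )
    return df


def run_dose_response(
    config: RunConfig, table_path, c_low: float, c_high: float,
    day: Optional[int] = None,
) -> dict:
    """Dose-response analysis bundle for an angle table.

    Writes per-genotype per-day slopes between ``c_low`` and ``c_high``,
    minimum effective concentrations versus mock, and (where the design
    is balanced) per-day two-way genotype × concentration ANOVA/Tukey
    results.
    """
    table = read_angle_table(table_path)
    out = Path(config.out_dir)
    slopes = dose_response_slope(table, c_low, c_high, day=day)
    mec = minimum_effective_concentration(table, alpha=config.alpha, day=day)
    _write_csv(slopes, out / "dose_response_slopes.csv")
    _write_csv(mec, out / "minimum_effective_concentration.csv")

    twoway_rows = []
    sub_all = table if day is None else table[table["day"] == day]
    for d, sub in sub_all.groupby("day", sort=True):
        try:
            res = two_way_anova_tukey(
                sub,
                value_col="angle_deg",
                factor_a="genotype",
                factor_b="concentration_uM",
                alpha=config.alpha,
            )
        except HookQuantError as e:
            twoway_rows.append(
                {"day": d, "source": "skipped", "sum_sq": np.nan, "df": np.nan,
                 "F": np.nan, "p": np.nan, "note": str(e)}
            )
            continue
        for _, r in res.anova.iterrows():
            twoway_rows.append(
                {"day": d, "source": r["source"], "sum_sq": r["sum_sq"],
                 "df": r["df"], "F": r["F"], "p": r["p"], "note": res.note}
            )
    twoway = pd.DataFrame(
        twoway_rows, columns=["day", "source", "sum_sq", "df", "F", "p", "note"]
    )
    _write_csv(twoway, out / "two_way_anova.csv")
    _write_log(
        out / "run_log.json",
        {
            "command": "dose-response",
            "hookquant_version": __version__,
            "config": config.to_dict(),
            "config_digest": config.digest(),
            "c_low": c_low,
            "c_high": c_high,
            "day": day,
            "table": str(table_path),
        },
    )
    return {"slopes": slopes, "mec": mec, "two_way": twoway}
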