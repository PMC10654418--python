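"""End-to-end driver: simulate -> prepare -> model -> overlap -> summarize.

A single :class:`RunConfig` (YAML-serializable) controls every stage;
all stage seeds are fanned out deterministically from one master seed,
so each stage is independently reproducible.  Every artifact lands in
the configured output directory and the run report embeds the config
hash, the derived seeds, and the record counts surviving each filter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import overlap as ov
from . import prep, rasters, sdm, summaries, synth

log = logging.getLogger(__name__)


def derive_seed(master: int, stage: str) -> int:
    """Per-stage seed from the master seed: SeedSequence keyed on a
    CRC32 of the stage name, reduced below 2^31."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(zlib.crc32(stage.encode()),))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    out_dir: str = "run_output"
    survey_path: str | None = None      # read a survey instead of simulating
    env_dir: str | None = None          # read .asc layers instead of simulating
    simulate: dict[str, Any] = field(default_factory=dict)  # EnvSpec/SurveySpec overrides
    cell: float = 25.0
    min_occurrence: int = 100
    n_trees: int = 1000
    importance_permutations: int = 10
    n_permutations: int = 100_000
    alpha: float = 0.05
    grid_step: float = 100.0
    cv_folds: int = 10
    do_crossval: bool = True
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
    return _Ctx()


def _simulate(config: RunConfig, out: Path) -> tuple[rasters.EnvStack, pd.DataFrame, dict[str, str]]:
    opts = dict(config.simulate)
    grid_opts = opts.pop("grid", None)
    env_spec = synth.EnvSpec(seed=derive_seed(config.seed, "env"))
    if grid_opts:
        env_spec = dataclasses.replace(env_spec, grid=rasters.GridSpec(**grid_opts))
    survey_spec = synth.SurveySpec(seed=derive_seed(config.seed, "survey"))
    survey_fields = {f.name for f in dataclasses.fields(synth.SurveySpec)}
    survey_spec = dataclasses.replace(
        survey_spec, **{k: v for k, v in opts.items() if k in survey_fields and k != "seed"}
    )
    env = synth.generate_env_stack(env_spec)
    niches = synth.default_niches(env_spec, seed=derive_seed(config.seed, "niches"))
    table, truth = synth.simulate_survey(env, niches, survey_spec)
    groups = {n.species: n.group for n in niches}
    rasters.write_env_stack(env, out / "env")
    table.to_csv(out / "survey.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    return env, table, groups


def run_pipeline(config: RunConfig, groups: dict[str, str] | None = None) -> dict[str, Any]:
    """Execute every stage in order and return the machine-readable
    report (also written to ``<out_dir>/report.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "config_hash": config.digest(),
        "master_seed": config.seed,
        "stage_seeds": {s: derive_seed(config.seed, s) for s in
                        ("env", "survey", "niches", "prep", "sdm", "overlap")},
        "counts": {},
    }
    config.to_yaml(out / "config.yaml")

    with _stage("inputs"):
        if config.survey_path and config.env_dir:
            env = rasters.read_env_stack(config.env_dir)
            table = pd.read_csv(config.survey_path)
            groups = groups or {}
        else:
            env, table, groups = _simulate(config, out)
    report["counts"]["raw_records"] = int(len(table))
    report["counts"]["raw_sites"] = int(table["site_id"].nunique())

    with _stage("prepare"):
        matrix = prep.prepare_survey(
            table, groups=groups, cell=config.cell,
            min_occurrence=config.min_occurrence, seed=derive_seed(config.seed, "prep"),
        )
        if not matrix.species:
            raise ValueError(
                f"no species reach {config.min_occurrence} occurrences; nothing to model"
            )
        matrix.to_wide_csv(out / "occurrence_matrix.csv")
        feats = prep.extract_env(matrix, env)
        aligned = matrix.values.loc[feats.index]
    report["counts"]["filtered_sites"] = int(matrix.n_sites)
    report["counts"]["modelled_sites"] = int(len(feats))
    report["counts"]["species"] = list(matrix.species)

    rf_config = sdm.RFConfig(
        n_trees=config.n_trees,
        importance_permutations=config.importance_permutations,
        seed=derive_seed(config.seed, "sdm"),
    )
    maps: dict[str, np.ndarray] = {}
    cv_results: dict[str, sdm.CVMetrics] = {}
    areas_rows = []
    with _stage("models"):
        (out / "maps").mkdir(exist_ok=True)
        for sp in matrix.species:
            y = aligned[sp]
            if config.do_crossval:
                cv_results[sp] = sdm.cross_validate(
                    feats, y, k=config.cv_folds, config=rf_config,
                )
            model = sdm.fit_rf(feats, y.rename(sp), kind="regression", config=rf_config)
            model.cv = cv_results.get(sp)
            pg = sdm.predict_grid(model, env, grid_step=config.grid_step)
            maps[sp] = pg.binary_map()
            rasters.write_ascii_grid(out / "maps" / f"{sp}_binary.asc", pg.grid, maps[sp])
            rasters.write_ascii_grid(out / "maps" / f"{sp}_probability.asc", pg.grid, pg.probability_map())
            areas_rows.append({
                "species": sp,
                "threshold": model.threshold,
                "area_km2": summaries.distribution_area(maps[sp], config.grid_step),
                "top_predictor": model.importance.index[0] if len(model.importance) else None,
            })
        if cv_results:
            table_cv = sdm.cv_table(cv_results)
            table_cv.to_csv(out / "cv_metrics.csv")
            report["cv_metrics"] = table_cv.round(4).to_dict(orient="index")

    with _stage("overlap"):
        plan = ov.PermutationPlan(
            n_permutations=config.n_permutations, alpha=config.alpha,
            seed=derive_seed(config.seed, "overlap"),
        )
        result = ov.pairwise_overlap(matrix, plan)
        result.d_matrix.to_csv(out / "schoener_d.csv")
        result.directional.to_csv(out / "directional_overlap.csv")
        result.pair_table.to_csv(out / "pair_table.csv", index=False)
        report["overlap"] = {
            "n_pairs": int(len(result.pair_table)),
            "n_significant": result.n_significant,
            "mean_d": {k: round(v, 4) for k, v in result.mean_d.items()},
        }
        if groups and len({groups.get(s) for s in matrix.species} - {None}) > 1:
            try:
                h, p, means = ov.group_overlap_comparison(result, groups)
            except ValueError as exc:  # an empty pair class after filtering
                log.warning("group comparison skipped: %s", exc)
            else:
                report["overlap"]["kruskal_wallis"] = {
                    "h": round(h, 4), "p": round(p, 6),
                    "group_mean_d": {k: round(v, 4) for k, v in means.items()},
                    "note": "pairwise D values sharing a species are not independent; descriptive",
                }

    with _stage("summaries"):
        stack = summaries.BinaryMapStack(
            maps=maps, cell_size=config.grid_step, groups=groups or {},
        )
        areas = pd.DataFrame(areas_rows).set_index("species")
        partition = summaries.single_vs_multi_area(stack)
        areas = areas.join(partition)
        areas.to_csv(out / "areas.csv")
        report["areas_km2"] = areas[["area_km2", "alone_km2", "co_occurring_km2"]].round(3).to_dict(orient="index")
        if groups and len({groups.get(s) for s in matrix.species} - {None}) > 1:
            breakdown = summaries.cohabitation_breakdown(stack, groups)
            with open(out / "cohabitation.json", "w") as fh:
                json.dump(breakdown, fh, indent=2)
            report["cohabitation"] = breakdown

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
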