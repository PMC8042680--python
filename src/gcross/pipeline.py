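"""End-to-end replication pipeline: descriptives -> G study -> D study.

For each (scenario pairing, measure) the pipeline produces the three table
shapes of the source study: cell means by scenario and rater, the
variance-component table with percent-of-total shares, and the D-study
footer of generalizability coefficients, plus the rater/task correlations
and the minimum-tasks search for a target reliability.  A manifest records
the configuration, seed and package version; outputs are written atomically
(nothing is left behind on failure) and are byte-identical across reruns of
the same config and input.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._round import round_half_up
from .descriptives import cell_means, inter_rater_correlation, inter_task_correlation
from .dstudy import DEFAULT_DESIGNS, g_table, min_tasks_for_target
from .gstudy import COMPONENT_NAMES, estimate_components, percent_of_total
from .records import build_cube, read_ratings
from .simulate import SimulationSpec, simulate_ratings

log = logging.getLogger("gcross")

__all__ = ["PipelineConfig", "run_pipeline"]

_COMPONENT_LABELS = {
    "p": "Person (P)", "t": "Task (T)", "r": "Rater (R)",
    "pt": "Person x Task", "pr": "Person x Rater", "tr": "Task x Rater",
    "e": "Error",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration for a full pipeline run."""

    output_dir: str | Path
    input: str | Path | None = None
    simulate: dict | None = None  # SimulationSpec kwargs incl. optional 'preset'
    pairings: tuple[tuple[str, tuple[str, ...]], ...] = ()
    measures: tuple[str, ...] = ("behavioural", "technical")
    designs: tuple[tuple[int, int], ...] = DEFAULT_DESIGNS
    target: float = 0.70
    target_raters: int = 2
    rounding: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.measures:
            raise ValueError("at least one measure is required")
        if self.input is None and self.simulate is None:
            raise ValueError("either an input CSV or a simulation block is required")
        if self.input is not None and not self.pairings:
            raise ValueError("CSV input requires at least one pairing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pairings" in raw:
            raw["pairings"] = tuple(
                (p["label"], tuple(p["tasks"])) for p in raw["pairings"]
            )
        if "measures" in raw:
            raw["measures"] = tuple(raw["measures"])
        if "designs" in raw:
            raw["designs"] = tuple(tuple(d) for d in raw["designs"])
        return cls(**raw)


def _slug(text: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in text.lower()).strip("_")


def _analyse_cube(cube, cfg: PipelineConfig, outdir: Path, tag: str) -> dict:
    log.info("analysing %s: %d persons x %d tasks x %d raters",
             tag, cube.n_p, cube.n_t, cube.n_r)

    desc = pd.DataFrame([dataclasses.asdict(s) for s in cell_means(cube)])
    desc.to_csv(outdir / f"{tag}_descriptives.csv", index=False)

    vc = estimate_components(cube)
    log.debug("raw components %s: %s", tag, vc.raw)
    pct = percent_of_total(vc)
    comp = pd.DataFrame(
        {
            "source": [_COMPONENT_LABELS[k] for k in COMPONENT_NAMES],
            "estimate": [round_half_up(vc.sigma2[k], cfg.rounding) for k in COMPONENT_NAMES],
            "percent": [pct[k] for k in COMPONENT_NAMES],
        }
    )
    comp.to_csv(outdir / f"{tag}_components.csv", index=False)

    # a zero (truncated) person variance leaves reliability undefined;
    # the D-study footer is then emitted with empty coefficient columns
    reliable = vc.sigma2["p"] > 0
    if reliable:
        dres = g_table(vc, list(cfg.designs))
        g_col = [round_half_up(d.g_coefficient, cfg.rounding) for d in dres]
        phi_col = [round_half_up(d.phi_coefficient, cfg.rounding) for d in dres]
    else:
        log.warning("%s: person variance estimated as 0; G undefined", tag)
        from .dstudy import DStudyResult, absolute_error_variance, relative_error_variance

        dres = [
            DStudyResult(nt, nr, relative_error_variance(vc, nt, nr),
                         absolute_error_variance(vc, nt, nr),
                         float("nan"), float("nan"))
            for nt, nr in cfg.designs
        ]
        g_col = [None] * len(dres)
        phi_col = [None] * len(dres)
    dtab = pd.DataFrame(
        {
            "n_tasks": [d.n_t_prime for d in dres],
            "n_raters": [d.n_r_prime for d in dres],
            "rel_error_var": [round(d.rel_error_var, 6) for d in dres],
            "abs_error_var": [round(d.abs_error_var, 6) for d in dres],
            "g": g_col,
            "phi": phi_col,
        }
    )
    dtab.to_csv(outdir / f"{tag}_dstudy.csv", index=False)

    corr = {}
    if cube.n_r == 2:
        corr["inter_rater"] = round_half_up(inter_rater_correlation(cube), 2)
    if cube.n_t == 2:
        corr["inter_task"] = round_half_up(inter_task_correlation(cube), 2)
    n_min = min_tasks_for_target(vc, cfg.target_raters, cfg.target) if reliable else None
    summary = {
        "tag": tag,
        "design": {"n_p": cube.n_p, "n_t": cube.n_t, "n_r": cube.n_r},
        "components": {k: vc.sigma2[k] for k in COMPONENT_NAMES},
        "percent": pct,
        "correlations": corr,
        "g_table": {
            f"g_t{d.n_t_prime}_r{d.n_r_prime}": g
            for d, g in zip(dres, g_col)
        },
        "min_tasks": {
            "target": cfg.target,
            "n_raters": cfg.target_raters,
            "n_tasks": n_min,
            "attainable": n_min is not None,
        },
    }
    with open(outdir / f"{tag}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _cubes_from_csv(cfg: PipelineConfig):
    records = read_ratings(cfg.input)
    for label, tasks in cfg.pairings:
        subset = [r for r in records if r.task_id in tasks]
        for measure in cfg.measures:
            yield f"{_slug(label)}_{measure}", build_cube(subset, measure)


def _cubes_from_simulation(cfg: PipelineConfig):
    sim = dict(cfg.simulate or {})
    preset = sim.pop("preset", None)
    sim.setdefault("seed", cfg.seed)
    for i, measure in enumerate(cfg.measures):
        kwargs = dict(sim)
        kwargs["seed"] = int(kwargs["seed"]) + i
        spec = (
            SimulationSpec.from_preset(preset, **kwargs)
            if preset
            else SimulationSpec(**kwargs)
        )
        cube = simulate_ratings(spec)
        cube = dataclasses.replace(cube, measure=measure)
        tag = f"{_slug(preset) if preset else 'simulated'}_{measure}"
        yield tag, cube


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns {tag: summary dict} for every analysis.

    All outputs are staged in a temporary directory and moved into
    ``config.output_dir`` only on success.
    """
    out_final = Path(config.output_dir)
    staging = Path(tempfile.mkdtemp(prefix="gcross_"))
    try:
        source = _cubes_from_csv(config) if config.input else _cubes_from_simulation(config)
        summaries = {}
        for tag, cube in source:
            summaries[tag] = _analyse_cube(cube, config, staging, tag)
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": {
                k: (str(v) if isinstance(v, Path) else v)
                for k, v in dataclasses.asdict(config).items()
            },
            "outputs": sorted(p.name for p in staging.iterdir()),
        }
        with open(staging / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        out_final.mkdir(parents=True, exist_ok=True)
        for p in sorted(staging.iterdir()):
            shutil.move(str(p), out_final / p.name)
        return summaries
    finally:
        shutil.rmtree(staging, ignore_errors=True)
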