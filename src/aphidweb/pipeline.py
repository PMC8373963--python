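"""End-to-end analysis pipeline: inputs -> site table -> inference reports.

Stage order mirrors the analysis chain of the study design this package
emulates: (1) read or simulate detections, plot surveys and landscape
compositions; (2) compute per-site-year ecosystem (dis)service rates,
community summaries and quantitative web metrics, joined with landscape
covers into the site table; (3) screen landscape covariates; (4) AICc
multimodel inference for the two rates; (5) piecewise SEM path analysis
with pruning and effect decomposition for each ultimate response.

All randomness flows from the single seed in the simulation config, and
all artifacts are written with deterministic float formatting, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ecofunction, selection, sem, simulate
from .io import (
    COVER_CLASSES,
    read_detections,
    read_landscape,
    read_surveys,
    write_detections,
    write_landscape,
    write_results,
    write_surveys,
)
from .webs import build_web, community_summary, web_metrics

logger = logging.getLogger("aphidweb")

__all__ = ["build_site_table", "run_pipeline", "load_config", "PipelineResult"]

#: Initial (unpruned) ES path model: the landscape candidate non-crop
#: habitat enters alongside the diversity -> generality -> richness chain.
DEFAULT_ES_EDGES = [
    ("parasitoid_diversity", "generality"),
    ("generality", "parasitoid_richness"),
    ("parasitoid_richness", "parasitism"),
    ("parasitoid_diversity", "parasitism"),
    ("generality", "parasitism"),
    ("non_crop_habitat", "parasitism"),
    ("non_crop_habitat", "generality"),
    ("non_crop_habitat", "parasitoid_richness"),
    ("non_crop_habitat", "parasitoid_diversity"),
]

#: Initial (unpruned) EDS path model.
DEFAULT_EDS_EDGES = [
    ("hyperparasitoid_richness", "hyperparasitoid_diversity"),
    ("hyperparasitoid_diversity", "vulnerability"),
    ("secondary_crops", "vulnerability"),
    ("vulnerability", "hyperparasitism"),
    ("hyperparasitoid_richness", "hyperparasitism"),
    ("hyperparasitoid_diversity", "hyperparasitism"),
    ("secondary_crops", "hyperparasitism"),
    ("non_crop_habitat", "hyperparasitism"),
]

DEFAULT_MODEL_SELECTION = [
    {"response": "parasitism", "predictors": ["generality", "vulnerability", "connectance"]},
    {"response": "hyperparasitism", "predictors": ["generality", "vulnerability", "connectance"]},
]


def build_site_table(detections, surveys, landscapes) -> pd.DataFrame:
    """Join rates, community summaries, web metrics and covers per site-year.

    Missing quantities (no aphids observed, empty web) become NaN and are
    serialized as an explicit missing token by the writers.
    """
    det_by_site: dict[tuple[str, int], list] = {}
    for r in detections:
        det_by_site.setdefault((r.site_id, r.year), []).append(r)
    sur_by_site: dict[tuple[str, int], list] = {}
    for s in surveys:
        sur_by_site.setdefault((s.site_id, s.year), []).append(s)

    rows = []
    for land in sorted(landscapes, key=lambda l: (l.site_id, l.year)):
        key = (land.site_id, land.year)
        dets = det_by_site.get(key, [])
        surs = sur_by_site.get(key, [])
        row: dict = {"site_id": land.site_id, "year": land.year}

        row["parasitism"] = ecofunction.parasitism_rate(surs) if surs else float("nan")
        row["hyperparasitism"] = (
            ecofunction.hyperparasitism_rate(dets) if dets else float("nan")
        )
        row["n_mummies_sampled"] = len(dets)
        row["n_aphids_total"] = sum(s.mummies + s.live_aphids for s in surs)

        prim_counts: dict[str, int] = {}
        hyper_counts: dict[str, int] = {}
        for d in dets:
            if d.primary_species:
                prim_counts[d.primary_species] = prim_counts.get(d.primary_species, 0) + 1
            for h in d.hyper_species:
                hyper_counts[h] = hyper_counts.get(h, 0) + 1
        for prefix, counts in (
            ("parasitoid", prim_counts),
            ("hyperparasitoid", hyper_counts),
        ):
            if counts:
                cs = community_summary(list(counts.values()))
                row[f"{prefix}_abundance"] = cs.abundance
                row[f"{prefix}_richness"] = cs.richness
                row[f"{prefix}_diversity"] = cs.shannon
            else:
                row[f"{prefix}_abundance"] = 0
                row[f"{prefix}_richness"] = 0
                row[f"{prefix}_diversity"] = 0.0

        web = build_web(dets, scope="pooled")
        if web.total > 0:
            m = web_metrics(web)
            row["generality"] = m.generality
            row["vulnerability"] = m.vulnerability
            row["connectance"] = m.connectance
        else:
            row["generality"] = float("nan")
            row["vulnerability"] = float("nan")
            row["connectance"] = float("nan")

        for c in COVER_CLASSES:
            row[c] = land.cover[c]
        row["sidi"] = land.sidi
        rows.append(row)
    return pd.DataFrame(rows)


@dataclasses.dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    site_table: pd.DataFrame
    screen: ecofunction.ScreenReport
    model_selection: dict[str, selection.MultiModelResult]
    sem_fits: dict[str, sem.SEMFit]
    truth: simulate.GroundTruth | None = None


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline config with [inputs] or [simulation] section."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    return cfg


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full chain from a config mapping (or YAML path).

    The config needs either an ``inputs`` section naming the three CSV
    files or a ``simulation`` section (keys of
    :class:`~aphidweb.simulate.SimulationConfig`); optional
    ``model_selection`` and ``sem`` sections override the default
    analyses.  When ``outdir`` is given every artifact is written there.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    if ("inputs" in config) == ("simulation" in config):
        raise ValueError("config must have exactly one of 'inputs' or 'simulation'")

    truth = None
    if "simulation" in config:
        sim_kwargs = dict(config["simulation"])
        for key in ("years", "landscape_concentration"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        sim_cfg = simulate.SimulationConfig(**sim_kwargs)
        bundle = simulate.generate_study(sim_cfg)
        detections, surveys, landscapes = bundle.detections, bundle.surveys, bundle.landscapes
        truth = bundle.truth
        logger.info(
            "simulated %d detections, %d survey rows, %d landscapes (seed %d)",
            len(detections), len(surveys), len(landscapes), sim_cfg.seed,
        )
    else:
        inputs = config["inputs"]
        detections = read_detections(inputs["detections"])
        surveys = read_surveys(inputs["surveys"])
        landscapes = read_landscape(inputs["landscape"])
        logger.info(
            "read %d detections, %d survey rows, %d landscapes",
            len(detections), len(surveys), len(landscapes),
        )

    site_table = _stage("site_table")(build_site_table)(detections, surveys, landscapes)
    screen = _stage("screen")(ecofunction.collinearity_screen)(site_table)

    ms_specs = config.get("model_selection", DEFAULT_MODEL_SELECTION)
    ms_results: dict[str, selection.MultiModelResult] = {}
    for spec in ms_specs:
        res = _stage(f"select:{spec['response']}")(selection.multimodel_inference)(
            spec["response"],
            list(spec["predictors"]),
            site_table.dropna(subset=[spec["response"], *spec["predictors"]]),
            random_effect=spec.get("random_effect"),
        )
        ms_results[spec["response"]] = res

    sem_cfg = config.get(
        "sem",
        {
            "parasitism": {"edges": DEFAULT_ES_EDGES},
            "hyperparasitism": {"edges": DEFAULT_EDS_EDGES},
        },
    )
    sem_fits: dict[str, sem.SEMFit] = {}
    for response, block in sem_cfg.items():
        diagram = sem.PathDiagram([tuple(e) for e in block["edges"]])
        cols = diagram.nodes
        data = site_table.dropna(subset=cols)[cols]
        # a constant column carries no path information; drop its node
        constant = [c for c in cols if c != response and data[c].std(ddof=1) == 0]
        if constant:
            logger.warning("sem:%s dropping zero-variance node(s) %s", response, constant)
            diagram.graph.remove_nodes_from(constant)
            cols = diagram.nodes
            data = site_table.dropna(subset=cols)[cols]
        fit = _stage(f"sem:{response}")(sem.prune_and_refit)(
            diagram, data, response, alpha=float(block.get("alpha", 0.05))
        )
        sem_fits[response] = fit

    result = PipelineResult(
        site_table=site_table,
        screen=screen,
        model_selection=ms_results,
        sem_fits=sem_fits,
        truth=truth,
    )
    if outdir is not None:
        _write_artifacts(result, detections, surveys, landscapes, Path(outdir))
    return result


def _write_artifacts(result: PipelineResult, detections, surveys, landscapes, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    write_results(result.site_table, outdir / "site_table.csv")
    write_detections(detections, outdir / "detections.csv")
    write_surveys(surveys, outdir / "surveys.csv")
    write_landscape(landscapes, outdir / "landscape.csv")
    (outdir / "screen_report.json").write_text(
        json.dumps(result.screen.to_dict(), indent=1, sort_keys=True)
    )
    (outdir / "model_selection.json").write_text(
        json.dumps(
            {resp: res.to_dict() for resp, res in sorted(result.model_selection.items())},
            indent=1,
            sort_keys=True,
        )
    )
    (outdir / "sem_report.json").write_text(
        json.dumps(
            {resp: fit.to_dict() for resp, fit in sorted(result.sem_fits.items())},
            indent=1,
            sort_keys=True,
        )
    )
    if result.truth is not None:
        result.truth.to_json(outdir / "ground_truth.json")
    logger.info("artifacts written to %s", outdir)
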