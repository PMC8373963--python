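"""Synthetic study generator with a known structural ground truth.

The generator emulates the shape of a multiyear cotton-aphid
parasitoid-hyperparasitoid field study: ~25 site-year landscape sectors,
one aphid host, a small dominance-skewed primary parasitoid community
(one species holding ~91% of individuals), a larger hyperparasitoid
community, plot surveys of live aphids and mummies, and per-mummy
molecular detections.  Every dataset is produced from a known linear
structural model over standardized site-level variables, so downstream
stages (web metrics, rates, model selection, piecewise SEM) all have a
parameter-recovery oracle.

Ground-truth structure
----------------------
Site-level latent variables follow the two reference path models
(:mod:`aphidweb.datasets`): exogenous nodes are standard normal (the
secondary-crop cover is taken from the simulated landscapes and
standardized), each endogenous node is the coefficient-weighted sum of
its parents plus a Gaussian disturbance scaled to keep unit variance, so
the configured coefficients are standardized path coefficients.  The two
latent rate indices are mapped to (0, 1) by a logistic link; realized
rates are then observed through binomial plot counts (parasitism) and
per-mummy Bernoulli indicators (hyperparasitism).

By default the generator produces *exact sample moments* (``empirical``
mode, following the convention of covariance-SEM simulators): exogenous
variables are standardized within-sample and each disturbance is
orthogonalized against its node's parents, so the sample path
coefficients equal the configured truth exactly and recovery checks are
free of Monte-Carlo error in the structural layer.  Residual variation
between configured truth and recovered coefficients then comes only from
the observation layers (logistic link, finite counts).  Set
``empirical=False`` for fully stochastic draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import EDS_PATH_COEFFICIENTS, ES_PATH_COEFFICIENTS
from .ecofunction import sidi
from .io import (
    COVER_CLASSES,
    DetectionRecord,
    LandscapeComposition,
    PlotSurvey,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "StudyBundle",
    "generate_landscapes",
    "generate_site_covariates",
    "generate_web_records",
    "generate_function_data",
    "generate_study",
]

#: Default Dirichlet concentration of the five-class composition sampler.
#: Means reflect a cotton-maize mosaic with secondary crops, non-crop
#: habitat and urban cover; the total concentration (12) gives moderate
#: between-site variation on the simplex.
DEFAULT_LANDSCAPE_CONCENTRATION = (3.0, 4.2, 1.8, 1.2, 1.8)

PRIMARY_SPECIES = ("Binodoxys communis", "Aphelinus albipodus", "Aphidius gifuensis")
HYPER_SPECIES = (
    "Syrphophagus spp.",
    "Phaenoglyphis villosa",
    "Syrphophagus eliavae",
    "Dendrocerus carpenteri",
    "Dendrocerus laticeps",
    "Asaphes spp.",
    "Pachyneuron aphidis",
)


def _default_coefficients() -> dict[tuple[str, str], float]:
    return {**ES_PATH_COEFFICIENTS, **EDS_PATH_COEFFICIENTS}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    The defaults are the study conditions emulated throughout the test
    suite: 25 site-years over three years, 3 primary and 7 hyperparasitoid
    species, 91% dominance of the top primary species, ~86 mummies
    collected per site-year, and the reference path-model coefficients as
    structural ground truth.  Rate links: the parasitism index maps to a
    rate with baseline 0.15 (moderate aphid biological control) and
    logit-scale 0.4; the hyperparasitism index maps with baseline 0.43
    (the overall hyperparasitoid share of detections in this system) and
    logit-scale 1.0, giving between-site rate spreads large relative to
    counting noise.
    """

    n_sites: int = 25
    years: tuple[int, ...] = (2014, 2015, 2016)
    seed: int = 0
    n_primary: int = 3
    n_hyper: int = 7
    primary_dominance: float = 0.91
    landscape_concentration: tuple[float, ...] = DEFAULT_LANDSCAPE_CONCENTRATION
    structural_coefficients: dict = field(default_factory=_default_coefficients)
    noise_sd: float = 1.0
    mummies_per_site: int = 86
    aphids_per_plot: float = 800.0
    n_plots: int = 3
    n_rounds: int = 3
    es_base_rate: float = 0.15
    es_logit_scale: float = 0.4
    eds_base_rate: float = 0.43
    eds_logit_scale: float = 1.0
    empirical: bool = True

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise ValueError("n_sites must be at least 3")
        if not (0.0 <= self.primary_dominance <= 1.0):
            raise ValueError("primary_dominance must lie in [0, 1]")
        for p in (self.es_base_rate, self.eds_base_rate):
            if not (0.0 < p < 1.0):
                raise ValueError("baseline rates must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if any(a <= 0 for a in self.landscape_concentration):
            raise ValueError("landscape concentrations must be positive")
        if len(self.landscape_concentration) != len(COVER_CLASSES):
            raise ValueError(
                f"need {len(COVER_CLASSES)} landscape concentrations, "
                f"got {len(self.landscape_concentration)}"
            )
        g = nx.DiGraph(list(self.structural_coefficients))
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("structural coefficient graph must be acyclic")

    def site_ids(self) -> list[tuple[str, int]]:
        """(site_id, year) labels: sites are spread over the study years."""
        out = []
        for i in range(self.n_sites):
            year = self.years[i % len(self.years)]
            out.append((f"S{i + 1:02d}", int(year)))
        return out


@dataclass
class GroundTruth:
    """Latent site-level variables and the coefficients that produced them."""

    covariates: pd.DataFrame
    coefficients: dict
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "coefficients": {f"{u}->{v}": b for (u, v), b in self.coefficients.items()},
            "covariates": self.covariates.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class StudyBundle:
    """Complete generated input set plus its ground truth."""

    detections: list[DetectionRecord]
    surveys: list[PlotSurvey]
    landscapes: list[LandscapeComposition]
    truth: GroundTruth


def _streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    """One independent random stream per generator, split from the master seed."""
    ss = np.random.SeedSequence(config.seed)
    names = ("landscape", "latent", "web", "survey")
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def generate_landscapes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[LandscapeComposition]:
    """Sample one five-class cover composition per site-year.

    Compositions are Dirichlet draws (independent Gamma draws normalized
    on the simplex); SIDI is computed from each composition.
    """
    rng = rng if rng is not None else _streams(config)["landscape"]
    alpha = np.asarray(config.landscape_concentration, dtype=float)
    out = []
    for site_id, year in config.site_ids():
        p = rng.dirichlet(alpha)
        p = p / p.sum()  # guard against accumulated rounding
        cover = dict(zip(COVER_CLASSES, (float(v) for v in p)))
        out.append(
            LandscapeComposition(
                site_id=site_id, year=year, cover=cover, sidi=sidi(list(cover.values()))
            )
        )
    return out


def _exact_standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant draw")
    return (x - x.mean()) / sd


def _orthogonalize(e: np.ndarray, parents: np.ndarray) -> np.ndarray:
    """Residualize e on [1, parents] and rescale to unit sample SD."""
    X = np.column_stack([np.ones(len(e)), parents])
    beta, *_ = np.linalg.lstsq(X, e, rcond=None)
    resid = e - X @ beta
    return resid / resid.std(ddof=1)


def generate_site_covariates(
    config: SimulationConfig,
    landscapes: list[LandscapeComposition],
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Propagate the structural model to per-site latent variables.

    Exogenous nodes are standard normal except ``secondary_crops``, which
    is the standardized secondary-crop cover of the simulated landscapes.
    Each endogenous node is the coefficient-weighted sum of its parents
    plus a disturbance scaled by ``noise_sd * sqrt(1 - Var(predictor))``,
    which at the default ``noise_sd = 1`` keeps every node at unit
    variance so the configured coefficients are standardized path
    coefficients.  The latent rate indices are mapped to rates through
    the logistic links described in :class:`SimulationConfig`.
    """
    rng = rng if rng is not None else _streams(config)["latent"]
    n = len(landscapes)
    graph = nx.DiGraph(list(config.structural_coefficients))
    values: dict[str, np.ndarray] = {}

    sc_raw = np.array([l.cover["secondary_crops"] for l in landscapes], dtype=float)
    order = list(nx.lexicographical_topological_sort(graph))
    for node in order:
        parents = sorted(graph.predecessors(node))
        if not parents:
            if node == "secondary_crops":
                x = _exact_standardize(sc_raw) if config.empirical else (
                    (sc_raw - sc_raw.mean()) / sc_raw.std(ddof=1)
                )
            else:
                x = rng.standard_normal(n)
                if config.empirical:
                    x = _exact_standardize(x)
            values[node] = x
            continue
        betas = np.array([config.structural_coefficients[(p, node)] for p in parents])
        P = np.column_stack([values[p] for p in parents])
        pred = P @ betas
        var_pred = float(pred.var(ddof=1))
        e = rng.standard_normal(n)
        if config.empirical:
            e = _orthogonalize(e, P)
        # disturbance variance floored at 1% so generation stays defined for
        # very small site counts, where sample predictor variance can
        # transiently exceed its population value of < 1
        disturbance_sd = config.noise_sd * np.sqrt(max(1.0 - var_pred, 0.01))
        values[node] = pred + disturbance_sd * e

    def _logistic(base: float, scale: float, z: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(np.log(base / (1 - base)) + scale * z)))

    df = pd.DataFrame(
        {
            "site_id": [l.site_id for l in landscapes],
            "year": [l.year for l in landscapes],
            **{node: values[node] for node in sorted(values)},
        }
    )
    df["es_rate"] = _logistic(config.es_base_rate, config.es_logit_scale, values["parasitism"])
    df["eds_rate"] = _logistic(
        config.eds_base_rate, config.eds_logit_scale, values["hyperparasitism"]
    )
    return GroundTruth(
        covariates=df, coefficients=dict(config.structural_coefficients), seed=config.seed
    )


def _hyper_weights(config: SimulationConfig, hyper_diversity: float) -> np.ndarray:
    """Site-specific hyperparasitoid multinomial with entropy tied to diversity.

    Base weights decay geometrically (ratio 0.6, putting ~40% of
    detections on the top species as in this system); the decay is
    tempered by the latent hyperparasitoid diversity of the site so that
    realized web vulnerability varies between sites.
    """
    ranks = np.arange(config.n_hyper, dtype=float)
    exponent = np.exp(-0.5 * hyper_diversity)
    w = 0.6 ** (ranks * exponent)
    return w / w.sum()


def _primary_probs(config: SimulationConfig, parasitoid_diversity: float) -> np.ndarray:
    """Primary parasitoid multinomial: fixed dominance, diversity-tempered tail."""
    d = config.primary_dominance
    k = config.n_primary
    if k == 1:
        return np.array([1.0])
    ranks = np.arange(k - 1, dtype=float)
    tail = 0.5 ** (ranks * np.exp(-0.5 * parasitoid_diversity))
    tail = (1.0 - d) * tail / tail.sum()
    return np.concatenate([[d], tail])


def generate_web_records(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> list[DetectionRecord]:
    """Draw per-mummy detection records for every site-year.

    Each site-year yields ``mummies_per_site`` mummies.  The primary
    parasitoid follows a dominance-skewed multinomial; each mummy is
    hyperparasitized with the site's latent hyperparasitism rate, and a
    hyperparasitized mummy carries exactly one hyperparasitoid drawn from
    the site-specific multinomial.  Per-site substreams keep earlier
    sites' draws stable when sites are added.
    """
    if rng is None:
        rng = _streams(config)["web"]
    if config.n_hyper == 0 and np.any(truth.covariates["eds_rate"].to_numpy() > 0):
        raise ValueError("n_hyper is 0 but hyperparasitism rates are positive")
    site_rngs = rng.spawn(len(truth.covariates))
    primaries = list(PRIMARY_SPECIES[: config.n_primary]) + [
        f"Primary sp. {j + 1}" for j in range(len(PRIMARY_SPECIES), config.n_primary)
    ]
    hypers = list(HYPER_SPECIES[: config.n_hyper]) + [
        f"Hyper sp. {j + 1}" for j in range(len(HYPER_SPECIES), config.n_hyper)
    ]
    records: list[DetectionRecord] = []
    for (_, row), site_rng in zip(truth.covariates.iterrows(), site_rngs):
        p_primary = _primary_probs(config, float(row["parasitoid_diversity"]))
        p_hyper = _hyper_weights(config, float(row["hyperparasitoid_diversity"]))
        eds = float(row["eds_rate"])
        for m in range(config.mummies_per_site):
            primary = primaries[site_rng.choice(config.n_primary, p=p_primary)]
            hyper: tuple[str, ...] = ()
            if site_rng.random() < eds:
                hyper = (hypers[site_rng.choice(config.n_hyper, p=p_hyper)],)
            records.append(
                DetectionRecord(
                    site_id=str(row["site_id"]),
                    year=int(row["year"]),
                    sample_id=f"{row['site_id']}-{row['year']}-M{m + 1:04d}",
                    primary_species=primary,
                    hyper_species=hyper,
                )
            )
    return records


def generate_function_data(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> list[PlotSurvey]:
    """Draw plot surveys whose pooled counts estimate the latent ES rate.

    Per plot and round the total aphid load is Poisson and the mummy
    count binomial with the site's latent parasitism rate, so the pooled
    realized rate converges to the latent rate as counts grow.
    """
    if rng is None:
        rng = _streams(config)["survey"]
    site_rngs = rng.spawn(len(truth.covariates))
    surveys: list[PlotSurvey] = []
    for (_, row), site_rng in zip(truth.covariates.iterrows(), site_rngs):
        es = float(row["es_rate"])
        for plot in range(1, config.n_plots + 1):
            for rnd in range(1, config.n_rounds + 1):
                total = int(site_rng.poisson(config.aphids_per_plot))
                mummies = int(site_rng.binomial(total, es)) if total else 0
                surveys.append(
                    PlotSurvey(
                        site_id=str(row["site_id"]),
                        year=int(row["year"]),
                        plot_id=f"P{plot}",
                        round=rnd,
                        live_aphids=total - mummies,
                        mummies=mummies,
                    )
                )
    return surveys


def structural_recovery_table(bundle: StudyBundle) -> pd.DataFrame:
    """Site table for parameter-recovery checks.

    Joins the ground-truth latent covariates with the *observed* rates:
    the pooled parasitism rate computed from the generated plot surveys
    and the hyperparasitism rate computed from the generated detection
    records, both via the package's own rate estimators.  Fitting the
    reference path models to this table recovers the configured
    structural coefficients up to the observation layers.
    """
    from .ecofunction import hyperparasitism_rate, parasitism_rate

    cov = bundle.truth.covariates.drop(columns=["parasitism", "hyperparasitism"])
    sur_by_site: dict[tuple[str, int], list] = {}
    for s in bundle.surveys:
        sur_by_site.setdefault((s.site_id, s.year), []).append(s)
    det_by_site: dict[tuple[str, int], list] = {}
    for d in bundle.detections:
        det_by_site.setdefault((d.site_id, d.year), []).append(d)
    rates = []
    for site_id, year in zip(cov["site_id"], cov["year"]):
        surs = sur_by_site.get((site_id, year), [])
        dets = det_by_site.get((site_id, year), [])
        rates.append(
            {
                "site_id": site_id,
                "year": year,
                "parasitism": parasitism_rate(surs),
                "hyperparasitism": hyperparasitism_rate(dets),
            }
        )
    return cov.merge(pd.DataFrame(rates), on=["site_id", "year"])


def generate_study(config: SimulationConfig) -> StudyBundle:
    """Generate a complete, internally consistent study input bundle.

    The bundle's tables use exactly the CSV schemas the package readers
    accept; the ground truth (latent covariates and coefficients) is
    returned alongside for recovery tests.
    """
    streams = _streams(config)
    landscapes = generate_landscapes(config, streams["landscape"])
    truth = generate_site_covariates(config, landscapes, streams["latent"])
    detections = generate_web_records(config, truth, streams["web"])
    surveys = generate_function_data(config, truth, streams["survey"])
    return StudyBundle(
        detections=detections, surveys=surveys, landscapes=landscapes, truth=truth
    )
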