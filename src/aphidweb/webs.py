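"""Quantitative bipartite food webs and weighted network metrics.

A :class:`QuantitativeWeb` stores the interaction matrix ``b`` of a
resource-consumer web (here: primary parasitoids as the lower trophic
level, hyperparasitoids as the upper level).  Entry ``b[i, k]`` counts
individuals of lower species *i* attacked by upper species *k*.  From the
marginal interaction distributions the module derives the weighted
(quantitative) versions of the classical web descriptors:

* **generality** ``Gq`` -- interaction-weighted mean effective number of
  resource species per consumer,
* **vulnerability** ``Vq`` -- interaction-weighted mean effective number of
  consumer species per resource,
* **connectance** ``Cq`` -- quantitative linkage density divided by the
  number of species acting in the web.

"Effective number" is the base-2 exponential of the Shannon entropy
(base 2) of a taxon's interaction frequencies, so a consumer splitting its
attacks evenly over two hosts counts two effective hosts, while one with a
strongly skewed diet counts closer to one.

The module also provides Shannon diversity (natural log) and the
abundance/richness/diversity community summary used for the parasitoid and
hyperparasitoid communities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .io import DetectionRecord

__all__ = [
    "QuantitativeWeb",
    "WebMetrics",
    "CommunitySummary",
    "WebBuildDiagnostics",
    "shannon_diversity",
    "community_summary",
    "build_web",
    "taxon_entropies",
    "web_metrics",
]


def shannon_diversity(counts: Sequence[float] | np.ndarray) -> float:
    """Shannon diversity H' = -sum p_i ln p_i over species with positive counts.

    Zero counts are ignored; natural logarithm.  Raises ``ValueError`` for
    negative or all-zero inputs.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or np.all(c == 0):
        raise ValueError("Shannon diversity undefined for empty or all-zero counts")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    p = c[c > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


@dataclass(frozen=True)
class CommunitySummary:
    """Abundance, species richness and Shannon diversity of one community."""

    abundance: int
    richness: int
    shannon: float

    def __post_init__(self) -> None:
        if self.richness > self.abundance:
            raise ValueError("richness cannot exceed abundance")


def community_summary(counts: Sequence[float] | np.ndarray) -> CommunitySummary:
    """Summarise a vector of per-species counts.

    Abundance is the total count, richness the number of species with a
    positive count, and H' the Shannon diversity (0 for a single species).
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if c.size == 0 or np.all(c == 0):
        raise ValueError("community summary undefined for all-zero counts")
    richness = int((c > 0).sum())
    h = 0.0 if richness <= 1 else shannon_diversity(c)
    return CommunitySummary(abundance=int(round(c.sum())), richness=richness, shannon=h)


@dataclass
class WebBuildDiagnostics:
    """Bookkeeping from web assembly.

    ``n_orphan_hyper`` counts mummies with a hyperparasitoid detection but
    no identified primary parasitoid: they cannot be placed in the
    resource-consumer matrix (the resource is unknown) and are excluded
    from the web, though they still contribute to hyperparasitoid
    community abundance elsewhere.
    """

    n_records: int = 0
    n_links: int = 0
    n_orphan_hyper: int = 0
    orphan_sample_ids: list = field(default_factory=list)


@dataclass
class QuantitativeWeb:
    """Weighted lower x upper interaction matrix with labelled margins.

    Rows are resources (primary parasitoids), columns are consumers
    (hyperparasitoids).  ``b[i, k]`` is the number of individuals of lower
    species *i* attacked by upper species *k*.
    """

    lower_species: list[str]
    upper_species: list[str]
    b: np.ndarray
    diagnostics: WebBuildDiagnostics = field(default_factory=WebBuildDiagnostics)

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        if self.b.shape != (len(self.lower_species), len(self.upper_species)):
            raise ValueError(
                f"matrix shape {self.b.shape} does not match species lists "
                f"({len(self.lower_species)} lower, {len(self.upper_species)} upper)"
            )
        if np.any(self.b < 0):
            raise ValueError("interaction counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        """Per-resource margin: total consumers attacking each lower species."""
        return self.b.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        """Per-consumer margin: total resources attacked by each upper species."""
        return self.b.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.b.sum())

    @property
    def n_acting_species(self) -> int:
        """Species from both levels with at least one interaction."""
        return int((self.row_totals > 0).sum() + (self.col_totals > 0).sum())

    def transpose(self) -> "QuantitativeWeb":
        """Swap trophic levels (consumers become resources)."""
        return QuantitativeWeb(
            lower_species=list(self.upper_species),
            upper_species=list(self.lower_species),
            b=self.b.T.copy(),
        )

    def to_edge_list(self) -> list[tuple[str, str, int]]:
        """(lower, upper, count) triples for every realised link."""
        out = []
        for i, lo in enumerate(self.lower_species):
            for k, up in enumerate(self.upper_species):
                if self.b[i, k] > 0:
                    out.append((lo, up, int(self.b[i, k])))
        return out


@dataclass(frozen=True)
class WebMetrics:
    """Weighted generality, vulnerability and connectance of one web."""

    generality: float
    vulnerability: float
    connectance: float
    n_acting_species: int


def build_web(
    records: Iterable[DetectionRecord],
    scope: Literal["site-year", "pooled"] = "pooled",
) -> QuantitativeWeb | dict[tuple[str, int], QuantitativeWeb]:
    """Assemble quantitative primary-hyperparasitoid web(s) from detections.

    Every record with an identified primary parasitoid *i* contributes one
    interaction to ``b[i, k]`` for each hyperparasitoid entry *k* it
    carries (repeated entries count multiply).  Records without
    hyperparasitoids add no link; records carrying hyperparasitoids but no
    primary are excluded and tallied in the diagnostics.

    With ``scope="pooled"`` a single web over all records is returned;
    with ``scope="site-year"`` a dict keyed by ``(site_id, year)``.
    """
    records = list(records)
    if scope == "site-year":
        groups: dict[tuple[str, int], list[DetectionRecord]] = {}
        for r in records:
            groups.setdefault((r.site_id, r.year), []).append(r)
        return {key: build_web(recs, scope="pooled") for key, recs in sorted(groups.items())}

    diag = WebBuildDiagnostics(n_records=len(records))
    lower: list[str] = []
    upper: list[str] = []
    counts: dict[tuple[str, str], int] = {}
    for r in records:
        if not r.hyper_species:
            continue
        if r.primary_species is None:
            diag.n_orphan_hyper += 1
            diag.orphan_sample_ids.append(r.sample_id)
            continue
        if r.primary_species not in lower:
            lower.append(r.primary_species)
        for h in r.hyper_species:
            if h not in upper:
                upper.append(h)
            counts[(r.primary_species, h)] = counts.get((r.primary_species, h), 0) + 1
            diag.n_links += 1

    lower = sorted(lower)
    upper = sorted(upper)
    b = np.zeros((len(lower), len(upper)))
    for (lo, up), n in counts.items():
        b[lower.index(lo), upper.index(up)] = n
    return QuantitativeWeb(lower_species=lower, upper_species=upper, b=b, diagnostics=diag)


def _effective_numbers(b: np.ndarray, axis: int) -> np.ndarray:
    """Effective partner numbers 2**H along one axis of the matrix.

    ``axis=0`` collapses rows, giving per-consumer (column) values;
    ``axis=1`` gives per-resource (row) values.  Taxa with a zero margin
    get 0 (they do not act in the web); 0*log0 is taken as 0.
    """
    margins = b.sum(axis=axis)
    out = np.zeros_like(margins, dtype=float)
    for k in np.nonzero(margins > 0)[0]:
        dist = np.take(b, k, axis=1 - axis)
        p = dist[dist > 0] / margins[k]
        h = float(-(p * np.log2(p)).sum())
        out[k] = 2.0**h
    return out


def taxon_entropies(web: QuantitativeWeb) -> dict[str, np.ndarray]:
    """Per-taxon interaction entropies and their effective numbers.

    Returns a dict with

    * ``H_N`` / ``n_N``: per-consumer entropy of the resource distribution
      in its column, and effective number of resource (host) species,
    * ``H_P`` / ``n_P``: per-resource entropy of the consumer distribution
      in its row, and effective number of consumer species.

    A taxon with a zero margin has entropy 0 and effective number 0.
    """
    n_N = _effective_numbers(web.b, axis=0)
    n_P = _effective_numbers(web.b, axis=1)
    with np.errstate(divide="ignore"):
        H_N = np.where(n_N > 0, np.log2(np.where(n_N > 0, n_N, 1.0)), 0.0)
        H_P = np.where(n_P > 0, np.log2(np.where(n_P > 0, n_P, 1.0)), 0.0)
    return {"H_N": H_N, "n_N": n_N, "H_P": H_P, "n_P": n_P}


def web_metrics(web: QuantitativeWeb) -> WebMetrics:
    """Weighted generality Gq, vulnerability Vq and connectance Cq.

    Gq averages each consumer's effective number of host species, weighted
    by its share of all interactions; Vq does the same per resource over
    effective consumer numbers; Cq is half their sum divided by the number
    of acting species (both levels, positive margin).  Raises
    ``ValueError`` on an empty web, where the metrics are undefined.
    """
    if web.total <= 0:
        raise ValueError("web metrics undefined for an empty web")
    eff = taxon_entropies(web)
    gq = float((web.col_totals / web.total) @ eff["n_N"])
    vq = float((web.row_totals / web.total) @ eff["n_P"])
    s = web.n_acting_species
    cq = 0.5 * (gq + vq) / s
    return WebMetrics(generality=gq, vulnerability=vq, connectance=cq, n_acting_species=s)
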