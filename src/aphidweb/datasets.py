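"""Reference path models for the cotton-aphid parasitoid system.

These are the pruned, standardized piecewise-SEM path models estimated
from a three-year survey of cotton aphid (*Aphis gossypii*)
parasitoid-hyperparasitoid networks across 25 agricultural landscape
sectors in northern China.  They serve three purposes in this package:

* worked examples for the effect-decomposition arithmetic,
* ground-truth coefficients for the synthetic-data generator, so the
  whole pipeline has a parameter-recovery oracle, and
* the canonical variable names used throughout the pipeline.

The ecosystem-service (ES) model describes aphid biological control:
parasitoid Shannon diversity raises food-web generality (Gq), generality
raises parasitoid species richness, and richness in turn lowers the
parasitism rate.  The ecosystem-disservice (EDS) model describes
hyperparasitism: hyperparasitoid richness raises hyperparasitoid
diversity, diversity raises food-web vulnerability (Vq) while secondary
crop cover lowers it, and vulnerability raises the hyperparasitism rate.
"""

from __future__ import annotations

from .sem import PathDiagram

__all__ = [
    "ES_PATH_COEFFICIENTS",
    "EDS_PATH_COEFFICIENTS",
    "es_path_diagram",
    "eds_path_diagram",
]

#: Standardized path coefficients of the pruned biological-control (ES) model.
ES_PATH_COEFFICIENTS: dict[tuple[str, str], float] = {
    ("parasitoid_diversity", "generality"): 0.899,
    ("generality", "parasitoid_richness"): 0.693,
    ("parasitoid_richness", "parasitism"): -0.524,
}

#: Standardized path coefficients of the pruned hyperparasitism (EDS) model.
EDS_PATH_COEFFICIENTS: dict[tuple[str, str], float] = {
    ("hyperparasitoid_richness", "hyperparasitoid_diversity"): 0.778,
    ("hyperparasitoid_diversity", "vulnerability"): 0.824,
    ("secondary_crops", "vulnerability"): -0.449,
    ("vulnerability", "hyperparasitism"): 0.514,
}


def es_path_diagram() -> PathDiagram:
    """Pruned biological-control path model with its standardized coefficients."""
    return PathDiagram([(u, v, b) for (u, v), b in ES_PATH_COEFFICIENTS.items()])


def eds_path_diagram() -> PathDiagram:
    """Pruned hyperparasitism path model with its standardized coefficients."""
    return PathDiagram([(u, v, b) for (u, v), b in EDS_PATH_COEFFICIENTS.items()])
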