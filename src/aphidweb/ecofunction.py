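"""Ecosystem service and disservice rates, landscape diversity and the
landscape-variable screening report.

The ecosystem service (ES) here is aphid biological control measured as
the parasitism rate: the proportion of mummified aphids among all aphids
(mummies plus live aphids), pooled over plots, points and sampling rounds
of one site-year.  Pooling counts before dividing is the maximum
likelihood estimate of a common binomial proportion and avoids giving
small plots equal weight with large ones.

The disservice (EDS) is the hyperparasitism rate: the mean over sampled
mummies of a 0/1 indicator that at least one hyperparasitoid was detected
in the mummy.  Multiple hyperparasitoid detections within one mummy do
not raise its indicator above 1.

Landscape composition is summarised by Simpson's inverse diversity index
SIDI = 1 / sum(p_i^2) over the five cover classes, and screened for
collinearity with a Pearson correlation matrix plus a correlation-based
PCA of the four cover classes retained for modelling (cotton, maize,
secondary crops, non-crop habitat; SIDI and urban are set aside because
SIDI is strongly collinear with the dominant crop covers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import COVER_CLASSES, DetectionRecord, PlotSurvey

__all__ = [
    "parasitism_rate",
    "hyperparasitism_rate",
    "sidi",
    "collinearity_screen",
    "ScreenReport",
]

#: Cover classes entering the PCA of the screening report.
PCA_COVERS = ("cotton", "maize", "secondary_crops", "non_crop_habitat")


def parasitism_rate(surveys: Iterable[PlotSurvey]) -> float:
    """Pooled parasitism rate of one site-year: mummies / (mummies + live).

    Counts are pooled over all plots and sampling rounds before forming
    the proportion.  Returns NaN (with a warning) when no aphids at all
    were observed; raises ``ValueError`` on an empty survey collection.
    """
    surveys = list(surveys)
    if not surveys:
        raise ValueError("parasitism rate undefined: no survey rows")
    mummies = sum(s.mummies for s in surveys)
    live = sum(s.live_aphids for s in surveys)
    total = mummies + live
    if total == 0:
        warnings.warn("no aphids observed; parasitism rate is missing", stacklevel=2)
        return float("nan")
    return mummies / total


def hyperparasitism_rate(records: Iterable[DetectionRecord]) -> float:
    """Hyperparasitism rate: mean per-mummy 0/1 hyperparasitoid indicator.

    Raises ``ValueError`` on an empty record collection (no mummies were
    sampled, so the rate is missing rather than zero).
    """
    records = list(records)
    if not records:
        raise ValueError("hyperparasitism rate undefined: no detection records")
    return sum(1 for r in records if r.hyperparasitized) / len(records)


def sidi(proportions: Sequence[float]) -> float:
    """Simpson's inverse diversity index 1 / sum(p_i^2) of a composition.

    The proportions must sum to 1 (tolerance 1e-9).  SIDI ranges from 1
    (one class occupies everything) to the number of non-zero classes
    (perfectly even composition).
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {p.sum()!r}, not 1")
    return float(1.0 / np.square(p).sum())


@dataclass
class ScreenReport:
    """Collinearity screen of the landscape covariates.

    ``correlations`` is the Pearson matrix over the five covers plus
    SIDI; ``flagged_pairs`` lists variable pairs whose |r| exceeds the
    threshold; ``pca_variance_fractions`` and ``pca_loadings`` come from a
    correlation-matrix PCA of the retained cover set.
    """

    correlations: pd.DataFrame
    flagged_pairs: list[tuple[str, str, float]]
    threshold: float
    pca_variance_fractions: np.ndarray
    pca_loadings: pd.DataFrame
    constant_columns: list[str]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "correlations": self.correlations.round(12).to_dict(),
            "flagged_pairs": [[a, b, r] for a, b, r in self.flagged_pairs],
            "pca_variance_fractions": [float(v) for v in self.pca_variance_fractions],
            "pca_loadings": self.pca_loadings.round(12).to_dict(),
            "constant_columns": self.constant_columns,
        }


def collinearity_screen(
    site_table: pd.DataFrame,
    threshold: float = 0.7,
    pca_covers: Sequence[str] = PCA_COVERS,
) -> ScreenReport:
    """Correlation and PCA screen of the landscape covariates.

    Computes Pearson correlations among the five cover proportions plus
    SIDI, flags pairs with |r| above ``threshold``, and runs a PCA on the
    correlation matrix of ``pca_covers``.  Columns with zero variance are
    excluded from the correlation matrix and listed in the report.
    Requires at least 3 site rows.
    """
    cols = [c for c in (*COVER_CLASSES, "sidi") if c in site_table.columns]
    if len(site_table) < 3:
        raise ValueError("collinearity screen needs at least 3 sites")
    data = site_table[cols].astype(float)
    constant = [c for c in cols if data[c].nunique(dropna=True) <= 1]
    usable = [c for c in cols if c not in constant]
    corr = data[usable].corr(method="pearson")

    flagged = []
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            r = float(corr.loc[a, b])
            if abs(r) > threshold:
                flagged.append((a, b, r))

    pca_cols = [c for c in pca_covers if c in usable]
    z = (data[pca_cols] - data[pca_cols].mean()) / data[pca_cols].std(ddof=1)
    cmat = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(cmat)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    fractions = np.clip(eigval, 0, None) / len(pca_cols)
    loadings = pd.DataFrame(
        eigvec,
        index=pca_cols,
        columns=[f"PC{i + 1}" for i in range(len(pca_cols))],
    )
    return ScreenReport(
        correlations=corr,
        flagged_pairs=flagged,
        threshold=threshold,
        pca_variance_fractions=fractions,
        pca_loadings=loadings,
        constant_columns=constant,
    )
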