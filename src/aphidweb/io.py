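"""Core data types and delimited-text readers/writers.

All tabular I/O is comma-delimited UTF-8 with a required header row,
decimal points and no thousands separators, so that write/read round
trips are numerically exact.  Hyperparasitoid species detected in the
same mummy are stored in a single semicolon-delimited cell, preserving
the one-mummy-one-row semantics that the hyperparasitism rate relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DetectionRecord",
    "PlotSurvey",
    "LandscapeComposition",
    "COVER_CLASSES",
    "SchemaError",
    "read_detections",
    "write_detections",
    "read_surveys",
    "write_surveys",
    "read_landscape",
    "write_landscape",
    "read_site_table",
    "write_results",
]

#: Land-cover classes of the 1500-m landscape sectors, in canonical order.
COVER_CLASSES = ("cotton", "maize", "secondary_crops", "non_crop_habitat", "urban")

MISSING_TOKEN = "NA"


class SchemaError(ValueError):
    """An input file does not match the documented column schema."""


@dataclass(frozen=True)
class DetectionRecord:
    """One mummified aphid with its molecular species detections.

    ``primary_species`` is the primary parasitoid identified from the
    mummy (``None`` when no primary DNA was detected); ``hyper_species``
    lists every hyperparasitoid detection, possibly with repeats when the
    assay reports multiplicity.  A record with neither a primary nor any
    hyperparasitoid is invalid: such a mummy carries no detection at all.
    """

    site_id: str
    year: int
    sample_id: str
    primary_species: str | None = None
    hyper_species: tuple[str, ...] = ()
    host_species: str = "Aphis gossypii"

    def __post_init__(self) -> None:
        if self.primary_species is None and not self.hyper_species:
            raise ValueError(
                f"record {self.sample_id!r}: no primary parasitoid and no "
                "hyperparasitoid detected"
            )

    @property
    def hyperparasitized(self) -> bool:
        """Per-mummy 0/1 hyperparasitism indicator (multiplicity ignored)."""
        return len(self.hyper_species) > 0


@dataclass(frozen=True)
class PlotSurvey:
    """Counts of live aphids and parasitoid mummies on one plot visit.

    One row per (plot, sampling round); 50 cotton plants are inspected
    per plot and counts are pooled over plants.
    """

    site_id: str
    year: int
    plot_id: str
    round: int
    live_aphids: int
    mummies: int

    def __post_init__(self) -> None:
        if self.live_aphids < 0 or self.mummies < 0:
            raise ValueError(
                f"survey {self.site_id}/{self.plot_id} round {self.round}: "
                "counts must be non-negative"
            )


@dataclass(frozen=True)
class LandscapeComposition:
    """Five-class cover proportions of one site-year landscape sector.

    Proportions must sum to one; ``sidi`` is Simpson's inverse diversity
    1 / sum(p_i^2) of the composition.
    """

    site_id: str
    year: int
    cover: dict = field(default_factory=dict)
    sidi: float = float("nan")

    def __post_init__(self) -> None:
        missing = set(COVER_CLASSES) - set(self.cover)
        if missing:
            raise ValueError(f"landscape {self.site_id}: missing cover classes {sorted(missing)}")
        total = sum(self.cover[c] for c in COVER_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"landscape {self.site_id}: cover proportions sum to {total!r}, not 1"
            )


# ---------------------------------------------------------------------------
# readers / writers


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


DETECTION_COLUMNS = ("site_id", "year", "sample_id", "host_species", "primary_species", "hyper_species")


def read_detections(path: str | Path) -> list[DetectionRecord]:
    """Read per-mummy detection records from CSV.

    Species names are whitespace-trimmed with case preserved; the
    ``hyper_species`` cell holds zero or more semicolon-separated names.
    A row with neither a primary nor a hyperparasitoid detection raises a
    row-indexed ``ValueError`` naming its sample_id.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, DETECTION_COLUMNS, path)
    records: list[DetectionRecord] = []
    seen: set[tuple[str, int, str]] = set()
    for idx, row in df.iterrows():
        primary = row["primary_species"].strip() or None
        hyper = tuple(h.strip() for h in row["hyper_species"].split(";") if h.strip())
        try:
            rec = DetectionRecord(
                site_id=row["site_id"].strip(),
                year=int(row["year"]),
                sample_id=row["sample_id"].strip(),
                primary_species=primary,
                hyper_species=hyper,
                host_species=row["host_species"].strip(),
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {idx + 2}: {exc}") from exc
        key = (rec.site_id, rec.year, rec.sample_id)
        if key in seen:
            raise ValueError(f"{path} row {idx + 2}: duplicate sample_id {rec.sample_id!r}")
        seen.add(key)
        records.append(rec)
    return records


def write_detections(records: list[DetectionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "site_id": [r.site_id for r in records],
            "year": [r.year for r in records],
            "sample_id": [r.sample_id for r in records],
            "host_species": [r.host_species for r in records],
            "primary_species": [r.primary_species or "" for r in records],
            "hyper_species": [";".join(r.hyper_species) for r in records],
        }
    )
    df.to_csv(path, index=False)


SURVEY_COLUMNS = ("site_id", "year", "plot_id", "round", "live_aphids", "mummies")


def read_surveys(path: str | Path) -> list[PlotSurvey]:
    """Read plot survey counts from CSV."""
    df = pd.read_csv(path, dtype={"site_id": str, "plot_id": str})
    _require_columns(df, SURVEY_COLUMNS, path)
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                PlotSurvey(
                    site_id=str(row["site_id"]).strip(),
                    year=int(row["year"]),
                    plot_id=str(row["plot_id"]).strip(),
                    round=int(row["round"]),
                    live_aphids=int(row["live_aphids"]),
                    mummies=int(row["mummies"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {idx + 2}: {exc}") from exc
    return out


def write_surveys(surveys: list[PlotSurvey], path: str | Path) -> None:
    df = pd.DataFrame([s.__dict__ for s in surveys])
    df.to_csv(path, index=False)


LANDSCAPE_COLUMNS = ("site_id", "year") + COVER_CLASSES


def read_landscape(path: str | Path) -> list[LandscapeComposition]:
    """Read landscape cover proportions from CSV; SIDI is recomputed."""
    from .ecofunction import sidi

    df = pd.read_csv(path, dtype={"site_id": str}, float_precision="round_trip")
    _require_columns(df, LANDSCAPE_COLUMNS, path)
    out = []
    for idx, row in df.iterrows():
        cover = {c: float(row[c]) for c in COVER_CLASSES}
        try:
            out.append(
                LandscapeComposition(
                    site_id=str(row["site_id"]).strip(),
                    year=int(row["year"]),
                    cover=cover,
                    sidi=sidi([cover[c] for c in COVER_CLASSES]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {idx + 2}: {exc}") from exc
    return out


def write_landscape(landscapes: list[LandscapeComposition], path: str | Path) -> None:
    rows = []
    for l in landscapes:
        row = {"site_id": l.site_id, "year": l.year}
        row.update({c: repr(float(l.cover[c])) for c in COVER_CLASSES})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_results(site_table: pd.DataFrame, path: str | Path) -> None:
    """Write the assembled per-site-year analysis table to CSV.

    Floats are serialised with ``repr`` so a round-trip read reproduces
    values to full double precision; missing rates (for example when a
    site had no aphids at all) are written as the explicit token ``NA``.
    """
    if site_table.empty:
        raise ValueError("refusing to write an empty site table")
    out = site_table.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: MISSING_TOKEN if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False, na_rep=MISSING_TOKEN)


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Read back a site table written by :func:`write_results`."""
    df = pd.read_csv(
        path,
        dtype={"site_id": str},
        na_values=[MISSING_TOKEN],
        keep_default_na=False,
        float_precision="round_trip",
    )
    for col in df.columns:
        if col not in ("site_id",) and df[col].dtype == object:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                pass
    return df
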