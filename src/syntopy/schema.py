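"""Specimen table schema, validation, I/O and per-nest aggregation.

The unit of observation is one ant worker, either a *Crematogaster* model
(one of three species: *scutellaris*, *schmidti*, *ionia*) or a
*Camponotus lateralis* mimic.  Each worker carries 18 mean RGB channel
intensities measured on six body parts (head, pronotum, mesonotum,
propodeum, petiole, gaster), plus cephalic length (CL) and cephalic width
(CW) in micrometres.  Workers are grouped into nests, nests into
collection sites; exactly one model species occurs at each site, and a
mimic's category ("<taxon>-syntopic") is derived from that mapping rather
than stored in the file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Body parts in measurement order: head, pronotum, mesonotum, propodeum,
# petiole, gaster; channels R, G, B within each part.
BODY_PARTS: tuple[str, ...] = ("he", "pr", "me", "pp", "pe", "ga")
CHANNELS: tuple[str, ...] = ("R", "G", "B")
COLOR_COLUMNS: tuple[str, ...] = tuple(
    f"{c}_{p}" for p in BODY_PARTS for c in CHANNELS
)
SQRT_COLOR_COLUMNS: tuple[str, ...] = tuple(f"sqrt{c}" for c in COLOR_COLUMNS)

MODEL_TAXA: tuple[str, ...] = ("scutellaris", "schmidti", "ionia")
GROUPS: tuple[str, ...] = ("model", "mimic")

ID_COLUMNS: tuple[str, ...] = ("site_id", "group", "nest_id", "specimen_id")
SIZE_COLUMNS: tuple[str, ...] = ("CL", "CW")
SPECIMEN_COLUMNS: tuple[str, ...] = ID_COLUMNS + COLOR_COLUMNS + SIZE_COLUMNS

#: Site -> model-species mapping of the 18-site study design.
DEFAULT_SITE_MODEL: dict[int, str] = {
    **{s: "scutellaris" for s in (1, 2, 3, 5, 6, 7, 8)},
    **{s: "schmidti" for s in (4, 9, 10, 11, 12, 13)},
    **{s: "ionia" for s in (14, 15, 16, 17, 18)},
}


class SchemaError(ValueError):
    """A specimen table violates the schema (range, uniqueness, missing)."""


class RegistryError(KeyError):
    """A site is unknown to, or inconsistent with, the site registry."""


@dataclass(frozen=True)
class SiteRegistry:
    """Mapping from collection site to its resident model species.

    Parameters
    ----------
    site_model
        ``site_id -> taxon`` with taxon one of :data:`MODEL_TAXA`.
    coordinates
        Optional ``site_id -> (lat, lon)``; carried through for mapping
        output, never used in statistics.
    """

    site_model: dict[int, str]
    coordinates: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for site, taxon in self.site_model.items():
            if taxon not in MODEL_TAXA:
                raise RegistryError(
                    f"site {site}: unknown model taxon {taxon!r}"
                )

    @classmethod
    def default(cls) -> "SiteRegistry":
        """The 18-site fixture of the study design."""
        return cls(dict(DEFAULT_SITE_MODEL))

    @property
    def sites(self) -> list[int]:
        return sorted(self.site_model)

    def model_taxon(self, site_id: int) -> str:
        try:
            return self.site_model[site_id]
        except KeyError:
            raise RegistryError(f"site {site_id} not in registry") from None

    def category(self, group: str, site_id: int, taxon: str | None = None) -> str:
        """Category label: the taxon for models, '<taxon>-syntopic' for mimics.

        Pure function of (group, site_id, registry); mimic categories are
        never read from a file.
        """
        if group == "model":
            return taxon if taxon is not None else self.model_taxon(site_id)
        if group == "mimic":
            return f"{self.model_taxon(site_id)}-syntopic"
        raise SchemaError(f"unknown group {group!r}")

    @classmethod
    def from_csv(cls, path) -> "SiteRegistry":
        df = pd.read_csv(path)
        mapping = {
            int(r.site_id): str(r.model_taxon) for r in df.itertuples()
        }
        coords = {}
        if {"lat", "lon"} <= set(df.columns):
            coords = {
                int(r.site_id): (float(r.lat), float(r.lon))
                for r in df.itertuples()
                if np.isfinite(r.lat) and np.isfinite(r.lon)
            }
        return cls(mapping, coords)

    def to_csv(self, path) -> None:
        rows = []
        for site in self.sites:
            row = {"site_id": site, "model_taxon": self.site_model[site]}
            if site in self.coordinates:
                row["lat"], row["lon"] = self.coordinates[site]
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


def cephalic_size(CL, CW):
    """Cephalic size CS = (CL + CW) / 2, the standard ant body-size proxy.

    Accepts scalars or arrays (µm); inputs must be strictly positive.
    """
    CL = np.asarray(CL, dtype=float)
    CW = np.asarray(CW, dtype=float)
    if np.any(CL <= 0) or np.any(CW <= 0):
        raise SchemaError("CL and CW must be strictly positive")
    cs = (CL + CW) / 2.0
    return float(cs) if cs.ndim == 0 else cs


def validate_specimens(df: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` naming the first offending cell, if any."""
    missing = [c for c in SPECIMEN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    if df[list(SPECIMEN_COLUMNS)].isna().any().any():
        col = df[list(SPECIMEN_COLUMNS)].isna().any().idxmax()
        row = int(df[df[col].isna()].index[0])
        raise SchemaError(f"blank value at row {row}, column {col!r}")
    bad_group = ~df["group"].isin(GROUPS)
    if bad_group.any():
        row = int(df.index[bad_group][0])
        raise SchemaError(
            f"row {row}, column 'group': {df.loc[row, 'group']!r} "
            f"not in {GROUPS}"
        )
    for col in COLOR_COLUMNS:
        vals = df[col].to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 255)
        if bad.any():
            row = int(df.index[np.flatnonzero(bad)[0]])
            raise SchemaError(
                f"row {row}, column {col!r}: value {df.loc[row, col]} "
                "outside [0, 255]"
            )
    for col in SIZE_COLUMNS:
        vals = df[col].to_numpy(dtype=float)
        if (vals <= 0).any():
            row = int(df.index[np.flatnonzero(vals <= 0)[0]])
            raise SchemaError(
                f"row {row}, column {col!r}: value {df.loc[row, col]} "
                "must be > 0"
            )
    dup = df.duplicated(subset=["site_id", "nest_id", "specimen_id"])
    if dup.any():
        row = int(df.index[dup][0])
        raise SchemaError(
            f"row {row}: duplicate (site_id, nest_id, specimen_id)"
        )


def annotate(df: pd.DataFrame, registry: SiteRegistry) -> pd.DataFrame:
    """Attach derived columns: taxon (models keep theirs), category, CS."""
    out = df.copy()
    unknown = set(out["site_id"].astype(int)) - set(registry.site_model)
    if unknown:
        raise RegistryError(f"sites not in registry: {sorted(unknown)}")
    if "taxon" not in out.columns:
        out["taxon"] = [
            registry.model_taxon(int(s)) if g == "model" else "lateralis"
            for s, g in zip(out["site_id"], out["group"])
        ]
    out["category"] = [
        registry.category(g, int(s))
        for s, g in zip(out["site_id"], out["group"])
    ]
    out["CS"] = cephalic_size(out["CL"], out["CW"])
    return out


def read_specimens(path, registry: SiteRegistry) -> pd.DataFrame:
    """Read and validate a specimen CSV; derive categories from the registry.

    Returns the validated table with ``taxon``, ``category`` and ``CS``
    columns appended.  Any out-of-range or blank cell raises
    :class:`SchemaError` identifying row and column.
    """
    df = pd.read_csv(path, dtype={"nest_id": str, "specimen_id": str},
                     float_precision="round_trip")
    validate_specimens(df)
    df["site_id"] = df["site_id"].astype(int)
    return annotate(df, registry)


def write_specimens(df: pd.DataFrame, path) -> None:
    """Write the canonical columns (derived columns are never stored)."""
    df[list(SPECIMEN_COLUMNS)].to_csv(path, index=False)


def specimens_to_csv_bytes(df: pd.DataFrame) -> bytes:
    """Canonical CSV serialization, for checksums and determinism checks."""
    buf = io.StringIO()
    df[list(SPECIMEN_COLUMNS)].to_csv(buf, index=False)
    return buf.getvalue().encode()


def nest_means(df: pd.DataFrame) -> pd.DataFrame:
    """Per-nest means: sqrt-scale color channels and raw-scale CS.

    One row per (site_id, group, nest_id) with columns ``sqrtR_he`` …
    ``sqrtB_ga`` (means of square-rooted channels), ``CS`` (mean raw CS,
    µm) and ``n_specimens``.  Colony means are the unit for the
    syntopy/allotopy distance analyses.
    """
    if df.empty:
        cols = list(ID_COLUMNS[:3]) + ["taxon", "category"] + \
            list(SQRT_COLOR_COLUMNS) + ["CS", "n_specimens"]
        return pd.DataFrame(columns=cols)
    work = df.copy()
    if "CS" not in work.columns:
        work["CS"] = cephalic_size(work["CL"], work["CW"])
    for raw, sq in zip(COLOR_COLUMNS, SQRT_COLOR_COLUMNS):
        work[sq] = np.sqrt(work[raw].to_numpy(dtype=float))
    keys = ["site_id", "group", "nest_id"]
    carried = [c for c in ("taxon", "category") if c in work.columns]
    agg = {c: "mean" for c in SQRT_COLOR_COLUMNS}
    agg["CS"] = "mean"
    for c in carried:
        agg[c] = "first"
    out = work.groupby(keys, as_index=False).agg(agg)
    out["n_specimens"] = work.groupby(keys).size().to_numpy()
    return out
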