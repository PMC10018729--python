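"""Data model and I/O for per-site contaminant concentration tables.

The central object is the :class:`ConcentrationTable`: a long-format table
of measured environmental concentrations (MEC, ng/L) per sample and
compound, together with per-compound method detection limits (MDL) and a
censoring flag for every entry below its MDL.  Censored entries are kept
for audit but contribute zero to every downstream aggregate and to every
toxic unit.

Compounds carry a source category (traffic, human consumption,
pesticide/biocide, other) used to aggregate site profiles by probable
source; a compound with any traffic-related use resolves to the traffic
category.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date as Date
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigError,
    InsufficientData,
    SchemaError,
    UnknownCompoundError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Category",
    "SiteType",
    "CompoundRecord",
    "CompoundLibrary",
    "SampleMeta",
    "ConcentrationTable",
    "resolve_category",
    "read_concentration_table",
    "write_concentration_table",
    "read_compound_library",
    "write_compound_library",
    "read_sample_meta",
    "write_sample_meta",
    "censor_below_mdl",
    "estimate_mdl",
    "aggregate_by_category",
]

#: multiplicative factors to ng/L for the units accepted in input schemas
_UNIT_TO_NG_L = {"ng_L": 1.0, "ug_L": 1e3, "mg_L": 1e6, "g_L": 1e9}


class Category(str, Enum):
    """Probable-source category of a compound."""

    TRAFFIC = "traffic"
    HUMAN_CONSUMPTION = "human_consumption"
    PESTICIDE_BIOCIDE = "pesticide_biocide"
    OTHER = "other"


#: precedence when several use tags map to different categories;
#: any traffic use wins, then pesticide/biocide, then human consumption
_CATEGORY_PRECEDENCE = [
    Category.TRAFFIC,
    Category.PESTICIDE_BIOCIDE,
    Category.HUMAN_CONSUMPTION,
    Category.OTHER,
]


def resolve_category(candidates: Iterable[Category | str]) -> Category:
    """Resolve a set of candidate categories to a single one by precedence.

    Compounds with multiple uses including a traffic use always resolve to
    ``traffic``; the remaining precedence is
    pesticide_biocide > human_consumption > other.
    """
    cats = {Category(c) for c in candidates}
    if not cats:
        return Category.OTHER
    for cat in _CATEGORY_PRECEDENCE:
        if cat in cats:
            return cat
    return Category.OTHER  # pragma: no cover


class SiteType(str, Enum):
    ROAD = "road"
    BACKGROUND = "background"
    WWTP_INFLUENT = "wwtp_influent"
    WWTP_EFFLUENT = "wwtp_effluent"


@dataclass(frozen=True)
class CompoundRecord:
    """Identity and physico-chemical metadata of one target compound.

    ``log_kow`` is the log10 octanol-water partition coefficient used by
    the baseline-toxicity model; ``log10_solubility_mg_per_l`` is the log10
    aqueous solubility in mg/L used by the solubility cap.  Either may be
    absent (``None``).
    """

    compound_id: str
    name: str = ""
    category: Category = Category.OTHER
    uses: tuple[str, ...] = ()
    log_kow: float | None = None
    log10_solubility_mg_per_l: float | None = None

    def __post_init__(self):
        if not self.compound_id:
            raise ValidationError("compound_id must be a non-empty string")
        object.__setattr__(self, "category", Category(self.category))
        object.__setattr__(self, "uses", tuple(self.uses))


class CompoundLibrary:
    """Mapping of compound_id -> :class:`CompoundRecord` with unique ids."""

    def __init__(self, records: Iterable[CompoundRecord]):
        self._records: dict[str, CompoundRecord] = {}
        for rec in records:
            if rec.compound_id in self._records:
                raise ValidationError(
                    f"duplicate compound_id in library: {rec.compound_id!r}"
                )
            self._records[rec.compound_id] = rec

    def __getitem__(self, compound_id: str) -> CompoundRecord:
        return self._records[compound_id]

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._records

    def __iter__(self):
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    @property
    def compound_ids(self) -> list[str]:
        return list(self._records)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: site type, date and (for WWTP samples) flow."""

    sample_id: str
    site_type: SiteType
    date: Date | None = None
    flow_m3_per_day: float | None = None
    traffic_intensity: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "site_type", SiteType(self.site_type))
        if self.site_type in (SiteType.WWTP_INFLUENT, SiteType.WWTP_EFFLUENT):
            if self.date is None:
                raise ValidationError(
                    f"WWTP sample {self.sample_id!r} requires a date"
                )
            if self.flow_m3_per_day is None or self.flow_m3_per_day <= 0:
                raise ValidationError(
                    f"WWTP sample {self.sample_id!r} requires flow > 0"
                )


class ConcentrationTable:
    """Long-format sample x compound concentration matrix in ng/L.

    Parameters
    ----------
    data
        DataFrame with columns ``sample_id``, ``compound_id``,
        ``concentration_ng_L`` and (optionally) boolean ``censored``.
    mdl_ng_l
        Per-compound method detection limit in ng/L.  A compound may be
        absent from the mapping until :func:`censor_below_mdl` is called.
    """

    COLUMNS = ["sample_id", "compound_id", "concentration_ng_L", "censored"]

    def __init__(self, data: pd.DataFrame, mdl_ng_l: Mapping[str, float] | None = None):
        df = data.copy()
        if "censored" not in df.columns:
            df["censored"] = False
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"concentration table missing columns: {missing}")
        df = df[self.COLUMNS].reset_index(drop=True)
        df["concentration_ng_L"] = df["concentration_ng_L"].astype(float)
        df["censored"] = df["censored"].astype(bool)
        neg = df.index[df["concentration_ng_L"] < 0]
        if len(neg):
            raise ValidationError(
                f"negative concentration in rows {list(neg)}"
            )
        self.data = df
        self.mdl_ng_l: dict[str, float] = dict(mdl_ng_l or {})

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())

    @property
    def compound_ids(self) -> list[str]:
        return sorted(self.data["compound_id"].unique())

    def detected(self) -> pd.DataFrame:
        """Rows not flagged censored (the entries that enter all aggregates)."""
        return self.data[~self.data["censored"]]

    def concentration(self, sample_id: str, compound_id: str) -> float | None:
        rows = self.data[
            (self.data["sample_id"] == sample_id)
            & (self.data["compound_id"] == compound_id)
        ]
        if rows.empty:
            return None
        return float(rows["concentration_ng_L"].iloc[0])


# ---------------------------------------------------------------------------
# I/O

DEFAULT_SCHEMA = {
    "sample_id": "sample_id",
    "compound_id": "compound_id",
    "concentration": "concentration_ng_L",
    "mdl": "mdl_ng_L",
    "unit": "ng_L",
}


def read_concentration_table(path, schema: Mapping[str, str] | None = None) -> ConcentrationTable:
    """Read a long-format delimited concentration file.

    ``schema`` maps the roles ``sample_id``, ``compound_id``,
    ``concentration`` (and optionally ``mdl``) to column names and declares
    the concentration ``unit`` (default ng/L).  Rows whose concentration
    cannot be parsed as a number are rejected with a warning naming the row
    numbers; a negative concentration is a hard validation error naming the
    row.
    """
    cfg = dict(DEFAULT_SCHEMA)
    cfg.update(schema or {})
    unit = cfg.get("unit", "ng_L")
    if unit not in _UNIT_TO_NG_L:
        raise ConfigError(f"unknown concentration unit {unit!r}")
    factor = _UNIT_TO_NG_L[unit]

    raw = pd.read_csv(path, dtype=str)
    required = [cfg["sample_id"], cfg["compound_id"], cfg["concentration"]]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    conc = pd.to_numeric(raw[cfg["concentration"]], errors="coerce")
    bad = raw.index[conc.isna()]
    if len(bad):
        # data row numbers are 1-based on top of the header line
        rows = [int(i) + 2 for i in bad]
        logger.warning("%s: rejected %d unparseable rows: %s", path, len(bad), rows)
        raw = raw.drop(index=bad)
        conc = conc.drop(index=bad)
    neg = raw.index[conc < 0]
    if len(neg):
        rows = [int(i) + 2 for i in neg]
        raise ValidationError(f"{path}: negative concentration in file rows {rows}")

    df = pd.DataFrame(
        {
            "sample_id": raw[cfg["sample_id"]].astype(str),
            "compound_id": raw[cfg["compound_id"]].astype(str),
            "concentration_ng_L": conc.astype(float) * factor,
        }
    )
    mdl: dict[str, float] = {}
    mdl_col = cfg.get("mdl")
    if mdl_col and mdl_col in raw.columns:
        vals = pd.to_numeric(raw[mdl_col], errors="coerce") * factor
        for cid, v in zip(df["compound_id"], vals):
            if not math.isnan(v):
                mdl[cid] = float(v)
    return ConcentrationTable(df, mdl)


def write_concentration_table(table: ConcentrationTable, path) -> None:
    """Write the canonical CSV (columns sample_id,compound_id,concentration_ng_L[,mdl_ng_L])."""
    df = table.data[["sample_id", "compound_id", "concentration_ng_L"]].copy()
    if table.mdl_ng_l:
        df["mdl_ng_L"] = df["compound_id"].map(table.mdl_ng_l)
    df.to_csv(path, index=False)


def read_compound_library(path) -> CompoundLibrary:
    """Read a compound library CSV (empty cells mean an absent value)."""
    raw = pd.read_csv(path, dtype=str)
    required = ["compound_id", "category"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    records = []
    for _, row in raw.iterrows():
        uses = ()
        if "uses" in raw.columns and isinstance(row.get("uses"), str) and row["uses"]:
            uses = tuple(t.strip() for t in row["uses"].split(";") if t.strip())

        def _opt(col):
            v = row.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
                return None
            return float(v)

        records.append(
            CompoundRecord(
                compound_id=str(row["compound_id"]),
                name=str(row.get("name", "") or ""),
                category=Category(row["category"]),
                uses=uses,
                log_kow=_opt("log_kow"),
                log10_solubility_mg_per_l=_opt("log10_solubility_mg_L"),
            )
        )
    return CompoundLibrary(records)


def write_compound_library(library: CompoundLibrary, path) -> None:
    rows = [
        {
            "compound_id": r.compound_id,
            "name": r.name,
            "category": r.category.value,
            "uses": ";".join(r.uses),
            "log_kow": r.log_kow,
            "log10_solubility_mg_L": r.log10_solubility_mg_per_l,
        }
        for r in library
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sample_meta(path) -> dict[str, SampleMeta]:
    raw = pd.read_csv(path, dtype=str)
    required = ["sample_id", "site_type"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    out: dict[str, SampleMeta] = {}
    for _, row in raw.iterrows():
        d = row.get("date")
        date = Date.fromisoformat(d) if isinstance(d, str) and d else None
        f = row.get("flow_m3_day")
        flow = float(f) if isinstance(f, str) and f else None
        ti = row.get("traffic_intensity")
        meta = SampleMeta(
            sample_id=str(row["sample_id"]),
            site_type=SiteType(row["site_type"]),
            date=date,
            flow_m3_per_day=flow,
            traffic_intensity=ti if isinstance(ti, str) and ti else None,
        )
        out[meta.sample_id] = meta
    return out


def write_sample_meta(meta: Mapping[str, SampleMeta], path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "site_type": m.site_type.value,
            "date": m.date.isoformat() if m.date else "",
            "flow_m3_day": m.flow_m3_per_day if m.flow_m3_per_day else "",
            "traffic_intensity": m.traffic_intensity or "",
        }
        for m in meta.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Censoring and MDL estimation


def censor_below_mdl(
    table: ConcentrationTable,
    default_mdl_ng_l: float | None = None,
) -> ConcentrationTable:
    """Flag entries strictly below their compound's MDL as censored.

    A value exactly equal to the MDL counts as detected.  Censored values
    are retained for audit but excluded from every aggregate and toxic
    unit.  The operation is idempotent.  A compound without an MDL is a
    configuration error unless ``default_mdl_ng_l`` is given.
    """
    mdl = dict(table.mdl_ng_l)
    missing = [c for c in table.compound_ids if c not in mdl]
    if missing:
        if default_mdl_ng_l is None:
            raise ConfigError(
                "no MDL for compounds and no default configured: "
                + ", ".join(sorted(missing))
            )
        for c in missing:
            mdl[c] = float(default_mdl_ng_l)
    df = table.data.copy()
    limits = df["compound_id"].map(mdl).astype(float)
    df["censored"] = df["concentration_ng_L"] < limits
    return ConcentrationTable(df, mdl)


def estimate_mdl(replicates: Sequence[float], confidence: float = 0.99) -> float:
    """Method detection limit from replicate low-level injections.

    MDL = t(n-1, one-sided, confidence) x sample standard deviation, the
    US-EPA replicate procedure.  Requires at least two replicates; scales
    linearly with a common factor on the replicate values.
    """
    vals = np.asarray(replicates, dtype=float)
    if vals.size < 2:
        raise InsufficientData("estimate_mdl requires at least 2 replicates")
    if not 0 < confidence < 1:
        raise ConfigError("confidence must be in (0, 1)")
    t = stats.t.ppf(confidence, df=vals.size - 1)
    return float(t * vals.std(ddof=1))


# ---------------------------------------------------------------------------
# Category aggregation


def aggregate_by_category(
    table: ConcentrationTable,
    library: CompoundLibrary,
    meta: Mapping[str, SampleMeta] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-sample summed concentration per source category, plus detection counts.

    Only non-censored entries are summed.  Returns a dict with:

    ``category_sums``
        sample_id x category sums (ng/L), zero-filled for all four
        categories and every sample in ``meta`` (if given) or in the table.
    ``sample_detections``
        detected compound count per sample.
    ``compound_detections``
        number of samples each compound was detected in.
    """
    unknown = set(table.compound_ids) - set(library.compound_ids)
    if unknown:
        raise UnknownCompoundError(unknown)

    samples = sorted(meta) if meta is not None else table.sample_ids
    cats = [c.value for c in Category]
    det = table.detected()
    cat_of = {r.compound_id: r.category.value for r in library}

    sums = pd.DataFrame(0.0, index=pd.Index(samples, name="sample_id"), columns=cats)
    if len(det):
        grouped = (
            det.assign(category=det["compound_id"].map(cat_of))
            .groupby(["sample_id", "category"], sort=True)["concentration_ng_L"]
            .sum()
        )
        for (sid, cat), v in grouped.items():
            if sid in sums.index:
                sums.loc[sid, cat] = v

    sample_det = pd.Series(0, index=sums.index, dtype=int, name="n_detected")
    if len(det):
        counts = det.groupby("sample_id")["compound_id"].nunique()
        sample_det.update(counts)
        sample_det = sample_det.astype(int)
    compound_det = (
        det.groupby("compound_id")["sample_id"].nunique().rename("n_samples")
        if len(det)
        else pd.Series(dtype=int, name="n_samples")
    )
    return {
        "category_sums": sums,
        "sample_detections": sample_det.to_frame(),
        "compound_detections": compound_det.to_frame(),
    }
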