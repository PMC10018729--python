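"""Source attribution and removal rates for WWTP influent/effluent series.

During a snow-melt event, compounds that originate in urban runoff rise
with the plant's inlet flow, while compounds from steady sources
(household wastewater) are diluted by it.  Each influent compound is
classified by the Spearman rank correlation between its daily
concentration and the daily inlet flow: above the cutoff (default 0.5)
it is runoff-dominated, below -cutoff it is diluted from another source,
otherwise its discharge pattern is mixed.

Removal is estimated from cumulative loads over the whole melt period
(concentration x flow summed over days), which damps the effect of
fluctuating flows and residence times: removal = 1 - effluent load /
influent load, binned as >80%, 50-80%, <50%, negative, or
effluent-below-MDL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as Date
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientData, SchemaError, UndefinedRemoval, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Stream",
    "SourceClass",
    "RemovalBin",
    "WwtpSeries",
    "SourceAttribution",
    "RemovalResult",
    "spearman_flow_correlation",
    "classify_source",
    "cumulative_load",
    "removal_rate",
    "attribute_sources",
    "removal_analysis",
    "read_wwtp_series",
    "write_wwtp_series",
]

#: ng/L x m3/day = 1e3 ng/day; loads are reported in mg over the period
_NG_L_M3_TO_MG = 1e-3


class Stream(str, Enum):
    INFLUENT = "influent"
    EFFLUENT = "effluent"


class SourceClass(str, Enum):
    RUNOFF_DOMINATED = "runoff_dominated"
    DILUTED_OTHER_SOURCE = "diluted_other_source"
    MIXED = "mixed"
    UNCLASSIFIABLE = "unclassifiable"


class RemovalBin(str, Enum):
    EFFLUENT_BELOW_MDL = "effluent_below_mdl"
    HIGH = "high"        # > 80%
    MEDIUM = "medium"    # 50-80% inclusive
    LOW = "low"          # >= 0 and < 50%
    NEGATIVE = "negative"


class WwtpSeries:
    """Daily composite samples of one WWTP stream.

    ``data`` holds columns ``date``, ``flow_m3_per_day``, ``compound_id``,
    ``concentration_ng_L`` and ``censored``; dates are strictly increasing
    with one flow value per date, and all flows are positive.
    """

    COLUMNS = ["date", "flow_m3_per_day", "compound_id", "concentration_ng_L", "censored"]

    def __init__(self, data: pd.DataFrame, stream: Stream):
        df = data.copy()
        if "censored" not in df.columns:
            df["censored"] = False
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"WWTP series missing columns: {missing}")
        df = df[self.COLUMNS].reset_index(drop=True)
        df["date"] = pd.to_datetime(df["date"]).dt.date
        df["flow_m3_per_day"] = df["flow_m3_per_day"].astype(float)
        df["concentration_ng_L"] = df["concentration_ng_L"].astype(float)
        df["censored"] = df["censored"].astype(bool)
        if (df["flow_m3_per_day"] <= 0).any():
            raise ValidationError("WWTP flow must be > 0")
        if (df["concentration_ng_L"] < 0).any():
            raise ValidationError("negative concentration in WWTP series")
        flows = df.groupby("date")["flow_m3_per_day"].nunique()
        if (flows > 1).any():
            raise ValidationError("inconsistent flow values within a date")
        self.data = df.sort_values(["date", "compound_id"]).reset_index(drop=True)
        self.stream = Stream(stream)

    @property
    def dates(self) -> list[Date]:
        return sorted(self.data["date"].unique())

    @property
    def compound_ids(self) -> list[str]:
        return sorted(self.data["compound_id"].unique())

    def detected_compounds(self) -> set[str]:
        det = self.data[~self.data["censored"]]
        return set(det["compound_id"].unique())

    def restrict_dates(self, start: Date, end: Date) -> "WwtpSeries":
        mask = (self.data["date"] >= start) & (self.data["date"] <= end)
        return WwtpSeries(self.data[mask], self.stream)


@dataclass(frozen=True)
class SourceAttribution:
    compound_id: str
    rho: float | None
    n: int
    source_class: SourceClass


@dataclass(frozen=True)
class RemovalResult:
    compound_id: str
    influent_load_mg: float
    effluent_load_mg: float
    removal_rate: float
    bin: RemovalBin


def spearman_flow_correlation(series: WwtpSeries, compound_id: str) -> tuple[float, int]:
    """Spearman rho between a compound's daily concentrations and the inlet flow.

    Uses only days on which the compound was detected (not censored);
    average ranks are assigned to ties.  Requires at least three pairs.
    A concentration series with zero variance has no rank association and
    returns rho = 0.
    """
    df = series.data
    sub = df[(df["compound_id"] == compound_id) & (~df["censored"])]
    n = len(sub)
    if n < 3:
        raise InsufficientData(
            f"{compound_id}: only {n} detected (concentration, flow) pairs; need >= 3"
        )
    conc = sub["concentration_ng_L"].to_numpy()
    flow = sub["flow_m3_per_day"].to_numpy()
    if np.ptp(conc) == 0 or np.ptp(flow) == 0:
        return 0.0, n
    rho = stats.spearmanr(conc, flow).statistic
    return float(rho), n


def classify_source(rho: float, cutoff: float = 0.5) -> SourceClass:
    """Classify a flow correlation; both boundaries are strict, |rho| = cutoff is mixed."""
    if not -1.0 <= rho <= 1.0 + 1e-12:
        raise ValidationError(f"Spearman rho out of range: {rho}")
    if rho > cutoff:
        return SourceClass.RUNOFF_DOMINATED
    if rho < -cutoff:
        return SourceClass.DILUTED_OTHER_SOURCE
    return SourceClass.MIXED


def cumulative_load(series: WwtpSeries, compound_id: str) -> tuple[float, bool]:
    """Cumulative load of one compound over the series period, in mg.

    load = sum over days of concentration_d x flow_d, with censored days
    contributing zero.  Returns (load, all_censored).
    """
    df = series.data
    sub = df[df["compound_id"] == compound_id]
    if sub.empty:
        return 0.0, True
    det = sub[~sub["censored"]]
    load = float(
        (det["concentration_ng_L"] * det["flow_m3_per_day"]).sum() * _NG_L_M3_TO_MG
    )
    return load, det.empty


def removal_rate(
    influent_load: float, effluent_load: float, effluent_all_censored: bool = False
) -> RemovalResult | None:
    """Removal rate 1 - effluent/influent from cumulative loads, with its bin.

    Bins: effluent entirely below MDL; high (> 80%); medium (50-80%,
    boundaries inclusive); low (0 to < 50%); negative (apparent in-plant
    formation or release).  An influent load of zero leaves the removal
    undefined.
    """
    if influent_load <= 0:
        raise UndefinedRemoval("influent load is zero; removal undefined")
    if effluent_load < 0:
        raise ValidationError("effluent load must be >= 0")
    rate = 1.0 - effluent_load / influent_load
    if effluent_all_censored:
        b = RemovalBin.EFFLUENT_BELOW_MDL
    elif rate > 0.8:
        b = RemovalBin.HIGH
    elif rate >= 0.5:
        b = RemovalBin.MEDIUM
    elif rate >= 0.0:
        b = RemovalBin.LOW
    else:
        b = RemovalBin.NEGATIVE
    return RemovalResult(
        compound_id="",
        influent_load_mg=float(influent_load),
        effluent_load_mg=float(effluent_load),
        removal_rate=rate,
        bin=b,
    )


def attribute_sources(
    influent: WwtpSeries, cutoff: float = 0.5, min_n: int = 3
) -> list[SourceAttribution]:
    """Classify every influent compound by its flow correlation."""
    if influent.stream is not Stream.INFLUENT:
        raise ValidationError("source attribution requires the influent series")
    out = []
    for cid in influent.compound_ids:
        try:
            rho, n = spearman_flow_correlation(influent, cid)
        except InsufficientData:
            det = influent.data[
                (influent.data["compound_id"] == cid) & (~influent.data["censored"])
            ]
            out.append(SourceAttribution(cid, None, len(det), SourceClass.UNCLASSIFIABLE))
            continue
        out.append(SourceAttribution(cid, rho, n, classify_source(rho, cutoff)))
    return out


def removal_analysis(
    influent: WwtpSeries,
    effluent: WwtpSeries,
    snow_compounds: Iterable[str] | None = None,
    window: tuple[Date, Date] | None = None,
) -> tuple[list[RemovalResult], dict]:
    """Removal rates for all compounds found both in snow and in the influent.

    The compound set is the explicit intersection of the snow detections
    (if given) with the influent detections.  Influent and effluent series
    are truncated to their overlapping date window (a mismatch logs a
    warning); ``window`` restricts the period further.  Compounds with
    zero influent load are excluded and reported.
    """
    if influent.stream is not Stream.INFLUENT or effluent.stream is not Stream.EFFLUENT:
        raise ValidationError("removal analysis needs an influent and an effluent series")
    start = max(min(influent.dates), min(effluent.dates))
    end = min(max(influent.dates), max(effluent.dates))
    if start > end:
        raise ValidationError("influent and effluent date windows do not overlap")
    if window is not None:
        start, end = max(start, window[0]), min(end, window[1])
        if start > end:
            raise ValidationError("configured window does not overlap the data")
    if (start, end) != (min(influent.dates), max(influent.dates)) or (start, end) != (
        min(effluent.dates),
        max(effluent.dates),
    ):
        logger.warning("series truncated to overlap %s .. %s", start, end)
    inf = influent.restrict_dates(start, end)
    eff = effluent.restrict_dates(start, end)

    candidates = inf.detected_compounds()
    if snow_compounds is not None:
        candidates &= set(snow_compounds)
    results: list[RemovalResult] = []
    undefined: list[str] = []
    for cid in sorted(candidates):
        inf_load, _ = cumulative_load(inf, cid)
        eff_load, eff_censored = cumulative_load(eff, cid)
        try:
            res = removal_rate(inf_load, eff_load, eff_censored)
        except UndefinedRemoval:
            undefined.append(cid)
            continue
        results.append(
            RemovalResult(cid, res.influent_load_mg, res.effluent_load_mg, res.removal_rate, res.bin)
        )
    report = {
        "n_intersection": len(candidates),
        "n_removal_results": len(results),
        "undefined_influent_load": undefined,
        "window": (start, end),
    }
    return results, report


# ---------------------------------------------------------------------------
# I/O (CSV: date,stream,flow_m3_day,compound_id,concentration_ng_L[,censored])


def read_wwtp_series(path) -> dict[Stream, WwtpSeries]:
    raw = pd.read_csv(path, dtype={"compound_id": str, "stream": str})
    required = ["date", "stream", "flow_m3_day", "compound_id", "concentration_ng_L"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    out: dict[Stream, WwtpSeries] = {}
    for stream_label, sub in raw.groupby("stream"):
        stream = Stream(stream_label)
        df = pd.DataFrame(
            {
                "date": sub["date"],
                "flow_m3_per_day": sub["flow_m3_day"].astype(float),
                "compound_id": sub["compound_id"],
                "concentration_ng_L": sub["concentration_ng_L"].astype(float),
            }
        )
        if "censored" in sub.columns:
            df["censored"] = sub["censored"].astype(bool)
        out[stream] = WwtpSeries(df, stream)
    return out


def write_wwtp_series(series_by_stream: Mapping[Stream, WwtpSeries], path) -> None:
    frames = []
    for stream, series in series_by_stream.items():
        df = series.data.copy()
        frames.append(
            pd.DataFrame(
                {
                    "date": [d.isoformat() for d in df["date"]],
                    "stream": Stream(stream).value,
                    "flow_m3_day": df["flow_m3_per_day"],
                    "compound_id": df["compound_id"],
                    "concentration_ng_L": df["concentration_ng_L"],
                    "censored": df["censored"],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def attributions_to_frame(attributions: Iterable[SourceAttribution]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound_id": a.compound_id,
                "rho": a.rho,
                "n": a.n,
                "source_class": a.source_class.value,
            }
            for a in attributions
        ],
        columns=["compound_id", "rho", "n", "source_class"],
    )


def removals_to_frame(results: Iterable[RemovalResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "influent_load_mg": r.influent_load_mg,
                "effluent_load_mg": r.effluent_load_mg,
                "removal_rate": r.removal_rate,
                "bin": r.bin.value,
            }
            for r in results
        ],
        columns=["compound_id", "influent_load_mg", "effluent_load_mg", "removal_rate", "bin"],
    )
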