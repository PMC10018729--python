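"""Toxic units, mixture sums under concentration addition, and risk drivers.

A toxic unit is the ratio of a measured environmental concentration to an
acute EC50 for one organism group, TU_i = MEC_i / EC50_i (both in mg/L;
MECs are stored in ng/L so a factor 1e-6 is applied exactly once here).
Mixture risk per sample and BQE is the sum of the toxic units of all
detected compounds (TUsum, concentration addition).  Samples are
prioritised by exceedance of per-BQE chronic TUsum thresholds; risk
drivers are the compounds with the largest individual TUs, with the long
tail aggregated as "further compounds".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_data import CompoundLibrary, ConcentrationTable
from .effects import BQE, EffectDatabase, EffectRecord, Provenance, parse_bqe
from .errors import ValidationError

__all__ = [
    "NG_PER_L_TO_MG_PER_L",
    "ToxicUnit",
    "RiskProfile",
    "RiskThresholds",
    "toxic_unit",
    "tusum",
    "classify_risk",
    "top_contributors",
    "compute_risk_profiles",
]

#: exactly one unit conversion between stored MEC (ng/L) and EC50 (mg/L)
NG_PER_L_TO_MG_PER_L = 1e-6


@dataclass(frozen=True)
class ToxicUnit:
    sample_id: str
    compound_id: str
    bqe: BQE
    tu: float
    ec50_provenance: Provenance

    def __post_init__(self):
        if self.tu < 0:
            raise ValidationError("toxic unit must be >= 0")


@dataclass(frozen=True)
class RiskProfile:
    """Per-sample, per-BQE mixture risk: TUsum, ranked contributors, flags."""

    sample_id: str
    bqe: BQE
    tusum: float
    contributions: tuple[tuple[str, float], ...]
    n_compounds: int
    chronic_exceeded: bool | None = None
    acute_exceeded: bool | None = None


@dataclass(frozen=True)
class RiskThresholds:
    """Chronic and acute TUsum thresholds per BQE.

    Chronic defaults are the screening thresholds commonly used for
    prioritisation: algae 0.02, crustaceans 0.001, fish 0.01.  The acute
    default is TUsum = 1 for every BQE (exposure equal to the median
    acute effect level).
    """

    chronic: Mapping[BQE, float] = field(
        default_factory=lambda: {BQE.ALGAE: 0.02, BQE.CRUSTACEAN: 0.001, BQE.FISH: 0.01}
    )
    acute: Mapping[BQE, float] = field(
        default_factory=lambda: {bqe: 1.0 for bqe in BQE}
    )

    def __post_init__(self):
        chronic = {parse_bqe(k): float(v) for k, v in dict(self.chronic).items()}
        acute = {parse_bqe(k): float(v) for k, v in dict(self.acute).items()}
        for bqe in BQE:
            if bqe not in chronic or bqe not in acute:
                raise ValidationError(f"thresholds missing for BQE {bqe.value}")
            if chronic[bqe] <= 0 or acute[bqe] <= 0:
                raise ValidationError("thresholds must be > 0")
            if acute[bqe] < chronic[bqe]:
                raise ValidationError("acute threshold must be >= chronic threshold")
        object.__setattr__(self, "chronic", chronic)
        object.__setattr__(self, "acute", acute)


def toxic_unit(
    mec_ng_per_l: float, effect: EffectRecord, sample_id: str = ""
) -> ToxicUnit:
    """TU = MEC / EC50 with both in mg/L; zero iff the MEC is zero."""
    if mec_ng_per_l < 0:
        raise ValidationError("MEC must be >= 0")
    if not (effect.ec50_mg_per_l > 0):
        raise ValidationError("EC50 must be > 0")
    tu = (mec_ng_per_l * NG_PER_L_TO_MG_PER_L) / effect.ec50_mg_per_l
    return ToxicUnit(
        sample_id=sample_id,
        compound_id=effect.compound_id,
        bqe=effect.bqe,
        tu=tu,
        ec50_provenance=effect.provenance,
    )


def tusum(tus: Sequence[ToxicUnit]) -> RiskProfile:
    """Mixture TUsum for one sample x BQE under concentration addition.

    Summation uses compensated (exact) summation so the result is
    invariant to input order; contributions are sorted by descending TU
    with ties broken lexicographically by compound id.  The empty list
    yields TUsum = 0.
    """
    if not tus:
        return RiskProfile(sample_id="", bqe=BQE.FISH, tusum=0.0, contributions=(), n_compounds=0)
    sample_ids = {t.sample_id for t in tus}
    bqes = {t.bqe for t in tus}
    if len(sample_ids) > 1 or len(bqes) > 1:
        raise ValidationError("tusum requires toxic units of one sample and one BQE")
    contributions = tuple(
        sorted(((t.compound_id, t.tu) for t in tus), key=lambda kv: (-kv[1], kv[0]))
    )
    total = math.fsum(t.tu for t in tus)
    return RiskProfile(
        sample_id=sample_ids.pop(),
        bqe=bqes.pop(),
        tusum=total,
        contributions=contributions,
        n_compounds=len(tus),
    )


def classify_risk(profile: RiskProfile, thresholds: RiskThresholds | None = None) -> RiskProfile:
    """Set chronic/acute exceedance flags; exceedance is strict (> threshold)."""
    thresholds = thresholds or RiskThresholds()
    return replace(
        profile,
        chronic_exceeded=profile.tusum > thresholds.chronic[profile.bqe],
        acute_exceeded=profile.tusum > thresholds.acute[profile.bqe],
    )


def top_contributors(
    profile: RiskProfile, min_tu: float = 0.01
) -> tuple[list[tuple[str, float]], float]:
    """Individually named risk drivers plus the aggregated "further compounds" TU.

    Contributors with TU >= ``min_tu`` are listed; the remainder is one
    aggregate chosen so that named + further equals TUsum exactly.
    """
    named = [(cid, tu) for cid, tu in profile.contributions if tu >= min_tu]
    further = profile.tusum - math.fsum(tu for _, tu in named)
    return named, further


def compute_risk_profiles(
    table: ConcentrationTable,
    library: CompoundLibrary,
    db: EffectDatabase,
    thresholds: RiskThresholds | None = None,
    bqes: Sequence[BQE] = tuple(BQE),
) -> tuple[list[RiskProfile], pd.DataFrame, pd.DataFrame]:
    """End-to-end mixture risk for every sample x BQE in a concentration table.

    Censored entries never produce a toxic unit.  Returns the classified
    profiles, a contributions table (sample_id, bqe, compound_id, tu,
    rank) and the EC50 exclusion report.
    """
    thresholds = thresholds or RiskThresholds()
    selected, exclusions = db.build_effect_table(library, bqes)
    detected = table.detected()

    profiles: list[RiskProfile] = []
    rows = []
    for sample_id in table.sample_ids:
        sub = detected[detected["sample_id"] == sample_id]
        for bqe in bqes:
            bqe = parse_bqe(bqe)
            tus = []
            for _, row in sub.iterrows():
                eff = selected.get((row["compound_id"], bqe))
                if eff is None:
                    continue
                tus.append(toxic_unit(row["concentration_ng_L"], eff, sample_id))
            if tus:
                profile = tusum(tus)
            else:
                profile = RiskProfile(sample_id, bqe, 0.0, (), 0)
            profile = classify_risk(profile, thresholds)
            profiles.append(profile)
            for rank, (cid, tu) in enumerate(profile.contributions, start=1):
                rows.append(
                    {
                        "sample_id": sample_id,
                        "bqe": bqe.value,
                        "compound_id": cid,
                        "tu": tu,
                        "rank": rank,
                    }
                )
    contributions = pd.DataFrame(
        rows, columns=["sample_id", "bqe", "compound_id", "tu", "rank"]
    )
    return profiles, contributions, exclusions


def profiles_to_frame(profiles: Iterable[RiskProfile]) -> pd.DataFrame:
    """Flatten profiles for CSV output."""
    return pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "bqe": p.bqe.value,
                "tusum": p.tusum,
                "n_compounds": p.n_compounds,
                "chronic_exceeded": bool(p.chronic_exceeded),
                "acute_exceeded": bool(p.acute_exceeded),
            }
            for p in profiles
        ],
        columns=[
            "sample_id",
            "bqe",
            "tusum",
            "n_compounds",
            "chronic_exceeded",
            "acute_exceeded",
        ],
    )
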