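"""Synthetic scenarios with known ground truth.

Generates compound libraries, snow-site concentration tables and WWTP
influent/effluent series whose statistical structure matches what the
analysis assumes: a consistent traffic fingerprint shared by road sites
with strongly attenuated background sites, many compounds detected at
exactly one site, log-normal concentrations spanning several orders of
magnitude, and a short daily WWTP composite series in which planted
compounds are flow-driven (runoff), flow-diluted (steady other sources)
or deliberately uncorrelated with flow, each with a known true removal
rate.

Every generator is a deterministic function of its scenario (including
the seed), and every planted parameter is emitted as ground truth in a
separate structure so downstream estimators can be checked against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    Category,
    CompoundLibrary,
    CompoundRecord,
    ConcentrationTable,
    SampleMeta,
    SiteType,
)
from .effects import BQE, EffectRecord, Provenance
from .errors import NoEffectData, ValidationError
from .wwtp import Stream, WwtpSeries

__all__ = [
    "SnowScenario",
    "WwtpScenario",
    "generate_compound_library",
    "generate_snow_samples",
    "generate_wwtp_series",
]

#: experimental EC50 range (mg/L) for synthetic effect records, log-uniform;
#: spans common acute algae/daphnia/fish EC50s so that at ng/L-to-ug/L
#: concentrations ordinary compounds contribute small TUs and only the
#: planted driver reaches TU ~ 1
_EC50_RANGE_MG_L = (1e-2, 1e3)

#: id and fish EC50 (mg/L) of the optional planted high-potency risk driver,
#: modelled on a tire-wear transformation product acutely toxic to salmonids
RISK_DRIVER_ID = "RD-001"
RISK_DRIVER_FISH_EC50_MG_L = 9.5e-5


def _allocate_counts(n: int, fractions: Mapping, rng: np.random.Generator) -> list:
    """Largest-remainder allocation of n items over the keys of ``fractions``."""
    keys = list(fractions)
    total = math.fsum(float(fractions[k]) for k in keys)
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"fractions must sum to 1 (got {total})")
    raw = [n * float(fractions[k]) for k in keys]
    counts = [int(math.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # largest remainders first
    for i in range(remainder):
        counts[order[i]] += 1
    labels = [k for k, c in zip(keys, counts) for _ in range(c)]
    return [labels[i] for i in rng.permutation(len(labels))]


def generate_compound_library(
    n_compounds: int = 100,
    category_mix: Mapping[Category, float] | None = None,
    effect_data_coverage: float = 0.3,
    seed: int = 0,
    include_risk_driver: bool = False,
) -> tuple[CompoundLibrary, list[EffectRecord]]:
    """Synthetic compound library plus experimental effect records.

    ``effect_data_coverage`` is the fraction of compounds carrying
    experimental EC50 records (drawn log-uniform per BQE); the remainder
    have only a logKow and rely on baseline prediction.  All compounds get
    a logKow and a correlated log10 solubility.  With
    ``include_risk_driver`` one extra compound is appended with a single
    very low experimental fish EC50, mimicking a high-potency traffic
    transformation product.
    """
    if not 0.0 <= effect_data_coverage <= 1.0:
        raise ValidationError("effect_data_coverage must be in [0, 1]")
    mix = category_mix or {
        Category.TRAFFIC: 0.28,
        Category.HUMAN_CONSUMPTION: 0.35,
        Category.PESTICIDE_BIOCIDE: 0.17,
        Category.OTHER: 0.20,
    }
    rng = np.random.default_rng(seed)
    categories = _allocate_counts(n_compounds, {Category(k): v for k, v in mix.items()}, rng)

    records: list[CompoundRecord] = []
    effects: list[EffectRecord] = []
    width = max(3, len(str(n_compounds)))
    for i, cat in enumerate(categories):
        cid = f"C{i:0{width}d}"
        log_kow = float(np.clip(rng.normal(3.0, 1.5), -1.5, 8.5))
        log_s = float(4.0 - 0.8 * log_kow + rng.normal(0.0, 0.5))
        uses = {"traffic": ("tire_wear",), "pesticide_biocide": ("biocide",)}.get(
            Category(cat).value, ()
        )
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=f"compound-{i}",
                category=Category(cat),
                uses=uses,
                log_kow=log_kow,
                log10_solubility_mg_per_l=log_s,
            )
        )

    n_cov = int(round(effect_data_coverage * n_compounds))
    covered = set(rng.choice([r.compound_id for r in records], size=n_cov, replace=False))
    for rec in records:
        if rec.compound_id not in covered:
            continue
        for bqe in BQE:
            lo, hi = np.log10(_EC50_RANGE_MG_L[0]), np.log10(_EC50_RANGE_MG_L[1])
            for _ in range(int(rng.integers(1, 4))):
                effects.append(
                    EffectRecord(
                        compound_id=rec.compound_id,
                        bqe=bqe,
                        ec50_mg_per_l=float(10.0 ** rng.uniform(lo, hi)),
                        provenance=Provenance.EXPERIMENTAL,
                        species=f"synthetic-sp{int(rng.integers(1, 9))}",
                    )
                )

    if include_risk_driver:
        records.append(
            CompoundRecord(
                compound_id=RISK_DRIVER_ID,
                name="synthetic high-potency risk driver",
                category=Category.TRAFFIC,
                uses=("tire_wear",),
                log_kow=3.9,
                log10_solubility_mg_per_l=-1.0,
            )
        )
        effects.append(
            EffectRecord(
                compound_id=RISK_DRIVER_ID,
                bqe=BQE.FISH,
                ec50_mg_per_l=RISK_DRIVER_FISH_EC50_MG_L,
                provenance=Provenance.EXPERIMENTAL,
                species="synthetic salmonid",
            )
        )
    return CompoundLibrary(records), effects


@dataclass(frozen=True)
class SnowScenario:
    """Snow sampling campaign: road sites sharing a traffic fingerprint.

    Defaults emulate a campaign of 20 road and 3 background sites whose
    summed traffic-compound concentrations average ~118 ug/L with ~40%
    between-site spread; background sites carry the fingerprint attenuated
    by a factor far below one.  ``singleton_fraction`` of the library's
    compounds are placed at exactly one site each.
    """

    n_road_sites: int = 20
    n_background_sites: int = 3
    traffic_total_ng_l: float = 118_000.0
    sigma_site: float = 0.35        # shared lognormal site factor (traffic)
    sigma_compound: float = 0.2     # per-compound lognormal noise
    background_attenuation: float = 0.02
    singleton_fraction: float = 0.6
    sub_mdl_fraction: float = 0.1
    mdl_ng_l: float = 1.0
    risk_driver_conc_ng_l: float = 95.0
    risk_driver_dominance: float = 3.0
    risk_driver_min_tu: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.singleton_fraction <= 1.0:
            raise ValidationError("singleton_fraction must be in [0, 1]")
        if not 0.0 <= self.sub_mdl_fraction < 1.0:
            raise ValidationError("sub_mdl_fraction must be in [0, 1)")
        if self.background_attenuation < 0:
            raise ValidationError("background_attenuation must be >= 0")


def generate_snow_samples(
    scenario: SnowScenario,
    library: CompoundLibrary,
    effect_db=None,
) -> tuple[ConcentrationTable, dict[str, SampleMeta], dict]:
    """Generate a snow-site concentration table with ground truth.

    Road sites share per-traffic-compound log-normal fingerprints scaled
    by a common site factor; background sites get the attenuated
    fingerprint.  If the library contains the planted risk driver it is
    placed at every road site at ``risk_driver_conc_ng_l``; when an
    :class:`~meltrisk.effects.EffectDatabase` is supplied the driver's
    concentration is instead raised per site until its fish toxic unit
    exceeds ``risk_driver_dominance`` times the largest other fish TU at
    that site (and at least ``risk_driver_min_tu``), so the driver is the
    dominant fish-risk compound by construction.  Ground truth holds the
    true per-sample category sums, the singleton compound ids, the
    dominant fish-risk compound per road site, and the number of rows
    planted below the MDL.
    """
    rng = np.random.default_rng(scenario.seed)
    traffic_ids = sorted(
        r.compound_id
        for r in library
        if r.category is Category.TRAFFIC and r.compound_id != RISK_DRIVER_ID
    )
    if not traffic_ids:
        raise ValidationError("library has no traffic compounds for the fingerprint")
    other_ids = sorted(
        r.compound_id
        for r in library
        if r.category is not Category.TRAFFIC and r.compound_id != RISK_DRIVER_ID
    )
    has_driver = RISK_DRIVER_ID in library

    # fingerprint medians: log-uniform weights scaled to the target total
    weights = 10.0 ** rng.uniform(0.0, 2.5, size=len(traffic_ids))
    medians = weights / weights.sum() * scenario.traffic_total_ng_l

    n_singletons = int(round(scenario.singleton_fraction * len(library)))
    if n_singletons > len(other_ids):
        raise ValidationError(
            f"singleton_fraction needs {n_singletons} non-traffic compounds, "
            f"library has {len(other_ids)}"
        )
    singleton_ids = list(rng.choice(other_ids, size=n_singletons, replace=False))
    multi_ids = sorted(set(other_ids) - set(singleton_ids))

    road = [f"road-{i + 1:02d}" for i in range(scenario.n_road_sites)]
    background = [f"background-{i + 1:02d}" for i in range(scenario.n_background_sites)]
    meta = {
        s: SampleMeta(s, SiteType.ROAD, traffic_intensity="high") for s in road
    }
    meta.update({s: SampleMeta(s, SiteType.BACKGROUND) for s in background})
    all_sites = road + background

    rows: list[dict] = []
    protected: list[bool] = []  # rows never planted below MDL
    true_traffic_sum: dict[str, float] = {}
    for site in all_sites:
        atten = 1.0 if site in road else scenario.background_attenuation
        site_factor = float(np.exp(rng.normal(0.0, scenario.sigma_site)))
        total = 0.0
        for cid, med in zip(traffic_ids, medians):
            conc = (
                atten
                * site_factor
                * med
                * float(np.exp(rng.normal(0.0, scenario.sigma_compound)))
            )
            rows.append(
                {"sample_id": site, "compound_id": cid, "concentration_ng_L": conc}
            )
            protected.append(False)
            total += conc
        true_traffic_sum[site] = total

    # multi-site compounds: present at every site at moderate levels
    for cid in multi_ids:
        med = 10.0 ** rng.uniform(1.0, 2.7)  # 10 .. 500 ng/L
        for site in all_sites:
            conc = med * float(np.exp(rng.normal(0.0, 0.5)))
            rows.append(
                {"sample_id": site, "compound_id": cid, "concentration_ng_L": conc}
            )
            protected.append(False)

    # singletons: one random site each
    for cid in singleton_ids:
        site = all_sites[int(rng.integers(0, len(all_sites)))]
        conc = 10.0 ** rng.uniform(1.0, 3.0)
        rows.append({"sample_id": site, "compound_id": cid, "concentration_ng_L": conc})
        protected.append(True)

    df = pd.DataFrame(rows)
    eligible = [i for i, p in enumerate(protected) if not p]
    n_plant = int(round(scenario.sub_mdl_fraction * len(eligible)))
    plant_idx = rng.choice(eligible, size=n_plant, replace=False) if n_plant else []
    for i in plant_idx:
        df.loc[i, "concentration_ng_L"] = 0.5 * scenario.mdl_ng_l

    if has_driver:
        driver_rows = []
        ec50 = None
        if effect_db is not None:
            ec50 = effect_db.select_ec50(library[RISK_DRIVER_ID], BQE.FISH).ec50_mg_per_l
        for site in road:
            if ec50 is None:
                conc = scenario.risk_driver_conc_ng_l
            else:
                # raise the driver until it dominates the site's fish risk
                sub = df[
                    (df["sample_id"] == site)
                    & (df["concentration_ng_L"] >= scenario.mdl_ng_l)
                ]
                max_tu = 0.0
                for _, row in sub.iterrows():
                    try:
                        eff = effect_db.select_ec50(library[row["compound_id"]], BQE.FISH)
                    except NoEffectData:
                        continue
                    max_tu = max(
                        max_tu, row["concentration_ng_L"] * 1e-6 / eff.ec50_mg_per_l
                    )
                tu = max(scenario.risk_driver_min_tu, scenario.risk_driver_dominance * max_tu)
                conc = tu * ec50 * 1e6
            driver_rows.append(
                {
                    "sample_id": site,
                    "compound_id": RISK_DRIVER_ID,
                    "concentration_ng_L": conc,
                }
            )
            if conc >= scenario.mdl_ng_l:  # the driver is itself a traffic compound
                true_traffic_sum[site] += conc
        df = pd.concat([df, pd.DataFrame(driver_rows)], ignore_index=True)

    mdl = {cid: scenario.mdl_ng_l for cid in df["compound_id"].unique()}
    table = ConcentrationTable(df, mdl)
    n_below = int((df["concentration_ng_L"] < df["compound_id"].map(mdl)).sum())
    ground_truth = {
        "true_traffic_sum_ng_l": true_traffic_sum,
        "singleton_ids": sorted(singleton_ids),
        "dominant_fish_risk": {s: RISK_DRIVER_ID for s in road} if has_driver else {},
        "n_below_mdl": n_below,
        "n_planted_below_mdl": int(n_plant),
    }
    return table, meta, ground_truth


#: cycled over planted compounds to cover every removal bin, including
#: full removal (effluent below MDL) and apparent in-plant formation
_DEFAULT_REMOVAL_PALETTE = (1.0, 0.99, 0.9, 0.7, 0.6, 0.3, 0.1, -0.2)


@dataclass(frozen=True)
class WwtpScenario:
    """Daily WWTP composite series over a snow-melt week.

    The default flow series rises to a melt peak and recedes; planted
    compound sets are flow-driven (concentration proportional to flow),
    flow-diluted (proportional to 1/flow) or constructed to have a rank
    pattern nearly uncorrelated with flow.  ``noise_fraction`` is the
    noise standard deviation as a fraction of each compound's signal
    range.  ``removal_rates`` are the true per-compound removal rates; a
    rate of 1 puts the effluent below the MDL.
    """

    runoff_ids: tuple[str, ...]
    diluted_ids: tuple[str, ...]
    mixed_ids: tuple[str, ...] = ()
    removal_rates: Mapping[str, float] = field(default_factory=dict)
    n_days: int = 6
    start_date: Date = Date(2021, 2, 17)
    flow_m3_per_day: tuple[float, ...] = (18_000.0, 26_000.0, 41_000.0, 52_000.0, 35_000.0, 22_000.0)
    noise_fraction: float = 0.05
    mdl_ng_l: float = 1.0
    mixed_rho_bound: float = 0.35
    seed: int = 0

    def __post_init__(self):
        sets = [set(self.runoff_ids), set(self.diluted_ids), set(self.mixed_ids)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValidationError(
                        f"planted compound sets overlap: {sorted(sets[i] & sets[j])}"
                    )
        if len(self.flow_m3_per_day) != self.n_days:
            raise ValidationError("flow series length must equal n_days")
        if any(f <= 0 for f in self.flow_m3_per_day):
            raise ValidationError("flows must be > 0")
        if not 0.0 <= self.noise_fraction < 1.0:
            raise ValidationError("noise_fraction must be in [0, 1)")

    @classmethod
    def from_counts(
        cls,
        library: CompoundLibrary,
        n_runoff: int = 13,
        n_diluted: int = 27,
        n_mixed: int = 23,
        seed: int = 0,
        **kwargs,
    ) -> "WwtpScenario":
        """Assign planted sets from a library and default removal rates."""
        rng = np.random.default_rng(seed)
        ids = list(
            rng.choice(library.compound_ids, size=n_runoff + n_diluted + n_mixed, replace=False)
        )
        runoff = tuple(ids[:n_runoff])
        diluted = tuple(ids[n_runoff : n_runoff + n_diluted])
        mixed = tuple(ids[n_runoff + n_diluted :])
        removal = {
            cid: _DEFAULT_REMOVAL_PALETTE[i % len(_DEFAULT_REMOVAL_PALETTE)]
            for i, cid in enumerate(ids)
        }
        return cls(
            runoff_ids=runoff,
            diluted_ids=diluted,
            mixed_ids=mixed,
            removal_rates=removal,
            seed=seed,
            **kwargs,
        )


def _mixed_pattern(
    flow: np.ndarray, rng: np.random.Generator, bound: float, max_tries: int = 10_000
) -> np.ndarray:
    """Rank pattern whose Spearman correlation with ``flow`` is within +/- bound.

    Rejection sampling over permutations; at n = 6 roughly half of all
    permutations qualify at bound 0.35, so this terminates quickly.
    """
    flow_ranks = np.argsort(np.argsort(flow))
    n = len(flow)
    denom = n * (n**2 - 1)
    for _ in range(max_tries):
        perm = rng.permutation(n)
        d = perm - flow_ranks
        rho = 1.0 - 6.0 * float(d @ d) / denom
        if abs(rho) <= bound:
            return perm
    raise ValidationError("could not find a mixed rank pattern within the bound")


def generate_wwtp_series(
    scenario: WwtpScenario, library: CompoundLibrary | None = None
) -> tuple[dict[Stream, WwtpSeries], dict]:
    """Generate paired influent/effluent series with ground truth.

    Influent concentrations follow the planted flow relation; the
    effluent carries a constant concentration chosen so that its
    cumulative load equals influent load x (1 - true removal), and is
    censored on days it falls below the MDL.  Ground truth maps each
    compound to its planted source class and true removal rate.
    """
    if library is not None:
        unknown = (
            set(scenario.runoff_ids) | set(scenario.diluted_ids) | set(scenario.mixed_ids)
        ) - set(library.compound_ids)
        if unknown:
            raise ValidationError(f"planted compounds absent from library: {sorted(unknown)}")
    rng = np.random.default_rng(scenario.seed)
    flow = np.asarray(scenario.flow_m3_per_day, dtype=float)
    dates = [scenario.start_date + timedelta(days=d) for d in range(scenario.n_days)]
    mean_flow = float(flow.mean())

    influent_conc: dict[str, np.ndarray] = {}
    truth_class: dict[str, str] = {}
    for cid in scenario.runoff_ids:
        target = 10.0 ** rng.uniform(2.0, 3.5)  # mean level 100 .. ~3000 ng/L
        signal = target * flow / mean_flow
        sd = scenario.noise_fraction * float(np.ptp(signal))
        conc = np.clip(signal + rng.normal(0.0, sd, size=scenario.n_days), 0.0, None)
        influent_conc[cid] = conc
        truth_class[cid] = "runoff_dominated"
    for cid in scenario.diluted_ids:
        target = 10.0 ** rng.uniform(2.0, 3.5)
        signal = target * mean_flow / flow
        sd = scenario.noise_fraction * float(np.ptp(signal))
        conc = np.clip(signal + rng.normal(0.0, sd, size=scenario.n_days), 0.0, None)
        influent_conc[cid] = conc
        truth_class[cid] = "diluted_other_source"
    for cid in scenario.mixed_ids:
        target = 10.0 ** rng.uniform(2.0, 3.5)
        perm = _mixed_pattern(flow, rng, scenario.mixed_rho_bound)
        signal = target * (1.0 + perm.astype(float))
        sd = scenario.noise_fraction * target
        conc = np.clip(signal + rng.normal(0.0, sd, size=scenario.n_days), 0.0, None)
        influent_conc[cid] = conc
        truth_class[cid] = "mixed"

    removal = {cid: float(scenario.removal_rates.get(cid, 0.5)) for cid in influent_conc}

    inf_rows, eff_rows = [], []
    for cid, conc in influent_conc.items():
        inf_load = float((conc * flow).sum())
        eff_load = inf_load * (1.0 - removal[cid])
        eff_conc = eff_load / float(flow.sum())  # constant concentration
        for d, c, f in zip(dates, conc, flow):
            inf_rows.append(
                {
                    "date": d,
                    "flow_m3_per_day": f,
                    "compound_id": cid,
                    "concentration_ng_L": c,
                    "censored": c < scenario.mdl_ng_l,
                }
            )
            eff_rows.append(
                {
                    "date": d,
                    "flow_m3_per_day": f,
                    "compound_id": cid,
                    "concentration_ng_L": eff_conc,
                    "censored": eff_conc < scenario.mdl_ng_l,
                }
            )

    series = {
        Stream.INFLUENT: WwtpSeries(pd.DataFrame(inf_rows), Stream.INFLUENT),
        Stream.EFFLUENT: WwtpSeries(pd.DataFrame(eff_rows), Stream.EFFLUENT),
    }
    ground_truth = {
        "source_class": truth_class,
        "removal_rate": removal,
        "mdl_ng_l": scenario.mdl_ng_l,
    }
    return series, ground_truth


def ground_truth_to_frame(truth: Mapping) -> pd.DataFrame:
    """Flatten a WWTP ground-truth mapping into a sidecar table."""
    ids = sorted(truth["source_class"])
    return pd.DataFrame(
        {
            "compound_id": ids,
            "source_class": [truth["source_class"][c] for c in ids],
            "removal_rate": [truth["removal_rate"][c] for c in ids],
        }
    )
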