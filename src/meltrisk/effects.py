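"""Per-compound, per-BQE acute effect concentrations (EC50).

EC50 values for the three biological quality elements (BQEs) — algae,
crustaceans (daphnia) and fish — are selected by a fixed hierarchy:

1. experimental records, aggregated as the 5th percentile of all EC50
   values available for the compound and BQE;
2. otherwise a baseline-toxicity (narcosis-type) QSAR prediction,
   log10 EC50 [mg/L] = a * logKow + b, with per-BQE coefficients;
3. a predicted EC50 more than half a log unit above the compound's water
   solubility is replaced by the solubility, since an effect concentration
   cannot exceed saturation.

A compound with neither experimental data nor a logKow is excluded from
that BQE and listed in an exclusion report; values are never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_data import CompoundLibrary, CompoundRecord
from .errors import ConfigError, NoEffectData, NoPrediction, SchemaError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "BQE",
    "Provenance",
    "EffectRecord",
    "BaselineModel",
    "EffectDatabase",
    "percentile5_ec50",
    "predict_baseline_ec50",
    "apply_solubility_cap",
    "read_effect_records",
    "load_baseline_model",
    "default_baseline_model",
]


class BQE(str, Enum):
    """Biological quality element (organism group) used for risk evaluation."""

    ALGAE = "algae"
    CRUSTACEAN = "crustacean"
    FISH = "fish"


#: accepted aliases in input files; "daphnia" and "crustacean" are one BQE
_BQE_ALIASES = {"daphnia": BQE.CRUSTACEAN, "green_algae": BQE.ALGAE}


def parse_bqe(label: str | BQE) -> BQE:
    if isinstance(label, BQE):
        return label
    key = str(label).strip().lower()
    if key in _BQE_ALIASES:
        return _BQE_ALIASES[key]
    try:
        return BQE(key)
    except ValueError:
        raise ValidationError(f"unknown BQE label {label!r}") from None


class Provenance(str, Enum):
    EXPERIMENTAL = "experimental"
    PREDICTED = "predicted"
    SOLUBILITY_CAPPED = "solubility_capped"


@dataclass(frozen=True)
class EffectRecord:
    compound_id: str
    bqe: BQE
    ec50_mg_per_l: float
    provenance: Provenance
    species: str | None = None
    note: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "bqe", parse_bqe(self.bqe))
        object.__setattr__(self, "provenance", Provenance(self.provenance))
        if not (self.ec50_mg_per_l > 0):
            raise ValidationError(
                f"EC50 must be > 0 (got {self.ec50_mg_per_l!r} for "
                f"{self.compound_id} / {self.bqe.value})"
            )


@dataclass(frozen=True)
class BaselineModel:
    """Per-BQE linear baseline-toxicity model: log10 EC50 [mg/L] = a*logKow + b."""

    slopes: Mapping[BQE, float]
    intercepts: Mapping[BQE, float]

    def __post_init__(self):
        slopes = {parse_bqe(k): float(v) for k, v in dict(self.slopes).items()}
        intercepts = {parse_bqe(k): float(v) for k, v in dict(self.intercepts).items()}
        for bqe in BQE:
            if bqe not in slopes or bqe not in intercepts:
                raise ConfigError(f"baseline model missing coefficients for {bqe.value}")
        object.__setattr__(self, "slopes", slopes)
        object.__setattr__(self, "intercepts", intercepts)


def percentile5_ec50(values: Sequence[float]) -> float:
    """5th percentile of experimental EC50 values (mg/L).

    Uses linear interpolation between order statistics (numpy's default
    percentile convention); permutation-invariant; a single value is
    returned unchanged.  Raises :class:`NoEffectData` on an empty list so
    callers fall through to prediction.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise NoEffectData("no experimental EC50 values")
    if np.any(vals <= 0):
        raise ValidationError("EC50 values must be positive")
    return float(np.percentile(vals, 5))


def predict_baseline_ec50(log_kow: float | None, bqe: BQE, model: BaselineModel) -> float:
    """Baseline-toxicity prediction: EC50 = 10^(a*logKow + b), in mg/L."""
    if log_kow is None:
        raise NoPrediction("log Kow absent; baseline prediction impossible")
    bqe = parse_bqe(bqe)
    return float(10.0 ** (model.slopes[bqe] * float(log_kow) + model.intercepts[bqe]))


def apply_solubility_cap(
    ec50_pred_mg_per_l: float,
    log10_solubility_mg_per_l: float | None,
    tolerance_log10: float = 0.5,
) -> tuple[float, Provenance]:
    """Replace a predicted EC50 exceeding the water solubility by the solubility.

    The cap fires when log10(EC50_pred) - log10(S) > tolerance; the half
    log unit tolerance absorbs uncertainty in the solubility estimate.  The
    capped value is never larger than the prediction, so capping can only
    raise a toxic unit (the conservative direction).  If the solubility is
    unknown the prediction is kept with a warning.
    """
    if not (ec50_pred_mg_per_l > 0):
        raise ValidationError("predicted EC50 must be > 0")
    if log10_solubility_mg_per_l is None:
        logger.warning("solubility unknown; cap not applied")
        return float(ec50_pred_mg_per_l), Provenance.PREDICTED
    if np.log10(ec50_pred_mg_per_l) > log10_solubility_mg_per_l + tolerance_log10:
        return float(10.0 ** log10_solubility_mg_per_l), Provenance.SOLUBILITY_CAPPED
    return float(ec50_pred_mg_per_l), Provenance.PREDICTED


class EffectDatabase:
    """Experimental effect records plus a baseline model, with hierarchical lookup.

    ``select_ec50`` is a deterministic, pure lookup: experimental records
    (5th-percentile aggregate) always win over prediction; prediction is
    solubility-capped.
    """

    def __init__(
        self,
        experimental: Iterable[EffectRecord] = (),
        baseline_model: BaselineModel | None = None,
        cap_tolerance_log10: float = 0.5,
    ):
        self._experimental: dict[tuple[str, BQE], list[EffectRecord]] = {}
        for rec in experimental:
            if rec.provenance is not Provenance.EXPERIMENTAL:
                raise ValidationError(
                    "EffectDatabase experimental records must have provenance=experimental"
                )
            self._experimental.setdefault((rec.compound_id, rec.bqe), []).append(rec)
        self.baseline_model = baseline_model
        self.cap_tolerance_log10 = float(cap_tolerance_log10)

    def experimental_values(self, compound_id: str, bqe: BQE) -> list[float]:
        recs = self._experimental.get((compound_id, parse_bqe(bqe)), [])
        return [r.ec50_mg_per_l for r in recs]

    def select_ec50(self, compound: CompoundRecord, bqe: BQE) -> EffectRecord:
        """Select the EC50 for one compound x BQE by the fixed hierarchy.

        Raises :class:`NoEffectData` when the compound has neither
        experimental records nor a logKow for prediction.
        """
        bqe = parse_bqe(bqe)
        values = self.experimental_values(compound.compound_id, bqe)
        if values:
            return EffectRecord(
                compound_id=compound.compound_id,
                bqe=bqe,
                ec50_mg_per_l=percentile5_ec50(values),
                provenance=Provenance.EXPERIMENTAL,
                note=f"p5 of {len(values)} experimental records",
            )
        if self.baseline_model is None:
            raise ConfigError("no baseline model configured and no experimental data")
        try:
            pred = predict_baseline_ec50(compound.log_kow, bqe, self.baseline_model)
        except NoPrediction:
            raise NoEffectData(
                f"{compound.compound_id}/{bqe.value}: no experimental data and no log Kow"
            ) from None
        ec50, prov = apply_solubility_cap(
            pred, compound.log10_solubility_mg_per_l, self.cap_tolerance_log10
        )
        return EffectRecord(
            compound_id=compound.compound_id,
            bqe=bqe,
            ec50_mg_per_l=ec50,
            provenance=prov,
        )

    def build_effect_table(
        self, library: CompoundLibrary, bqes: Sequence[BQE] = tuple(BQE)
    ) -> tuple[dict[tuple[str, BQE], EffectRecord], pd.DataFrame]:
        """Select EC50s for every compound x BQE; return the table and an exclusion report.

        The exclusion report has columns compound_id, bqe, reason.
        """
        selected: dict[tuple[str, BQE], EffectRecord] = {}
        exclusions = []
        for compound in library:
            for bqe in bqes:
                try:
                    selected[(compound.compound_id, parse_bqe(bqe))] = self.select_ec50(
                        compound, bqe
                    )
                except NoEffectData as exc:
                    exclusions.append(
                        {
                            "compound_id": compound.compound_id,
                            "bqe": parse_bqe(bqe).value,
                            "reason": str(exc),
                        }
                    )
        report = pd.DataFrame(exclusions, columns=["compound_id", "bqe", "reason"])
        return selected, report


# ---------------------------------------------------------------------------
# I/O


def read_effect_records(path) -> list[EffectRecord]:
    """Read experimental effect records (CSV: compound_id,bqe,ec50_mg_L[,species,reference])."""
    raw = pd.read_csv(path, dtype=str)
    required = ["compound_id", "bqe", "ec50_mg_L"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    records = []
    for _, row in raw.iterrows():
        species = row.get("species")
        records.append(
            EffectRecord(
                compound_id=str(row["compound_id"]),
                bqe=parse_bqe(row["bqe"]),
                ec50_mg_per_l=float(row["ec50_mg_L"]),
                provenance=Provenance.EXPERIMENTAL,
                species=species if isinstance(species, str) and species else None,
            )
        )
    return records


def write_effect_records(records: Iterable[EffectRecord], path) -> None:
    rows = [
        {
            "compound_id": r.compound_id,
            "bqe": r.bqe.value,
            "ec50_mg_L": r.ec50_mg_per_l,
            "species": r.species or "",
            "reference": r.note or "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_baseline_model(path) -> tuple[BaselineModel, float]:
    """Load per-BQE slope/intercept and cap tolerance from a YAML config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    try:
        coeffs = cfg["baseline_model"]
        slopes = {k: v["slope"] for k, v in coeffs.items()}
        intercepts = {k: v["intercept"] for k, v in coeffs.items()}
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: malformed baseline model config ({exc})") from None
    tolerance = float(cfg.get("cap_tolerance_log10", 0.5))
    return BaselineModel(slopes, intercepts), tolerance


def default_baseline_model() -> tuple[BaselineModel, float]:
    """The packaged default narcosis-type coefficients (data, not code)."""
    return load_baseline_model(Path(__file__).parent / "data" / "baseline_model.yaml")
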