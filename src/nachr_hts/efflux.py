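"""Orthogonal 86Rb+ efflux validation analytics.

The efflux assay is a direct measure of ion flux through the receptor
channel, used to confirm that primary-screen hits act on the receptor
rather than on the fluorescence readout.  Each plate carries triplicate
total-efflux controls (agonist only), triplicate non-specific controls
(fully blocked, or buffer alone), and triplicate test wells per compound.
Specific efflux is the total-minus-nonspecific difference; a compound's
percent inhibition rescales its test-well mean onto the [total, nonspecific]
window.  A compound is validated when its mean inhibition across the
(three) independent experiments exceeds 3x the spread of the no-drug
control inhibition, strictly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (DataError, FormatError, InsufficientDataError,
                     InvalidPlateError, UndefinedMetricError)
from .qc import z_prime

TEST = "TEST"
TOTAL_CONTROL = "TOTAL_CONTROL"
NONSPECIFIC_CONTROL = "NONSPECIFIC_CONTROL"
EFFLUX_ROLES = (TEST, TOTAL_CONTROL, NONSPECIFIC_CONTROL)


@dataclass
class EffluxPlate:
    """One 24-well efflux plate: per-well counts (cpm) with roles."""

    plate_id: str
    subtype: str
    experiment: str
    wells: pd.DataFrame  # columns: well, role, compound_id, cpm

    def __post_init__(self) -> None:
        required = {"well", "role", "compound_id", "cpm"}
        missing = required - set(self.wells.columns)
        if missing:
            raise FormatError(f"efflux plate missing columns {sorted(missing)}")
        bad = set(self.wells["role"]) - set(EFFLUX_ROLES)
        if bad:
            raise DataError(f"unknown efflux roles {sorted(bad)}")
        if (self.wells["cpm"] < 0).any() or not np.isfinite(self.wells["cpm"]).all():
            raise DataError("cpm values must be finite and non-negative")

    def cpm(self, role: str, compound_id: str | None = None) -> np.ndarray:
        sel = self.wells["role"] == role
        if compound_id is not None:
            sel &= self.wells["compound_id"] == compound_id
        return self.wells.loc[sel, "cpm"].to_numpy(dtype=float)

    def compound_ids(self) -> list[str]:
        return sorted(set(self.wells.loc[self.wells["role"] == TEST, "compound_id"]))

    def to_csv(self, path: str | Path) -> None:
        df = self.wells.copy()
        df.insert(0, "experiment", self.experiment)
        df.insert(0, "subtype", self.subtype)
        df.insert(0, "plate_id", self.plate_id)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EffluxPlate":
        df = pd.read_csv(path, dtype={"plate_id": str, "subtype": str,
                                      "experiment": str, "well": str,
                                      "role": str, "compound_id": str},
                         keep_default_na=False,
                     float_precision="round_trip")
        for col in ("plate_id", "subtype", "experiment"):
            if col not in df.columns:
                raise FormatError(f"efflux file missing column {col}")
        meta = {c: str(df[c].iloc[0]) for c in ("plate_id", "subtype", "experiment")}
        return cls(meta["plate_id"], meta["subtype"], meta["experiment"],
                   df[["well", "role", "compound_id", "cpm"]].copy())


def specific_efflux(total: Sequence[float], nonspecific: Sequence[float]) -> float:
    """Channel-mediated efflux: mean(total) - mean(nonspecific); must be > 0."""
    total = np.asarray(total, dtype=float)
    nonspecific = np.asarray(nonspecific, dtype=float)
    if total.size == 0 or nonspecific.size == 0:
        raise InsufficientDataError("both control series must be non-empty")
    diff = float(total.mean() - nonspecific.mean())
    if diff <= 0:
        raise InvalidPlateError(
            f"non-positive specific efflux ({diff:.3g} cpm): plate unusable")
    return diff


def efflux_pct_inhibition(test: Sequence[float], total: Sequence[float],
                          nonspecific: Sequence[float]) -> float:
    """Percent inhibition anchored on the control window.

    0% at the no-antagonist (total) control mean, 100% at the fully-blocked
    (nonspecific) control mean.  Values may fall outside [0, 100] with
    noise and are deliberately not clipped.
    """
    spec = specific_efflux(total, nonspecific)
    test = np.asarray(test, dtype=float)
    if test.size == 0:
        raise InsufficientDataError("test series must be non-empty")
    total_mean = float(np.asarray(total, dtype=float).mean())
    return 100.0 * (total_mean - test.mean()) / spec


@dataclass
class ValidationResult:
    compound_id: str
    mean_pct_inhibition: float
    sd_pct_inhibition: float
    validated: bool
    n_experiments: int


def validate_compound(compound_id: str, per_experiment_inhibition: Sequence[float],
                      control_spread: float, sd_multiplier: float = 3.0
                      ) -> ValidationResult:
    """Apply the 3x-SD validation rule.

    ``control_spread`` is the SD of no-drug control inhibition (centred at
    0% by construction); a compound validates when its mean inhibition
    across experiments strictly exceeds ``sd_multiplier * control_spread``.
    """
    vals = np.asarray(per_experiment_inhibition, dtype=float)
    if vals.size < 1:
        raise InsufficientDataError("at least one experiment required")
    if control_spread < 0:
        raise DataError("control_spread must be non-negative")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return ValidationResult(compound_id, mean, sd,
                            mean > sd_multiplier * control_spread, int(vals.size))


def efflux_z_prime(total: Sequence[float], nonspecific: Sequence[float]) -> float:
    """Z'-factor of the efflux assay from its two control sets."""
    return z_prime(total, nonspecific)


def validation_rate(validated: int, resupplied: int) -> float:
    """Percent of resupplied primary hits that validated."""
    if resupplied <= 0:
        raise UndefinedMetricError("validation rate needs resupplied > 0")
    return 100.0 * validated / resupplied


def control_inhibition_spread(plates: Sequence[EffluxPlate]) -> float:
    """SD of no-drug control inhibition, pooled across plates.

    Each total-control well, treated as if it were a test well, yields an
    inhibition value scattered around 0%; their pooled SD measures the
    assay's no-effect spread and sets the 3x-SD validation cutoff.
    """
    per_well = []
    for p in plates:
        total = p.cpm(TOTAL_CONTROL)
        nonspec = p.cpm(NONSPECIFIC_CONTROL)
        spec = specific_efflux(total, nonspec)
        per_well.extend(100.0 * (total.mean() - total) / spec)
    if len(per_well) < 2:
        raise InsufficientDataError("control spread needs >= 2 control wells")
    return float(np.std(per_well, ddof=1))


def analyze_efflux(plates: Sequence[EffluxPlate], sd_multiplier: float = 3.0
                   ) -> tuple[dict[str, ValidationResult], float, list[float]]:
    """Per-compound validation calls for one subtype's efflux experiments.

    Groups plates by experiment, computes each compound's per-experiment
    inhibition against that plate's own controls, pools the no-drug control
    spread across all plates, and applies the 3x-SD rule.  Returns
    ``(results, control_spread, per_plate_z_primes)``.
    """
    spread = control_inhibition_spread(plates)
    z_primes = [efflux_z_prime(p.cpm(TOTAL_CONTROL), p.cpm(NONSPECIFIC_CONTROL))
                for p in plates]
    per_compound: dict[str, list[float]] = {}
    for p in plates:
        total = p.cpm(TOTAL_CONTROL)
        nonspec = p.cpm(NONSPECIFIC_CONTROL)
        for cid in p.compound_ids():
            inh = efflux_pct_inhibition(p.cpm(TEST, cid), total, nonspec)
            per_compound.setdefault(cid, []).append(inh)
    results = {cid: validate_compound(cid, vals, spread, sd_multiplier)
               for cid, vals in sorted(per_compound.items())}
    return results, spread, z_primes


def validation_frame(results: Mapping[str, ValidationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "compound_id": r.compound_id,
        "mean_pct_inhibition": r.mean_pct_inhibition,
        "sd_pct_inhibition": r.sd_pct_inhibition,
        "validated": r.validated,
        "n_experiments": r.n_experiments,
    } for r in results.values()])
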