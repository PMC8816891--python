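"""Plate-level quality-control statistics and gating.

The screen is gated on three standard HTS performance statistics computed
from the in-plate controls: coefficient of variation (CV), signal-to-
background ratio (S:B), and the Z'-factor

    Z' = 1 - 3 (sd_pos + sd_zero) / |mean_pos - mean_zero|,

which folds both variability and dynamic range into a single score (1 is a
perfect assay; > 0.5 denotes an excellent one).  Default gates follow the
usual HTS guidelines: CV < 10%, S:B > 4, Z' > 0.5, all strict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, UndefinedMetricError
from .plates import Role, parse_well

if TYPE_CHECKING:  # pragma: no cover
    from .screen import NormalizedPlate

#: 1 / Phi^{-1}(3/4): scales the median absolute deviation to a Gaussian SD.
MAD_SCALE = 1.4826


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample SD (n-1 denominator) over mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("CV needs at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise UndefinedMetricError("CV undefined for zero-mean series")
    return float(x.std(ddof=1) / mean)


def signal_to_background(pos: Sequence[float], zero: Sequence[float]) -> float:
    """Ratio of positive-control to zero-control mean (background-subtracted signals)."""
    pos = np.asarray(pos, dtype=float)
    zero = np.asarray(zero, dtype=float)
    if pos.size == 0 or zero.size == 0:
        raise InsufficientDataError("S:B needs non-empty control series")
    mu_zero = zero.mean()
    if mu_zero == 0:
        raise UndefinedMetricError("S:B undefined for zero-mean background")
    return float(pos.mean() / mu_zero)


def z_prime(pos: Sequence[float], zero: Sequence[float]) -> float:
    """Z'-factor of a control pair; in (-inf, 1], 1 only for zero-variance controls."""
    pos = np.asarray(pos, dtype=float)
    zero = np.asarray(zero, dtype=float)
    if pos.size < 2 or zero.size < 2:
        raise InsufficientDataError("Z' needs at least 2 values per control series")
    mu_p, mu_z = pos.mean(), zero.mean()
    if mu_p == mu_z:
        raise UndefinedMetricError("Z' undefined when control means are equal")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + zero.std(ddof=1)) / abs(mu_p - mu_z))


def remove_control_outliers(values: Sequence[float], k: float = 3.0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Median +- k * 1.4826 * MAD outlier filter for control wells.

    Returns ``(retained_values, removed_indices)``.  Never removes more
    than 25% of the points (the most extreme are removed first); with fewer
    than 4 points, or zero MAD, nothing is removed.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        warnings.warn("fewer than 4 control values; outlier removal skipped")
        return x, np.array([], dtype=int)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x, np.array([], dtype=int)
    dev = np.abs(x - med) / (MAD_SCALE * mad)
    flagged = np.flatnonzero(dev > k)
    max_remove = int(0.25 * x.size)
    if flagged.size > max_remove:
        flagged = flagged[np.argsort(dev[flagged])[::-1][:max_remove]]
    removed = np.sort(flagged)
    keep = np.setdiff1d(np.arange(x.size), removed)
    return x[keep], removed


def positional_bias(plate: "NormalizedPlate", min_wells: int = 3,
                    flag_threshold: float = 3.0) -> pd.DataFrame:
    """Per-row / per-column standardized deviation of test-well NFS.

    Detects striping and gradient artifacts: for each row and column with at
    least ``min_wells`` test wells, reports (row-or-column mean - grand
    mean) / grand SD and flags |bias| above ``flag_threshold``.  Rows or
    columns with too few test wells are skipped with a warning.
    """
    layout = plate.layout
    test_wells = [w for w in layout.wells_with_role(Role.TEST) if w in plate.nfs]
    vals = np.array([plate.nfs[w] for w in test_wells])
    if vals.size == 0:
        return pd.DataFrame(columns=["axis", "label", "n", "bias", "flagged"])
    grand_mean = vals.mean()
    grand_sd = vals.std(ddof=1) if vals.size > 1 else 0.0

    groups: dict[tuple[str, str], list[float]] = {}
    for w, v in zip(test_wells, vals):
        r, c = parse_well(w)
        groups.setdefault(("row", w[0]), []).append(v)
        groups.setdefault(("col", str(c + 1)), []).append(v)

    rows = []
    for (axis, label), g in sorted(groups.items()):
        if len(g) < min_wells:
            warnings.warn(f"{axis} {label}: only {len(g)} test wells; bias skipped")
            continue
        bias = 0.0 if grand_sd == 0 else (float(np.mean(g)) - grand_mean) / grand_sd
        rows.append({"axis": axis, "label": label, "n": len(g), "bias": bias,
                     "flagged": abs(bias) > flag_threshold})
    return pd.DataFrame(rows)


@dataclass
class QCThresholds:
    """Gate settings; defaults are the standard HTS guidelines (strict inequalities)."""

    max_cv: float = 0.10
    min_sb: float = 4.0
    min_z_prime: float = 0.5
    bias_flag: float = 3.0
    outlier_k: float = 3.0


@dataclass
class QCReport:
    plate_id: str
    cv_pos: float
    cv_zero: float
    sb_ratio: float
    z_prime: float
    row_bias: pd.DataFrame = field(repr=False)
    col_bias: pd.DataFrame = field(repr=False)
    outliers_removed: list[str] = field(default_factory=list)
    passed: bool = False

    def to_dict(self) -> dict:
        return {
            "plate_id": self.plate_id,
            "cv_pos": self.cv_pos,
            "cv_zero": self.cv_zero,
            "sb_ratio": self.sb_ratio,
            "z_prime": self.z_prime,
            "n_rows_flagged": int(self.row_bias["flagged"].sum()) if len(self.row_bias) else 0,
            "n_cols_flagged": int(self.col_bias["flagged"].sum()) if len(self.col_bias) else 0,
            "outliers_removed": list(self.outliers_removed),
            "passed": bool(self.passed),
        }


def gate_plate(report: QCReport, thresholds: QCThresholds | None = None) -> bool:
    """Pass/fail decision: CV_pos < max, S:B > min, Z' > min — all strict."""
    t = thresholds or QCThresholds()
    return (report.cv_pos < t.max_cv
            and report.sb_ratio > t.min_sb
            and report.z_prime > t.min_z_prime)


def qc_plate(plate: "NormalizedPlate", thresholds: QCThresholds | None = None) -> QCReport:
    """Full QC report for one normalized plate.

    CV, S:B and Z' are computed on outlier-filtered, background-subtracted
    control signals (the same retained wells that anchored normalization);
    positional bias is computed on test-well NFS.
    """
    t = thresholds or QCThresholds()
    pos = plate.retained_pos_net
    zero = plate.retained_zero_net
    bias = positional_bias(plate, flag_threshold=t.bias_flag)
    row_bias = bias[bias["axis"] == "row"].reset_index(drop=True)
    col_bias = bias[bias["axis"] == "col"].reset_index(drop=True)
    report = QCReport(
        plate_id=plate.plate_id,
        cv_pos=coefficient_of_variation(pos),
        cv_zero=coefficient_of_variation(zero),
        sb_ratio=signal_to_background(pos, zero),
        z_prime=z_prime(pos, zero),
        row_bias=row_bias,
        col_bias=col_bias,
        outliers_removed=list(plate.control_outliers),
    )
    report.passed = gate_plate(report, t)
    return report
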