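"""Background subtraction, control-anchored normalization, and hit calling.

Each well's net signal is ``final - baseline``.  Per plate, net signals are
rescaled to the normalized fluorescent signal (NFS) using the outlier-
filtered in-plate control means:

    NFS_w = (net_w - mean_zero) / (mean_pos - mean_zero)

so the DMSO (zero-signal) control mean sits at exactly 0 and the EC90-
agonist (positive-signal) control mean at exactly 1.  Percent inhibition is
``100 * (1 - NFS)``.  Hits are test wells whose NFS falls strictly below a
per-run threshold of mean - 3 SD of all test-well NFS in that run; a
compound is a confirmed hit when it is a hit in every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (DataError, DegeneratePlateError, InsufficientDataError,
                     UndefinedMetricError)
from .plates import PlateLayout, RawPlateRead, Role
from .qc import remove_control_outliers


def subtract_background(raw: RawPlateRead) -> tuple[dict[str, float], list[str]]:
    """Per-well net signal (final - baseline) and the wells that went negative.

    Negative net signals are kept (they carry information about artifacts)
    but flagged.
    """
    if set(raw.baseline) != set(raw.final):
        raise DataError("baseline and final reads cover different wells")
    net = {w: raw.final[w] - raw.baseline[w] for w in raw.final}
    flagged = sorted(w for w, v in net.items() if v < 0)
    return net, flagged


@dataclass
class NormalizedPlate:
    """One plate after background subtraction and control anchoring."""

    plate_id: str
    run_id: str
    subtype: str
    layout: PlateLayout
    net: dict[str, float]
    nfs: dict[str, float]
    pct_inhibition: dict[str, float]
    retained_zero_net: np.ndarray = field(repr=False)
    retained_pos_net: np.ndarray = field(repr=False)
    control_outliers: list[str] = field(default_factory=list)
    negative_net_wells: list[str] = field(default_factory=list)

    def test_well_nfs(self) -> pd.Series:
        wells = [w for w in self.layout.wells_with_role(Role.TEST) if w in self.nfs]
        return pd.Series({w: self.nfs[w] for w in wells}, name=self.plate_id)

    def compound_nfs(self) -> pd.Series:
        """NFS indexed by compound id for every assigned test well."""
        out = {}
        for w, cid in self.layout.compound_map.items():
            if self.layout.role_map[w] is Role.TEST and w in self.nfs:
                out[cid] = self.nfs[w]
        return pd.Series(out, name=self.plate_id)


def normalize_plate(net: Mapping[str, float], layout: PlateLayout,
                    outlier_k: float = 3.0, plate_id: str = "",
                    run_id: str = "", subtype: str = "") -> NormalizedPlate:
    """Anchor a plate's net signals to its internal controls.

    Controls are outlier-filtered (median/MAD rule, factor ``outlier_k``)
    before their means are taken, so a single bad control well cannot skew
    the anchors.  Raises :class:`DegeneratePlateError` when the retained
    control means do not separate.
    """
    zero_wells = [w for w in layout.wells_with_role(Role.ZERO_CONTROL) if w in net]
    pos_wells = [w for w in layout.wells_with_role(Role.POS_CONTROL) if w in net]
    zero = np.array([net[w] for w in zero_wells], dtype=float)
    pos = np.array([net[w] for w in pos_wells], dtype=float)

    zero_ret, zero_rm = remove_control_outliers(zero, outlier_k)
    pos_ret, pos_rm = remove_control_outliers(pos, outlier_k)
    if zero_ret.size < 2 or pos_ret.size < 2:
        raise InsufficientDataError("need >= 2 retained wells per control class")
    mu_zero, mu_pos = zero_ret.mean(), pos_ret.mean()
    if mu_pos == mu_zero:
        raise DegeneratePlateError(
            f"plate {plate_id}: control means equal ({mu_pos}); no signal window")

    span = mu_pos - mu_zero
    nfs = {w: (v - mu_zero) / span for w, v in net.items()}
    pct = {w: 100.0 * (1.0 - x) for w, x in nfs.items()}
    outlier_wells = [zero_wells[i] for i in zero_rm] + [pos_wells[i] for i in pos_rm]
    negatives = sorted(w for w, v in net.items() if v < 0)
    return NormalizedPlate(plate_id, run_id, subtype, layout, dict(net), nfs, pct,
                           zero_ret, pos_ret, sorted(outlier_wells), negatives)


def hit_threshold(run_nfs: Sequence[float], sd_multiplier: float = 3.0) -> float:
    """Per-run hit cutoff: mean - ``sd_multiplier`` * SD of test-well NFS.

    Pooled over all test wells of the run's QC-passing plates; the SD uses
    the n-1 denominator.
    """
    x = np.asarray(run_nfs, dtype=float)
    if x.size < 10:
        raise InsufficientDataError("hit threshold needs >= 10 test wells")
    return float(x.mean() - sd_multiplier * x.std(ddof=1))


def call_hits(nfs: Sequence[float], threshold: float) -> np.ndarray:
    """Hit flags: NFS strictly below the threshold."""
    return np.asarray(nfs, dtype=float) < threshold


def replicate_concordance(run1_nfs: Sequence[float], run2_nfs: Sequence[float]
                          ) -> tuple[float, float, float]:
    """OLS regression of run 2 on run 1: returns (R^2, slope, intercept)."""
    x = np.asarray(run1_nfs, dtype=float)
    y = np.asarray(run2_nfs, dtype=float)
    if x.size != y.size:
        raise DataError("paired series have different lengths")
    if x.size < 3:
        raise InsufficientDataError("concordance needs >= 3 pairs")
    if np.ptp(x) == 0:
        raise UndefinedMetricError("zero variance in predictor run")
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2), float(res.slope), float(res.intercept)


@dataclass
class ScreenResult:
    """Duplicate-run screen outcome for one receptor subtype.

    ``table`` has one row per manifest compound with per-run NFS, per-run
    hit flags, ``evaluable`` (all the compound's plates passed QC in every
    run) and ``confirmed`` (hit in every run).
    """

    subtype: str
    table: pd.DataFrame
    thresholds: dict[str, float]
    concordance: dict[str, float] = field(default_factory=dict)

    @property
    def run_ids(self) -> list[str]:
        return sorted(self.thresholds)

    @property
    def n_evaluable(self) -> int:
        return int(self.table["evaluable"].sum())

    @property
    def n_unique_hits(self) -> int:
        hit_cols = [c for c in self.table.columns if c.startswith("hit_")]
        ev = self.table["evaluable"]
        return int((self.table.loc[ev, hit_cols].any(axis=1)).sum())

    @property
    def n_confirmed_hits(self) -> int:
        return int(self.table["confirmed"].sum())

    def confirmed_ids(self) -> list[str]:
        return list(self.table.loc[self.table["confirmed"], "compound_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def compile_screen_result(plates_by_run: Mapping[str, Sequence[NormalizedPlate]],
                          qc_pass: Mapping[str, bool],
                          manifest_ids: Sequence[str],
                          subtype: str = "",
                          sd_multiplier: float = 3.0) -> ScreenResult:
    """Assemble per-compound calls from normalized plates of a duplicate run.

    ``qc_pass`` maps plate_id -> gate verdict; compounds on any failing (or
    missing) plate in any run are marked non-evaluable and never called.
    The hit threshold of each run pools test-well NFS across that run's
    passing plates only.
    """
    runs = sorted(plates_by_run)
    table = pd.DataFrame({"compound_id": list(manifest_ids)}).set_index("compound_id")
    thresholds: dict[str, float] = {}
    evaluable = pd.Series(True, index=table.index)

    for run in runs:
        passing = [p for p in plates_by_run[run] if qc_pass.get(p.plate_id, False)]
        pooled = np.concatenate([p.test_well_nfs().to_numpy() for p in passing]) \
            if passing else np.array([])
        # a run with no usable plates gets a NaN threshold: nothing can be a hit
        thresholds[run] = hit_threshold(pooled, sd_multiplier) if pooled.size >= 10 \
            else float("nan")
        nfs = pd.concat([p.compound_nfs() for p in passing]) if passing else pd.Series(dtype=float)
        nfs = nfs[~nfs.index.duplicated()]
        table[f"nfs_{run}"] = nfs.reindex(table.index)
        evaluable &= table[f"nfs_{run}"].notna()

    table["evaluable"] = evaluable
    for run in runs:
        flags = call_hits(table[f"nfs_{run}"].fillna(np.inf), thresholds[run])
        table[f"hit_{run}"] = flags & table["evaluable"]
    hit_cols = [f"hit_{run}" for run in runs]
    table["confirmed"] = table[hit_cols].all(axis=1)

    concordance: dict[str, float] = {}
    if len(runs) >= 2:
        a, b = f"nfs_{runs[0]}", f"nfs_{runs[1]}"
        paired = table.loc[table["evaluable"], [a, b]].dropna()
        if len(paired) >= 3 and np.ptp(paired[a].to_numpy()) > 0:
            r2, slope, intercept = replicate_concordance(paired[a], paired[b])
            concordance = {"r2_test": r2, "slope_test": slope, "intercept_test": intercept}
    return ScreenResult(subtype, table.reset_index(), thresholds, concordance)


def rates_from_counts(unique_hits: int, both_run_hits: int, evaluable: int,
                      library_size: int) -> dict[str, float]:
    """Screen rate arithmetic from whole-screen counts.

    primary_hit_rate   = 100 * unique_hits   / evaluable
    adjusted_hit_rate  = 100 * both_run_hits / evaluable
    pct_data_passed_qc = 100 * evaluable     / library_size
    """
    if evaluable <= 0:
        raise UndefinedMetricError("no evaluable compounds")
    if library_size <= 0:
        raise UndefinedMetricError("library size must be positive")
    return {
        "primary_hit_rate": 100.0 * unique_hits / evaluable,
        "adjusted_hit_rate": 100.0 * both_run_hits / evaluable,
        "pct_data_passed_qc": 100.0 * evaluable / library_size,
    }


def screen_rates(result: ScreenResult, library_size: int) -> dict[str, float]:
    """Primary/adjusted hit rates and %-passed-QC for a compiled screen."""
    return rates_from_counts(result.n_unique_hits, result.n_confirmed_hits,
                             result.n_evaluable, library_size)
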