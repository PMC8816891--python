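"""End-to-end orchestration: subtract -> QC -> normalize -> call -> validate
-> classify, plus the summary tables a screening campaign reports.

`run_screen_pipeline` processes one subtype's duplicate-run plate set into
a :class:`~nachr_hts.screen.ScreenResult` with QC reports and an exclusion
log.  `run_study` drives a complete simulated three-subtype campaign with
planted ground truth, including orthogonal efflux validation of the
confirmed hits and selectivity classification.  `report_tables` condenses
study outcomes into the two standard summary tables (per-assay QC and hit
selection) and the cross-assay means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .efflux import analyze_efflux, validation_frame, validation_rate
from .errors import (DegeneratePlateError, InsufficientDataError,
                     NachrHtsError, UndefinedMetricError)
from .plates import CompoundManifest, PlateLayout, RawPlateRead, make_manifest
from .qc import QCReport, QCThresholds, qc_plate
from .screen import (NormalizedPlate, ScreenResult, compile_screen_result,
                     normalize_plate, screen_rates, subtract_background)
from .selectivity import (SUBTYPES, SelectivityProfile, profiles_frame,
                          venn_counts)
from .simulate import (DEFAULT_CONTEXTS, CompoundTruth, NoiseModel,
                       default_truth_library, generate_efflux_experiment,
                       generate_screen)


@dataclass
class RunConfig:
    """All tunable pipeline settings in one place.

    Campaign-standard defaults: SD multiplier 3 for both the hit
    threshold and the efflux validation cutoff, median/MAD outlier factor
    3, and the standard QC gates (CV < 10%, S:B > 4, Z' > 0.5).
    """

    qc: QCThresholds = field(default_factory=QCThresholds)
    outlier_k: float = 3.0
    hit_sd_multiplier: float = 3.0
    validation_sd_multiplier: float = 3.0
    n_runs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hit_sd_multiplier <= 0 or self.validation_sd_multiplier <= 0:
            raise NachrHtsError("SD multipliers must be positive")


@dataclass
class SubtypeOutcome:
    """One subtype's screen: calls, QC reports, and the exclusion log."""

    subtype: str
    result: ScreenResult
    qc_reports: dict[str, QCReport]
    exclusions: list[str]
    rates: dict[str, float]


def run_screen_pipeline(plates: list[RawPlateRead],
                        layouts: dict[str, PlateLayout],
                        manifest: CompoundManifest,
                        config: RunConfig | None = None,
                        subtype: str = "") -> SubtypeOutcome:
    """Process raw duplicate-run plates into per-compound hit calls.

    Every plate is background-subtracted, normalized to its internal
    controls and QC-gated; plates that fail QC (or cannot be normalized)
    are logged and their compounds become non-evaluable.  Hit thresholds
    are computed per run over the QC-passing plates, and rates over the
    evaluable denominator.
    """
    config = config or RunConfig()
    subtype = subtype or (plates[0].subtype if plates else "")
    by_run: dict[str, list[NormalizedPlate]] = {}
    qc_reports: dict[str, QCReport] = {}
    qc_pass: dict[str, bool] = {}
    exclusions: list[str] = []

    for raw in plates:
        layout = layouts[raw.plate_id]
        by_run.setdefault(raw.run_id, [])  # run must be visible even if all its plates fail
        net, neg_wells = subtract_background(raw)
        if neg_wells:
            exclusions.append(
                f"{raw.plate_id}: {len(neg_wells)} negative net wells flagged")
        try:
            norm = normalize_plate(net, layout, config.outlier_k,
                                   raw.plate_id, raw.run_id, raw.subtype)
        except (DegeneratePlateError, InsufficientDataError) as exc:
            qc_pass[raw.plate_id] = False
            exclusions.append(f"{raw.plate_id}: normalization failed ({exc})")
            continue
        report = qc_plate(norm, config.qc)
        qc_reports[raw.plate_id] = report
        qc_pass[raw.plate_id] = report.passed
        if not report.passed:
            exclusions.append(
                f"{raw.plate_id}: failed QC gate "
                f"(CV {report.cv_pos:.3f}, S:B {report.sb_ratio:.1f}, "
                f"Z' {report.z_prime:.3f}); compounds non-evaluable")
        by_run.setdefault(raw.run_id, []).append(norm)

    result = compile_screen_result(by_run, qc_pass, manifest.compound_ids,
                                   subtype, config.hit_sd_multiplier)
    try:
        rates = screen_rates(result, len(manifest))
    except UndefinedMetricError:
        exclusions.append("no evaluable compounds: hit rates undefined")
        rates = {"primary_hit_rate": float("nan"),
                 "adjusted_hit_rate": float("nan"),
                 "pct_data_passed_qc": 0.0}
    return SubtypeOutcome(subtype, result, qc_reports, exclusions, rates)


@dataclass
class StudyOutcome:
    """A full simulated multi-subtype campaign with planted ground truth."""

    manifest: CompoundManifest
    truth: dict[str, CompoundTruth]
    planted_groups: pd.Series
    screens: dict[str, SubtypeOutcome]
    validations: dict[str, pd.DataFrame]       # subtype -> validation frame
    efflux_z_primes: dict[str, list[float]]
    control_spreads: dict[str, float]
    profiles: list[SelectivityProfile]
    venn: dict

    def profiles_frame(self) -> pd.DataFrame:
        return profiles_frame(self.profiles)


def run_study(seed: int = 0, n_compounds: int = 2298,
              noise: NoiseModel | None = None,
              config: RunConfig | None = None,
              contexts: dict | None = None,
              truth: dict[str, CompoundTruth] | None = None,
              planted_groups: pd.Series | None = None) -> StudyOutcome:
    """Simulate and analyze a complete three-subtype duplicate-run campaign.

    Generates the library and planted truth (unless supplied), screens each
    subtype in duplicate, advances compounds confirmed in at least one
    subtype to simulated efflux validation across all three subtypes, and
    classifies the advanced compounds into selectivity groups.
    """
    config = config or RunConfig(seed=seed)
    noise = noise or NoiseModel(seed=seed)
    contexts = contexts or DEFAULT_CONTEXTS
    manifest = make_manifest(n_compounds)
    if truth is None:
        truth, planted_groups = default_truth_library(manifest, seed=seed)
    elif planted_groups is None:
        planted_groups = pd.Series("", index=pd.Index(manifest.compound_ids))

    rng = np.random.default_rng(noise.seed)
    screens: dict[str, SubtypeOutcome] = {}
    for subtype in SUBTYPES:
        plates, layouts, _ = generate_screen(
            manifest, truth, contexts[subtype], noise, config.n_runs, rng=rng)
        screens[subtype] = run_screen_pipeline(plates, layouts, manifest,
                                               config, subtype)

    advanced = sorted(set().union(*(s.result.confirmed_ids() for s in screens.values())))
    validations: dict[str, pd.DataFrame] = {}
    spreads: dict[str, float] = {}
    z_primes: dict[str, list[float]] = {}
    val_flags: dict[str, dict[str, bool]] = {}
    val_inh: dict[str, dict[str, float]] = {}
    for subtype in SUBTYPES:
        plates, _ = generate_efflux_experiment(
            [truth[cid] for cid in advanced], subtype, noise, rng=rng)
        results, spread, zps = analyze_efflux(plates, config.validation_sd_multiplier)
        validations[subtype] = validation_frame(results)
        spreads[subtype] = spread
        z_primes[subtype] = zps
        val_flags[subtype] = {cid: r.validated for cid, r in results.items()}
        val_inh[subtype] = {cid: r.mean_pct_inhibition for cid, r in results.items()}

    profiles = [SelectivityProfile(
        cid,
        {s: val_flags[s].get(cid, False) for s in SUBTYPES},
        {s: val_inh[s].get(cid, float("nan")) for s in SUBTYPES},
    ) for cid in advanced]

    return StudyOutcome(manifest, truth, planted_groups, screens, validations,
                        z_primes, spreads, profiles, venn_counts(profiles))


# -- reporting --------------------------------------------------------------

def _cv_range(outcome: SubtypeOutcome) -> tuple[float, float]:
    cvs = [r.cv_pos for r in outcome.qc_reports.values()]
    return (min(cvs), max(cvs)) if cvs else (float("nan"), float("nan"))


def qc_summary_table(screens: dict[str, SubtypeOutcome]) -> pd.DataFrame:
    """Per-assay QC summary: CV range, mean/SD S:B and Z', plate and
    evaluable-compound counts, % of library data passing QC."""
    rows = []
    for subtype, out in screens.items():
        sbs = [r.sb_ratio for r in out.qc_reports.values()]
        zps = [r.z_prime for r in out.qc_reports.values()]
        lo, hi = _cv_range(out)
        rows.append({
            "subtype": subtype,
            "cv_min": round(lo, 4), "cv_max": round(hi, 4),
            "avg_sb": round(float(np.mean(sbs)), 3),
            "sd_sb": round(float(np.std(sbs, ddof=1)), 3) if len(sbs) > 1 else 0.0,
            "avg_z_prime": round(float(np.mean(zps)), 3),
            "sd_z_prime": round(float(np.std(zps, ddof=1)), 3) if len(zps) > 1 else 0.0,
            "n_plates": len(out.qc_reports),
            "n_evaluable": out.result.n_evaluable,
            "pct_data_passed_qc": round(out.rates["pct_data_passed_qc"], 2),
        })
    return pd.DataFrame(rows)


def hit_summary_table(screens: dict[str, SubtypeOutcome],
                      validations: dict[str, pd.DataFrame] | None = None
                      ) -> pd.DataFrame:
    """Per-assay hit selection summary with the standard rate precisions
    (adjusted rate to 3 decimals, other percentages to 2)."""
    rows = []
    for subtype, out in screens.items():
        row = {
            "subtype": subtype,
            "n_unique_hits": out.result.n_unique_hits,
            "primary_hit_rate": round(out.rates["primary_hit_rate"], 2),
            "n_both_run_hits": out.result.n_confirmed_hits,
            "adjusted_hit_rate": round(out.rates["adjusted_hit_rate"], 3),
        }
        if validations is not None and subtype in validations:
            vdf = validations[subtype]
            confirmed = set(out.result.confirmed_ids())
            tested = vdf[vdf["compound_id"].isin(confirmed)]
            n_res = len(tested)
            n_val = int(tested["validated"].sum())
            row.update({
                "n_resupplied": n_res,
                "n_validated": n_val,
                "validation_rate": round(validation_rate(n_val, n_res), 2)
                if n_res else float("nan"),
            })
        rows.append(row)
    return pd.DataFrame(rows)


def cross_assay_means(hit_table: pd.DataFrame) -> dict[str, float]:
    """Abstract-style cross-assay summaries: mean adjusted hit rate to one
    decimal, mean validation rate to the nearest integer percent."""
    out = {"mean_adjusted_hit_rate": round(float(hit_table["adjusted_hit_rate"].mean()), 1)}
    if "validation_rate" in hit_table:
        out["mean_validation_rate"] = round(float(hit_table["validation_rate"].mean()))
    return out


def report_tables(study: StudyOutcome) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """QC table, hit-selection table, and cross-assay summary for a study."""
    t1 = qc_summary_table(study.screens)
    t2 = hit_summary_table(study.screens, study.validations)
    return t1, t2, cross_assay_means(t2)
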