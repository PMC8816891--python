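"""Seeded generator of membrane-potential screens and efflux experiments.

The generator is phenomenological at the well level: each well's expected
net fluorescence is an affine function of the true fractional inhibition of
agonist-evoked receptor function in that well,

    net = floor + (ceiling - floor) * (1 - I),

where ``floor`` is the DMSO (zero-signal) level and ``ceiling`` the EC90-
agonist level.  An antagonist's inhibition at test concentration c follows
a 4PL law, I = efficacy_ceiling / (1 + (ic50 / c)^hill).  Noise is
multiplicative Gaussian per well (CV-parameterized, matching how control
CVs are reported), with a log-normal per-plate scale drift that cancels
under in-plate normalization, an independently drawn low-level baseline
read, and an optional multiplicative edge-well artifact.

Compounds that perturb the dye readout without touching the channel are
modeled with ``artifact_inhibition``: apparent inhibition in the
fluorescence screen, zero effect in the efflux assay.  These are the
compounds an orthogonal validation screen exists to reject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .doseresponse import AGONIST, four_pl
from .efflux import NONSPECIFIC_CONTROL, TEST, TOTAL_CONTROL, EffluxPlate
from .errors import ConfigurationError, DataError, DomainError
from .plates import (DEFAULT_ASSAY_CONC, CompoundManifest, PlateLayout,
                     RawPlateRead, Role, default_layout, split_across_plates)
from .selectivity import (A3B4_AND_A4B2, A3B4_AND_A6, A3B4_ONLY, A4B2_ONLY,
                          A6_ONLY, ALL_THREE, BOTH_B2, NOT_VALIDATED, SUBTYPES)

#: Reference-antagonist (mecamylamine-like) IC50s per subtype, molar.
MECAMYLAMINE_IC50 = {"A3B4": 1.91e-6, "A4B2": 0.54e-6, "A6B2B3": 1.67e-6}

#: Agonist (nicotine-like) EC50s per subtype, molar, used by the
#: dose-response recovery studies.
NICOTINE_EC50 = {"A3B4": 733.3e-9, "A4B2": 19.44e-9, "A6B2B3": 28.34e-9}


@dataclass(frozen=True)
class AssayContext:
    """Per-subtype assay conditions and signal scale (arbitrary units)."""

    subtype: str
    ec90_agonist_conc: float
    signal_floor: float
    signal_ceiling: float

    def __post_init__(self) -> None:
        if not (self.signal_ceiling > self.signal_floor > 0):
            raise ConfigurationError("need ceiling > floor > 0")


#: Default contexts: EC90 agonist 20 uM for A3B4, 500 nM for the two beta2
#: subtypes; ceilings chosen so the expected net S:B matches each assay's
#: characteristic value (~148, ~61, ~64).
DEFAULT_CONTEXTS = {
    "A3B4": AssayContext("A3B4", 20e-6, 50.0, 50.0 * 147.848),
    "A4B2": AssayContext("A4B2", 500e-9, 50.0, 50.0 * 61.458),
    "A6B2B3": AssayContext("A6B2B3", 500e-9, 50.0, 50.0 * 63.838),
}


@dataclass(frozen=True)
class NoiseModel:
    """Well-level and plate-level noise settings.

    ``well_cv`` is the target coefficient of variation of control wells
    (default 6%, mid-range of the observed 2.4-10% per-plate CVs; it
    yields expected plate Z' near 0.8, matching the per-assay averages);
    ``plate_scale_sd`` the SD of the log-normal plate-to-plate drift;
    ``edge_bias`` a multiplicative distortion applied to border wells when
    non-zero.  The baseline read is drawn at 10% of the signal floor with
    the same CV.
    """

    well_cv: float = 0.06
    plate_scale_sd: float = 0.08
    edge_bias: float = 0.0
    baseline_frac: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("well_cv", "plate_scale_sd", "edge_bias", "baseline_frac"):
            if not math.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class CompoundTruth:
    """Ground-truth pharmacology of one library compound."""

    compound_id: str
    is_antagonist_at: dict[str, bool] = field(default_factory=dict)
    ic50: dict[str, float] = field(default_factory=dict)
    hill: float = 1.0
    efficacy_ceiling: float = 1.0
    artifact_inhibition: float = 0.0  # fluorescence-only apparent inhibition

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficacy_ceiling <= 1.0:
            raise ConfigurationError("efficacy_ceiling must lie in [0, 1]")
        for s, flag in self.is_antagonist_at.items():
            if flag and s not in self.ic50:
                raise ConfigurationError(
                    f"{self.compound_id}: antagonist at {s} but no IC50 given")

    def channel_inhibition(self, subtype: str, conc: float = DEFAULT_ASSAY_CONC) -> float:
        """True fractional inhibition of receptor function at ``conc``."""
        if not self.is_antagonist_at.get(subtype, False):
            return 0.0
        return self.efficacy_ceiling / (1.0 + (self.ic50[subtype] / conc) ** self.hill)

    def fluorescence_inhibition(self, subtype: str, conc: float = DEFAULT_ASSAY_CONC) -> float:
        """Apparent inhibition seen by the dye readout (channel + artifact)."""
        return min(1.0, max(self.channel_inhibition(subtype, conc),
                            self.artifact_inhibition))


def _noisy(expected: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return np.array(expected, dtype=float)
    draw = expected * (1.0 + cv * rng.standard_normal(expected.shape))
    return np.clip(draw, 0.0, None)


def generate_screen(manifest: CompoundManifest, truth: dict[str, CompoundTruth],
                    ctx: AssayContext, noise: NoiseModel, n_runs: int = 2,
                    layout: PlateLayout | None = None,
                    rng: np.random.Generator | None = None
                    ) -> tuple[list[RawPlateRead], dict[str, PlateLayout], pd.DataFrame]:
    """Simulate a full duplicate-run screen for one subtype.

    Splits the manifest across plates under the default layout (204 test
    wells per plate), draws both fluorescence reads for every non-EMPTY
    well in every run, and returns the plate reads, per-plate layouts, and
    a ground-truth table (compound_id, subtype, true channel inhibition and
    apparent fluorescence inhibition at the screening concentration).
    """
    if n_runs < 1:
        raise ConfigurationError("n_runs must be >= 1")
    missing = [cid for cid in manifest.compound_ids if cid not in truth]
    if missing:
        raise ConfigurationError(
            f"truth missing {len(missing)} compound(s), e.g. {missing[:3]}")
    rng = rng if rng is not None else noise.rng()
    template = layout if layout is not None else default_layout()
    assay_conc = dict(zip(manifest.table["compound_id"], manifest.table["assay_conc_M"]))
    assignments = split_across_plates(manifest.compound_ids, template)

    floor, ceiling = ctx.signal_floor, ctx.signal_ceiling
    span = ceiling - floor
    base_level = noise.baseline_frac * floor
    mec_ic50 = MECAMYLAMINE_IC50.get(ctx.subtype, 1.0e-6)

    reads: list[RawPlateRead] = []
    layouts: dict[str, PlateLayout] = {}
    for run in range(1, n_runs + 1):
        run_id = f"R{run}"
        for p, assign in enumerate(assignments, start=1):
            plate_id = f"{ctx.subtype}_{run_id}_P{p:02d}"
            plate_layout = template.with_compounds(
                assign, conc=float(np.mean([assay_conc[c] for c in assign.values()])))
            if plate_id not in layouts:
                layouts[plate_id] = plate_layout
            scale = float(np.exp(noise.plate_scale_sd * rng.standard_normal())) \
                if noise.plate_scale_sd > 0 else 1.0

            wells, expected = [], []
            for w, role in plate_layout.role_map.items():
                if role is Role.EMPTY:
                    continue
                if role is Role.ZERO_CONTROL:
                    inh = 1.0  # DMSO only: no agonist response above floor
                    sig = floor
                elif role in (Role.POS_CONTROL, Role.EDGE_EXCLUDED):
                    sig = ceiling
                elif role is Role.ANTAG_CONTROL:
                    c = plate_layout.conc_map[w]
                    i_mec = 1.0 / (1.0 + mec_ic50 / c)
                    sig = floor + span * (1.0 - i_mec)
                else:  # TEST
                    cid = plate_layout.compound_map[w]
                    i_c = truth[cid].fluorescence_inhibition(
                        ctx.subtype, assay_conc[cid])
                    sig = floor + span * (1.0 - i_c)
                if role is Role.EDGE_EXCLUDED and noise.edge_bias:
                    sig = sig * (1.0 + noise.edge_bias)
                wells.append(w)
                expected.append(sig)

            expected = np.asarray(expected) * scale
            signal = _noisy(expected, noise.well_cv, rng)
            b0 = np.full(len(wells), base_level * scale)
            baseline_read = _noisy(b0, noise.well_cv, rng)
            final_read = _noisy(b0, noise.well_cv, rng) + signal
            reads.append(RawPlateRead(plate_id, run_id, ctx.subtype,
                                      dict(zip(wells, baseline_read)),
                                      dict(zip(wells, final_read))))

    truth_rows = [{
        "compound_id": cid,
        "subtype": ctx.subtype,
        "true_inhibition": truth[cid].channel_inhibition(ctx.subtype, assay_conc[cid]),
        "apparent_inhibition": truth[cid].fluorescence_inhibition(ctx.subtype, assay_conc[cid]),
    } for cid in manifest.compound_ids]
    return reads, layouts, pd.DataFrame(truth_rows)


# -- efflux experiments -----------------------------------------------------

#: Default efflux signal scale, counts per minute.
EFFLUX_NONSPECIFIC_CPM = 500.0
EFFLUX_SPECIFIC_CPM = 3000.0
EFFLUX_COMPOUNDS_PER_PLATE = 6


def generate_efflux_experiment(compounds: list[CompoundTruth], subtype: str,
                               noise: NoiseModel, n_experiments: int = 3,
                               test_conc: float = DEFAULT_ASSAY_CONC,
                               rng: np.random.Generator | None = None
                               ) -> tuple[list[EffluxPlate], pd.DataFrame]:
    """Simulate triplicate-design 86Rb+ efflux experiments for one subtype.

    Each 24-well plate carries triplicate total-efflux and non-specific
    controls plus triplicate test wells for up to 6 compounds; every
    compound appears once per independent experiment (3 by default).
    Expected test-well counts are nonspecific + specific * (1 - I), with I
    the compound's true channel inhibition — fluorescence artifacts have
    I = 0 here by construction.
    """
    rng = rng if rng is not None else noise.rng()
    well_grid = [f"{r}{c}" for r in "ABCD" for c in range(1, 7)]
    plates: list[EffluxPlate] = []
    for e in range(1, n_experiments + 1):
        scale = float(np.exp(noise.plate_scale_sd * rng.standard_normal())) \
            if noise.plate_scale_sd > 0 else 1.0
        for p in range(0, len(compounds), EFFLUX_COMPOUNDS_PER_PLATE):
            chunk = compounds[p:p + EFFLUX_COMPOUNDS_PER_PLATE]
            roles = [TOTAL_CONTROL] * 3 + [NONSPECIFIC_CONTROL] * 3
            cids = [""] * 6
            expected = [EFFLUX_NONSPECIFIC_CPM + EFFLUX_SPECIFIC_CPM] * 3 \
                + [EFFLUX_NONSPECIFIC_CPM] * 3
            for t in chunk:
                i_c = t.channel_inhibition(subtype, test_conc)
                roles += [TEST] * 3
                cids += [t.compound_id] * 3
                expected += [EFFLUX_NONSPECIFIC_CPM
                             + EFFLUX_SPECIFIC_CPM * (1.0 - i_c)] * 3
            cpm = _noisy(np.asarray(expected) * scale, noise.well_cv, rng)
            plate_id = f"EFX_{subtype}_E{e}_P{p // EFFLUX_COMPOUNDS_PER_PLATE + 1:02d}"
            plates.append(EffluxPlate(plate_id, subtype, f"E{e}", pd.DataFrame({
                "well": well_grid[:len(roles)],
                "role": roles,
                "compound_id": cids,
                "cpm": cpm,
            })))
    gt = pd.DataFrame([{
        "compound_id": t.compound_id,
        "subtype": subtype,
        "true_inhibition": t.channel_inhibition(subtype, test_conc),
    } for t in compounds])
    return plates, gt


def generate_dose_response(bottom: float, top: float, x50: float, hill: float,
                           conc_grid, reps: int = 4, cv: float = 0.05,
                           seed: int = 0, direction: str = AGONIST) -> pd.DataFrame:
    """Replicated responses drawn around a 4PL curve on a concentration grid.

    Noise is multiplicative Gaussian at ``cv`` (cv=0 reproduces the curve
    exactly); output columns are conc_M, replicate, response.
    """
    conc = np.asarray(conc_grid, dtype=float)
    if np.any(conc <= 0):
        raise DomainError("concentrations must be positive")
    if reps < 1:
        raise DataError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    curve = four_pl(conc, bottom, top, x50, hill, direction)
    rows = []
    for rep in range(1, reps + 1):
        resp = curve if cv == 0 else curve * (1.0 + cv * rng.standard_normal(conc.shape))
        for c, y in zip(conc, resp):
            rows.append({"conc_M": c, "replicate": rep, "response": float(y)})
    return pd.DataFrame(rows)


# -- planted-truth library --------------------------------------------------

#: Planted selectivity-group sizes for the default study fixture.
DEFAULT_GROUP_PLAN = {
    A3B4_ONLY: 26,
    A4B2_ONLY: 6,
    A6_ONLY: 5,
    BOTH_B2: 20,
    ALL_THREE: 10,
    NOT_VALIDATED: 15,
}

_GROUP_SUBTYPES = {
    A3B4_ONLY: ("A3B4",),
    A4B2_ONLY: ("A4B2",),
    A6_ONLY: ("A6B2B3",),
    BOTH_B2: ("A4B2", "A6B2B3"),
    ALL_THREE: SUBTYPES,
    NOT_VALIDATED: (),
    A3B4_AND_A4B2: ("A3B4", "A4B2"),
    A3B4_AND_A6: ("A3B4", "A6B2B3"),
}

#: Planted inhibition (fraction, measured at the 10 uM screening
#: concentration) for the antagonist classes: the high-efficacy class
#: (> 75% inhibition of agonist-evoked function), a moderate class, and the
#: low-efficacy class (<= 50%).  The generator back-computes each
#: compound's efficacy ceiling from its IC50 so the planted value is the
#: inhibition the screen actually sees.
HIGH_INHIBITION = (0.80, 0.93)
MODERATE_INHIBITION = (0.55, 0.70)
LOW_INHIBITION = (0.46, 0.50)


def default_truth_library(manifest: CompoundManifest, seed: int = 0,
                          group_plan: dict[str, int] | None = None
                          ) -> tuple[dict[str, CompoundTruth], pd.Series]:
    """Plant antagonist profiles with known selectivity groups in a library.

    Mirrors the observed composition: the alpha3beta4-selective group is
    mostly high-efficacy (24 of 26 above 75% inhibition at 10 uM, the other
    2 moderate), the beta2-assay groups low-efficacy (<= 50%), the
    all-three group high-efficacy, and the not-validated group pure
    fluorescence artifacts (strong apparent inhibition, zero channel
    effect).  All remaining compounds are inactive.  Returns the truth map
    and each compound's planted group label.
    """
    plan = dict(DEFAULT_GROUP_PLAN if group_plan is None else group_plan)
    n_planted = sum(plan.values())
    ids = manifest.compound_ids
    if n_planted > len(ids):
        raise ConfigurationError("group plan larger than the library")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=n_planted, replace=False)

    def loguniform(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    truth: dict[str, CompoundTruth] = {
        cid: CompoundTruth(cid, {s: False for s in SUBTYPES}) for cid in ids}
    groups = pd.Series("INACTIVE", index=pd.Index(ids, name="compound_id"), name="group")

    i = 0
    for group, count in plan.items():
        subtypes = _GROUP_SUBTYPES[group]
        for j in range(count):
            cid = ids[chosen[i]]
            i += 1
            groups[cid] = group
            if group == NOT_VALIDATED:
                truth[cid] = CompoundTruth(
                    cid, {s: False for s in SUBTYPES},
                    artifact_inhibition=rng.uniform(0.75, 0.90))
                continue
            # alpha3beta4-selectives: 24 of 26 high-efficacy, 2 moderate
            if group == A3B4_ONLY:
                inh_range = HIGH_INHIBITION if j < count - 2 else MODERATE_INHIBITION
            elif group == ALL_THREE:
                inh_range = HIGH_INHIBITION
            else:
                inh_range = LOW_INHIBITION
            target = rng.uniform(*inh_range)
            ic50 = {s: loguniform(2e-7, 1e-6) for s in subtypes}
            # one shared ceiling scaled from the worst-case IC50 so the
            # planted inhibition is met at every antagonized subtype
            ceiling = min(1.0, target * (1.0 + max(ic50.values()) / DEFAULT_ASSAY_CONC))
            truth[cid] = CompoundTruth(
                cid,
                {s: s in subtypes for s in SUBTYPES},
                ic50,
                hill=1.0,
                efficacy_ceiling=ceiling,
            )
    return truth, groups
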