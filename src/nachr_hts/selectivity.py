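"""Cross-subtype integration of validation outcomes into selectivity groups.

A compound tested against the three receptor subtypes (alpha3beta4,
alpha4beta2, alpha6/3beta2beta3) carries one validated/not-validated flag
per subtype.  The 2^3 flag combinations partition compounds into named
selectivity groups; the beta2-containing pair (alpha4beta2 and
alpha6/3beta2beta3) share pharmacology, so their joint group gets its own
name while the two alpha3beta4+single-beta2 patterns keep explicit labels
of their own to make the classifier total.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

SUBTYPES = ("A3B4", "A4B2", "A6B2B3")

A3B4_ONLY = "A3B4_ONLY"
A4B2_ONLY = "A4B2_ONLY"
A6_ONLY = "A6_ONLY"
BOTH_B2 = "BOTH_B2"
ALL_THREE = "ALL_THREE"
NOT_VALIDATED = "NOT_VALIDATED"
A3B4_AND_A4B2 = "A3B4_AND_A4B2"
A3B4_AND_A6 = "A3B4_AND_A6"

GROUPS = (A3B4_ONLY, A4B2_ONLY, A6_ONLY, BOTH_B2, ALL_THREE, NOT_VALIDATED,
          A3B4_AND_A4B2, A3B4_AND_A6)

_TRUTH_TABLE = {
    (False, False, False): NOT_VALIDATED,
    (True, False, False): A3B4_ONLY,
    (False, True, False): A4B2_ONLY,
    (False, False, True): A6_ONLY,
    (False, True, True): BOTH_B2,
    (True, True, True): ALL_THREE,
    (True, True, False): A3B4_AND_A4B2,
    (True, False, True): A3B4_AND_A6,
}


def classify_compound(validated_a3b4, validated_a4b2, validated_a6) -> str:
    """Map the three per-subtype validated flags to a selectivity group."""
    flags = (validated_a3b4, validated_a4b2, validated_a6)
    if any(f is None or (isinstance(f, float) and np.isnan(f)) for f in flags):
        raise DataError("all three validated flags are required")
    return _TRUTH_TABLE[tuple(bool(f) for f in flags)]


@dataclass
class SelectivityProfile:
    compound_id: str
    validated: dict[str, bool]          # subtype -> flag
    pct_inhibition: dict[str, float]    # subtype -> mean % inhibition
    group: str = ""

    def __post_init__(self) -> None:
        missing = set(SUBTYPES) - set(self.validated)
        if missing:
            raise DataError(f"profile {self.compound_id} missing subtypes {sorted(missing)}")
        if not self.group:
            self.group = classify_compound(*(self.validated[s] for s in SUBTYPES))


def profiles_frame(profiles: list[SelectivityProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"compound_id": p.compound_id, "group": p.group}
        for s in SUBTYPES:
            row[f"validated_{s}"] = bool(p.validated[s])
            row[f"pct_inhibition_{s}"] = p.pct_inhibition.get(s, np.nan)
        rows.append(row)
    cols = (["compound_id", "group"]
            + [f"validated_{s}" for s in SUBTYPES]
            + [f"pct_inhibition_{s}" for s in SUBTYPES])
    return pd.DataFrame(rows, columns=cols)


def venn_counts(profiles: list[SelectivityProfile]) -> dict:
    """Group sizes plus the pairwise/triple overlap counts of validated hits.

    Group counts always sum to the number of profiles; the overlap counts
    describe the Venn diagram of per-subtype validated sets.
    """
    groups = Counter(p.group for p in profiles)
    by_group = {g: int(groups.get(g, 0)) for g in GROUPS}
    val = {s: {p.compound_id for p in profiles if p.validated[s]} for s in SUBTYPES}
    overlaps = {
        "A3B4_and_A4B2": len(val["A3B4"] & val["A4B2"]),
        "A3B4_and_A6B2B3": len(val["A3B4"] & val["A6B2B3"]),
        "A4B2_and_A6B2B3": len(val["A4B2"] & val["A6B2B3"]),
        "all_three": len(val["A3B4"] & val["A4B2"] & val["A6B2B3"]),
    }
    return {"groups": by_group,
            "validated_per_subtype": {s: len(val[s]) for s in SUBTYPES},
            "overlaps": overlaps,
            "total": len(profiles)}


def efficacy_summary(profiles: list[SelectivityProfile]) -> pd.DataFrame:
    """Per-group efficacy statistics.

    A compound's efficacy is its largest mean % inhibition across the
    subtypes where it validated (across all subtypes for unvalidated
    compounds).  Bins use strict comparisons: > 75% is "highly
    efficacious", <= 50% is the low-efficacy class.
    """
    rows = []
    by_group: dict[str, list[float]] = {}
    for p in profiles:
        subtypes = [s for s in SUBTYPES if p.validated[s]] or list(SUBTYPES)
        eff = max(p.pct_inhibition.get(s, -np.inf) for s in subtypes)
        by_group.setdefault(p.group, []).append(eff)
    for g in GROUPS:
        vals = np.array(by_group.get(g, []), dtype=float)
        rows.append({
            "group": g,
            "n": vals.size,
            "n_above_75pct": int((vals > 75.0).sum()),
            "n_at_or_below_50pct": int((vals <= 50.0).sum()),
            "median_pct_inhibition": float(np.median(vals)) if vals.size else np.nan,
        })
    return pd.DataFrame(rows)
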