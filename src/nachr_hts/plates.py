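"""Plate geometry, well roles, compound manifests, and plate-file I/O.

A screening plate is a 384-well (16 x 24) grid addressed in plate-reader
convention: row letter A..P, 1-based column number (``A1`` .. ``P24``).
Because membrane-potential plates show an edge artifact, every well within
two rows or two columns of the plate border is excluded from use, leaving a
12 x 20 = 240-well interior for test compounds and in-plate controls.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import CapacityError, DataError, FormatError

ROW_LABELS = string.ascii_uppercase[:16]
N_ROWS = 16
N_COLS = 24
EDGE_BAND = 2  # wells within 2 rows/cols of any edge are excluded

#: Default final assay concentration for test compounds (molar).
DEFAULT_ASSAY_CONC = 10e-6

#: Antagonist-control titration: 12-point, 3-fold serial dilution from 100 uM
#: (spans 100 uM down to ~0.56 nM).
ANTAG_TOP_CONC = 100e-6
ANTAG_DILUTION = 3.0
ANTAG_POINTS = 12


class Role(str, Enum):
    TEST = "TEST"
    ZERO_CONTROL = "ZERO_CONTROL"        # DMSO only: zero-signal anchor
    POS_CONTROL = "POS_CONTROL"          # EC90 agonist: full-signal anchor
    ANTAG_CONTROL = "ANTAG_CONTROL"      # reference antagonist titration
    EDGE_EXCLUDED = "EDGE_EXCLUDED"
    EMPTY = "EMPTY"


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> plate-reader address like ``C3``."""
    return f"{ROW_LABELS[row]}{col + 1}"


def parse_well(name: str) -> tuple[int, int]:
    """Plate-reader address -> 0-based (row, col). Raises FormatError."""
    name = name.strip().upper()
    if not name or name[0] not in ROW_LABELS or not name[1:].isdigit():
        raise FormatError(f"malformed well address: {name!r}")
    row = ROW_LABELS.index(name[0])
    col = int(name[1:]) - 1
    if not (0 <= col < N_COLS):
        raise FormatError(f"column out of range in well address: {name!r}")
    return row, col


def all_wells(n_rows: int = N_ROWS, n_cols: int = N_COLS) -> list[str]:
    return [well_name(r, c) for r in range(n_rows) for c in range(n_cols)]


def is_edge(row: int, col: int, n_rows: int = N_ROWS, n_cols: int = N_COLS,
            band: int = EDGE_BAND) -> bool:
    return (row < band or row >= n_rows - band
            or col < band or col >= n_cols - band)


@dataclass
class PlateLayout:
    """Well roles plus per-well compound identity and concentration.

    ``role_map`` assigns every well exactly one :class:`Role`;
    ``compound_map``/``conc_map`` are defined only where meaningful
    (TEST and ANTAG_CONTROL wells).
    """

    n_rows: int = N_ROWS
    n_cols: int = N_COLS
    role_map: dict[str, Role] = field(default_factory=dict)
    compound_map: dict[str, str] = field(default_factory=dict)
    conc_map: dict[str, float] = field(default_factory=dict)

    def wells_with_role(self, role: Role) -> list[str]:
        return [w for w, r in self.role_map.items() if r is role]

    def role_counts(self) -> dict[Role, int]:
        counts = {role: 0 for role in Role}
        for r in self.role_map.values():
            counts[r] += 1
        return counts

    def validate(self) -> None:
        expected = set(all_wells(self.n_rows, self.n_cols))
        if set(self.role_map) != expected:
            raise DataError("role_map must cover every well exactly once")
        for w, r in self.role_map.items():
            if r is Role.EDGE_EXCLUDED and w in self.compound_map:
                raise DataError(f"edge-excluded well {w} carries a compound")

    def with_compounds(self, assignments: Mapping[str, str],
                       conc: float = DEFAULT_ASSAY_CONC) -> "PlateLayout":
        """Return a copy with compounds placed into TEST wells.

        TEST wells not named in ``assignments`` become EMPTY (short final
        plate of a library split).
        """
        role_map = dict(self.role_map)
        compound_map = dict(self.compound_map)
        conc_map = dict(self.conc_map)
        for w, cid in assignments.items():
            if role_map.get(w) is not Role.TEST:
                raise DataError(f"cannot assign compound to non-TEST well {w}")
            compound_map[w] = cid
            conc_map[w] = conc
        for w in self.wells_with_role(Role.TEST):
            if w not in compound_map:
                role_map[w] = Role.EMPTY
        return PlateLayout(self.n_rows, self.n_cols, role_map, compound_map, conc_map)

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in all_wells(self.n_rows, self.n_cols):
            rows.append({
                "well": w,
                "role": self.role_map[w].value,
                "compound_id": self.compound_map.get(w, ""),
                "conc_M": self.conc_map.get(w, ""),
            })
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlateLayout":
        df = pd.read_csv(path, dtype={"well": str, "role": str, "compound_id": str},
                         keep_default_na=False,
                     float_precision="round_trip")
        required = {"well", "role", "compound_id", "conc_M"}
        if not required.issubset(df.columns):
            raise FormatError(f"layout file missing columns {required - set(df.columns)}")
        role_map, compound_map, conc_map = {}, {}, {}
        for rec in df.itertuples(index=False):
            parse_well(rec.well)
            role_map[rec.well] = Role(rec.role)
            if rec.compound_id:
                compound_map[rec.well] = rec.compound_id
            if rec.conc_M != "":
                conc_map[rec.well] = float(rec.conc_M)
        layout = cls(role_map=role_map, compound_map=compound_map, conc_map=conc_map)
        layout.validate()
        return layout


def antag_titration_concs(top: float = ANTAG_TOP_CONC, dilution: float = ANTAG_DILUTION,
                          points: int = ANTAG_POINTS) -> np.ndarray:
    """Serial-dilution series, highest first (100 uM .. ~0.565 nM by default)."""
    return top / dilution ** np.arange(points)


def default_layout(n_controls: int = 12, titration_points: int = ANTAG_POINTS) -> PlateLayout:
    """Standard 384-well antagonist-screen template.

    Border-2 wells are EDGE_EXCLUDED.  Controls occupy fixed interior
    columns so the template is reproducible: zero-signal (DMSO) controls in
    column 3, positive-signal (EC90 agonist) controls in column 4, and the
    reference-antagonist titration in column 5 (highest concentration in
    row C, 3-fold steps down to row N).  The remaining interior wells are
    TEST (204 for the 12/12/12 defaults).
    """
    interior = [(r, c) for r in range(N_ROWS) for c in range(N_COLS)
                if not is_edge(r, c)]
    n_needed = 2 * n_controls + titration_points
    if n_needed > len(interior) or n_controls > N_ROWS - 2 * EDGE_BAND or \
            titration_points > N_ROWS - 2 * EDGE_BAND:
        raise CapacityError(
            f"{n_needed} control wells requested; interior holds {len(interior)} "
            f"with at most {N_ROWS - 2 * EDGE_BAND} per column")

    role_map: dict[str, Role] = {}
    conc_map: dict[str, float] = {}
    for r in range(N_ROWS):
        for c in range(N_COLS):
            role_map[well_name(r, c)] = (
                Role.EDGE_EXCLUDED if is_edge(r, c) else Role.TEST)

    interior_rows = range(EDGE_BAND, N_ROWS - EDGE_BAND)
    for i, r in enumerate(interior_rows):
        if i < n_controls:
            role_map[well_name(r, EDGE_BAND)] = Role.ZERO_CONTROL       # col 3
            role_map[well_name(r, EDGE_BAND + 1)] = Role.POS_CONTROL    # col 4
    concs = antag_titration_concs(points=titration_points)
    for i, r in enumerate(interior_rows):
        if i < titration_points:
            w = well_name(r, EDGE_BAND + 2)                             # col 5
            role_map[w] = Role.ANTAG_CONTROL
            conc_map[w] = float(concs[i])

    return PlateLayout(role_map=role_map, conc_map=conc_map)


@dataclass
class RawPlateRead:
    """Two fluorescence reads per well: baseline (pre-compound) and final."""

    plate_id: str
    run_id: str
    subtype: str
    baseline: dict[str, float]
    final: dict[str, float]

    def validate(self) -> None:
        if set(self.baseline) != set(self.final):
            raise DataError("baseline and final reads cover different wells")
        for w, v in list(self.baseline.items()) + list(self.final.items()):
            if not np.isfinite(v) or v < 0:
                raise DataError(f"non-finite or negative fluorescence in well {w}: {v}")

    def to_frame(self) -> pd.DataFrame:
        wells = sorted(self.baseline, key=parse_well)
        return pd.DataFrame({
            "well": wells,
            "baseline": [self.baseline[w] for w in wells],
            "final": [self.final[w] for w in wells],
        })

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.insert(0, "subtype", self.subtype)
        df.insert(0, "run_id", self.run_id)
        df.insert(0, "plate_id", self.plate_id)
        df.to_csv(path, index=False)


def read_plate_csv(path: str | Path, plate_id: str | None = None,
                   run_id: str | None = None, subtype: str | None = None) -> RawPlateRead:
    """Read one plate's two-read CSV (columns: well, baseline, final).

    Optional ``plate_id``/``run_id``/``subtype`` columns written by
    :meth:`RawPlateRead.to_csv` are picked up when present; keyword
    arguments override them.
    """
    df = pd.read_csv(path, dtype={"well": str}, keep_default_na=False,
                     float_precision="round_trip")
    required = {"well", "baseline", "final"}
    if not required.issubset(df.columns):
        raise FormatError(f"plate file missing columns {sorted(required - set(df.columns))}")
    if df["well"].duplicated().any():
        dup = df.loc[df["well"].duplicated(), "well"].iloc[0]
        raise DataError(f"duplicate well {dup!r} in {path}")

    def meta(col: str, override: str | None) -> str:
        if override is not None:
            return override
        if col in df.columns and len(df):
            return str(df[col].iloc[0])
        return ""

    baseline, final = {}, {}
    for rec in df.itertuples(index=False):
        parse_well(rec.well)
        b, f = float(rec.baseline), float(rec.final)
        if b < 0 or f < 0:
            raise DataError(f"negative fluorescence in well {rec.well}")
        baseline[rec.well] = b
        final[rec.well] = f
    read = RawPlateRead(meta("plate_id", plate_id), meta("run_id", run_id),
                        meta("subtype", subtype), baseline, final)
    read.validate()
    return read


@dataclass
class CompoundManifest:
    """Screening-deck manifest: one row per compound."""

    table: pd.DataFrame  # columns: compound_id, source_well, stock_conc_M, assay_conc_M

    COLUMNS = ("compound_id", "source_well", "stock_conc_M", "assay_conc_M")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise FormatError(f"manifest missing columns {sorted(missing)}")
        if self.table["compound_id"].duplicated().any():
            raise DataError("duplicate compound_id in manifest")
        if (self.table["assay_conc_M"] <= 0).any():
            raise DataError("assay_conc_M must be positive")

    @property
    def compound_ids(self) -> list[str]:
        return list(self.table["compound_id"])

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CompoundManifest":
        return cls(pd.read_csv(path, dtype={"compound_id": str, "source_well": str}))


def make_manifest(n_compounds: int, stock_conc: float = 10e-3,
                  assay_conc: float = DEFAULT_ASSAY_CONC) -> CompoundManifest:
    """Synthetic manifest of ``n_compounds`` sequential compound ids."""
    width = max(4, len(str(n_compounds)))
    ids = [f"CMP{i + 1:0{width}d}" for i in range(n_compounds)]
    return CompoundManifest(pd.DataFrame({
        "compound_id": ids,
        "source_well": [f"S{(i // 384) + 1:02d}:{all_wells()[i % 384]}" for i in range(n_compounds)],
        "stock_conc_M": stock_conc,
        "assay_conc_M": assay_conc,
    }))


def split_across_plates(compound_ids: Iterable[str], layout: PlateLayout) -> list[dict[str, str]]:
    """Chunk a compound list into per-plate well->compound assignments.

    TEST wells are filled in row-major order; the last plate may be short.
    """
    test_wells = sorted(layout.wells_with_role(Role.TEST), key=parse_well)
    ids = list(compound_ids)
    per = len(test_wells)
    return [dict(zip(test_wells, ids[i:i + per])) for i in range(0, len(ids), per)]
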