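"""Per-tooth score records and group summary statistics.

The study dataset (35 single-rooted permanent teeth from 23 medieval
individuals, Sains-en-Gohelle, France) ships with the package as a
comma-separated fixture mirroring the published characterization table:
visual scores (Molnar wear, Si/Sta caries, pulp exposure, impaction,
hypercementosis score, bone context), micro-CT thickness summaries
(MAX THI, LOC MAX, LOC MIN, PREF LOC, apposition shape) and confocal
topography summaries (MAX VE, aspect triple).

User tables in the same schema are accepted by :func:`load_records`.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

ETIOLOGIES = ("IMP", "INF", "HYPO", "HYPER", "MIX")
SEXES = ("F", "M", "I", "MD")
SIDES = ("m", "d", "<", ">")
THIRDS = (1, 2, 3)

#: FDI position digit -> tooth type (I1 central incisor ... P4 second premolar)
_TOOTH_TYPE = {1: "I1", 2: "I2", 3: "C", 4: "P3", 5: "P4"}


class FixtureError(ValueError):
    """Raised when a record table fails validation; names row and field."""


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (printed-table style)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


_LOC_TOKEN = re.compile(r"^([123]*)([md<>]*)$")


def parse_localization(code: str) -> tuple[set[int], set[str], bool]:
    """Parse a LOC MAX / LOC MIN code into (thirds, sides, ok).

    Codes combine root thirds (1 apical, 2 middle, 3 cervical) with side
    letters (m mesial, d distal, ``<`` buccal, ``>`` lingual), e.g. ``"2d"``,
    ``"1>d +2m"``, ``"d>"``.  A bare ``"No"`` (no identifiable side) parses to
    empty sets.  Unparseable codes keep the verbatim text upstream and return
    ``ok=False``.
    """
    thirds: set[int] = set()
    sides: set[str] = set()
    text = code.strip()
    if text.lower() in ("no", ""):
        return thirds, sides, True
    for token in re.split(r"[\s+]+", text):
        m = _LOC_TOKEN.match(token)
        if not m:
            return set(), set(), False
        thirds.update(int(c) for c in m.group(1))
        sides.update(m.group(2))
    return thirds, sides, True


@dataclass(frozen=True)
class ToothRecord:
    """One row of the characterization table (one tooth)."""

    specimen_id: str
    fdi: int
    ba_code: str
    sex: str
    age_class: str
    etiology: str
    wear_deg: int
    wear_dir: int
    wear_for: int
    caries_si: int | None
    caries_sta: int | None
    pulp_exp: str            # none / W / C / M
    impacted: bool
    hc_score: str            # "type.stage.form", e.g. "3.3.m"
    fen: bool
    cal: bool
    nt: str                  # 0 / 1m / 1d / 2 / NA
    ant: int                 # 0 impacted, 1 present, 2 ante-mortem loss, 3 NA
    max_thi_um: float
    loc_max: str
    loc_min: str
    pref: bool
    shape_note: str          # NOD/Nds/OG/RID/LSP/RES/FR/SE/CAR/W/none
    note_verbatim: str
    roi_loc: str
    max_ve_um: float | None
    aspect: str | None       # e.g. "+S2"
    roi_note: str
    of_loc: str
    of_max_ve_um: float | None
    of_aspect: str | None
    of_note: str
    excluded: bool
    loc_max_parse_ok: bool = field(default=True, compare=False)

    @property
    def tooth_id(self) -> str:
        return f"{self.specimen_id}_{self.fdi}"

    @property
    def tooth_type(self) -> str:
        return _TOOTH_TYPE[self.fdi % 10]

    @property
    def loc_max_parsed(self) -> tuple[set[int], set[str]]:
        thirds, sides, _ = parse_localization(self.loc_max)
        return thirds, sides

    @property
    def hc_stage(self) -> int:
        return int(self.hc_score.split(".")[1])

    @property
    def caries_present(self) -> bool:
        return self.caries_si is not None


@dataclass(frozen=True)
class GroupSummary:
    """Mean / SD (n-1) / range of one numeric field within one etiology group."""

    group: str
    n: int
    mean: float
    sd: float | None
    min: float
    max: float

    def rounded(self) -> dict[str, int | None]:
        """Values rounded half-away-from-zero to integer µm, as printed."""
        return {
            "n": self.n,
            "mean": round_half_away(self.mean),
            "sd": None if self.sd is None else round_half_away(self.sd),
            "min": round_half_away(self.min),
            "max": round_half_away(self.max),
        }


_SHAPE_NOTES = {"NOD", "Nds", "OG", "RID", "LSP", "RES", "FR", "SE", "CAR", "W", "none"}


def _parse_row(row: dict[str, str], lineno: int) -> ToothRecord:
    def fail(col: str, msg: str) -> FixtureError:
        return FixtureError(f"row {lineno} ({row.get('specimen_id')}_{row.get('fdi')}), field '{col}': {msg}")

    def opt_float(col: str) -> float | None:
        v = row[col].strip()
        if v == "":
            return None
        try:
            return float(v)
        except ValueError:
            raise fail(col, f"not numeric: {v!r}") from None

    def opt_int(col: str) -> int | None:
        v = row[col].strip()
        if v == "":
            return None
        try:
            return int(v)
        except ValueError:
            raise fail(col, f"not an integer: {v!r}") from None

    def boolean(col: str) -> bool:
        v = row[col].strip().lower()
        if v in ("1", "yes", "true"):
            return True
        if v in ("0", "no", "false"):
            return False
        raise fail(col, f"not boolean: {row[col]!r}")

    try:
        fdi = int(row["fdi"])
    except ValueError:
        raise fail("fdi", f"not an integer: {row['fdi']!r}") from None
    if fdi % 10 not in _TOOTH_TYPE:
        raise fail("fdi", f"not a single-rooted tooth position: {fdi}")
    if row["sex"] not in SEXES:
        raise fail("sex", f"unknown sex code {row['sex']!r}")
    if row["etiology"] not in ETIOLOGIES:
        raise fail("etiology", f"unknown etiology {row['etiology']!r}")
    wear = {}
    for col, hi in (("wear_deg", 8), ("wear_dir", 8), ("wear_for", 6)):
        v = opt_int(col)
        if v is None or not 0 <= v <= hi:
            raise fail(col, f"outside 0..{hi}: {row[col]!r}")
        wear[col] = v
    caries_si, caries_sta = opt_int("caries_si"), opt_int("caries_sta")
    if (caries_si is None) != (caries_sta is None):
        raise fail("caries_si", "caries site and stage must be paired")
    if row["pulp_exp"] not in ("none", "W", "C", "M"):
        raise fail("pulp_exp", f"unknown pulp exposure code {row['pulp_exp']!r}")
    hc = row["hc_score"]
    if not re.match(r"^[123]\.[1234]\.[mM]$", hc):
        raise fail("hc_score", f"not a type.stage.form code: {hc!r}")
    if row["nt"] not in ("0", "1m", "1d", "2", "NA"):
        raise fail("nt", f"unknown neighboring-tooth-loss code {row['nt']!r}")
    ant = opt_int("ant")
    if ant is None or ant not in (0, 1, 2, 3):
        raise fail("ant", f"antagonist code must be 0..3: {row['ant']!r}")
    max_thi = opt_float("max_thi_um")
    if max_thi is None or max_thi <= 0:
        raise fail("max_thi_um", f"must be a positive thickness in um: {row['max_thi_um']!r}")
    shape = row["shape_note"]
    if shape not in _SHAPE_NOTES:
        raise fail("shape_note", f"unknown apposition/surface note {shape!r}")
    max_ve = opt_float("max_ve_um")
    if max_ve is not None and max_ve < 0:
        raise fail("max_ve_um", "negative elevation")
    aspect = row["aspect"].strip() or None
    if aspect is not None and not re.match(r"^[+-][SR][12]$", aspect):
        raise fail("aspect", f"not a (+/-)(S/R)(1/2) triple: {aspect!r}")
    of_aspect = row["of_aspect"].strip() or None
    if of_aspect is not None and not re.match(r"^[+-][SR][12]$", of_aspect):
        raise fail("of_aspect", f"not a (+/-)(S/R)(1/2) triple: {of_aspect!r}")
    _, _, loc_ok = parse_localization(row["loc_max"])
    return ToothRecord(
        specimen_id=row["specimen_id"],
        fdi=fdi,
        ba_code=row["ba_code"],
        sex=row["sex"],
        age_class=row["age_class"],
        etiology=row["etiology"],
        wear_deg=wear["wear_deg"],
        wear_dir=wear["wear_dir"],
        wear_for=wear["wear_for"],
        caries_si=caries_si,
        caries_sta=caries_sta,
        pulp_exp=row["pulp_exp"],
        impacted=boolean("impacted"),
        hc_score=hc,
        fen=boolean("fen"),
        cal=boolean("cal"),
        nt=row["nt"],
        ant=ant,
        max_thi_um=max_thi,
        loc_max=row["loc_max"],
        loc_min=row["loc_min"],
        pref=boolean("pref"),
        shape_note=shape,
        note_verbatim=row["note_verbatim"],
        roi_loc=row["roi_loc"],
        max_ve_um=max_ve,
        aspect=aspect,
        roi_note=row["roi_note"],
        of_loc=row["of_loc"],
        of_max_ve_um=opt_float("of_max_ve_um"),
        of_aspect=of_aspect,
        of_note=row["of_note"],
        excluded=boolean("excluded"),
        loc_max_parse_ok=loc_ok,
    )


def load_records(path: str | Path) -> list[ToothRecord]:
    """Load a record table in the fixture schema from ``path``."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        rows = []
        for i, row in enumerate(reader, start=2):
            if None in row or any(v is None for v in row.values()):
                raise FixtureError(f"row {i}: wrong number of fields")
            rows.append(_parse_row(row, i))
    if not rows:
        raise FixtureError("empty record table")
    return rows


def load_fixture() -> list[ToothRecord]:
    """Load the packaged 35-tooth study table, with validation.

    Two teeth (Sp1010_44, Sp1230_44) carry ``excluded=True``: micro-CT
    inspection revealed two coalescent roots concealed by cementum, so they
    were dropped from the single-rooted analysis sample of 33.
    """
    src = resources.files("cementum").joinpath("data/table2.csv")
    with resources.as_file(src) as p:
        records = load_records(p)
    n_spec = len({r.specimen_id for r in records})
    if len(records) != 35 or n_spec != 23:
        raise FixtureError(
            f"fixture must hold 35 teeth from 23 individuals, got {len(records)}/{n_spec}"
        )
    if sum(r.excluded for r in records) != 2:
        raise FixtureError("fixture must flag exactly 2 excluded two-rooted teeth")
    return records


def included(records: Iterable[ToothRecord]) -> list[ToothRecord]:
    return [r for r in records if not r.excluded]


def group_summary(
    records: Sequence[ToothRecord],
    field_name: str = "max_thi_um",
    exclude: Callable[[ToothRecord], bool] | None = None,
) -> dict[str, GroupSummary]:
    """Per-etiology mean/SD/range of a numeric record field.

    Records flagged ``excluded`` (two-rooted), records missing the field, and
    records matched by the optional ``exclude`` predicate (e.g. confocal
    acquisitions taken on a cementum fracture) are left out.  SD uses the
    n−1 denominator and is ``None`` for groups of a single tooth; groups
    with no usable record are absent from the result.
    """
    out: dict[str, GroupSummary] = {}
    for group in ETIOLOGIES:
        values = [
            float(getattr(r, field_name))
            for r in records
            if r.etiology == group
            and not r.excluded
            and getattr(r, field_name) is not None
            and not (exclude is not None and exclude(r))
        ]
        if not values:
            continue
        n = len(values)
        mean = sum(values) / n
        sd = None
        if n > 1:
            sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
        out[group] = GroupSummary(group, n, mean, sd, min(values), max(values))
    return out


def fracture_roi(record: ToothRecord) -> bool:
    """True when the confocal region of interest fell on a cementum fracture.

    Those acquisitions (Sp17_15 in the hypofunctional group, Sp591_12 in the
    hyperfunctional group) measure the fracture relief, not the cementum
    surface, and are excluded from group MAX VE averages.
    """
    return record.roi_note == "FR"
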