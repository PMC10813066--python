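"""Visual-examination scoring systems and the derived hypercementosis score.

Wear is graded with the Molnar system (degree 1–8, direction, form; 0 encodes
"crown not preserved"), caries with the Si/Sta site-and-stage pair, and the
hypercementosis score is the composite ``type.stage.form`` triple:

* type — 1 diffuse, 2 focal only, 3 mixed diffuse + focal;
* stage — contiguous extent of apposition in root thirds (1 apical only,
  2 apical+middle, 3 all three), or 4 when the cemento-enamel junction is
  damaged/absent and the whole preserved root is affected;
* form — m moderate / M marked.

``validate_record`` checks cross-field consistency of human-entered codes;
``score_hypercementosis`` derives the composite score from a computed
thickness field.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .records import ToothRecord


@dataclass(frozen=True)
class WearScore:
    deg: int
    dir: int
    form: int

    def __post_init__(self):
        for name, v, hi in (("deg", self.deg, 8), ("dir", self.dir, 8), ("form", self.form, 6)):
            if not 0 <= v <= hi:
                raise ValueError(f"wear {name} outside 0..{hi}: {v}")


@dataclass(frozen=True)
class CariesScore:
    site: int
    stage: int

    def __post_init__(self):
        if not 1 <= self.site <= 3:
            raise ValueError(f"caries site outside 1..3: {self.site}")
        if not 1 <= self.stage <= 4:
            raise ValueError(f"caries stage outside 1..4: {self.stage}")


@dataclass(frozen=True)
class HCScore:
    """Composite hypercementosis score, serialized as ``"type.stage.form"``."""

    type: int
    stage: int
    form: str

    def __post_init__(self):
        if self.type not in (1, 2, 3):
            raise ValueError(f"hypercementosis type must be 1..3: {self.type}")
        if self.stage not in (1, 2, 3, 4):
            raise ValueError(f"hypercementosis stage must be 1..4: {self.stage}")
        if self.form not in ("m", "M"):
            raise ValueError(f"hypercementosis form must be m or M: {self.form!r}")

    def serialize(self) -> str:
        return f"{self.type}.{self.stage}.{self.form}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize()

    @classmethod
    def parse(cls, text: str) -> "HCScore":
        m = re.match(r"^([123])\.([1234])\.([mM])$", text.strip())
        if not m:
            raise ValueError(f"not a type.stage.form hypercementosis code: {text!r}")
        return cls(int(m.group(1)), int(m.group(2)), m.group(3))


@dataclass(frozen=True)
class Violation:
    record_id: str
    field: str
    rule: str

    def __str__(self) -> str:
        return f"{self.record_id}: {self.field}: {self.rule}"


def validate_record(record: ToothRecord) -> list[Violation]:
    """Cross-field consistency checks on one visually scored record.

    Violations are returned, never raised: an archeological table legitimately
    carries odd rows and the caller decides what is fatal.
    """
    v: list[Violation] = []

    def bad(field: str, rule: str) -> None:
        v.append(Violation(record.tooth_id, field, rule))

    if record.wear_deg == 1 and (record.wear_dir != 1 or record.wear_for != 1):
        bad("wear_dir", "degree 1 (no wear) requires natural direction and form (1/1)")
    if record.wear_deg == 0 and (record.wear_dir != 0 or record.wear_for != 0):
        bad("wear_dir", "degree 0 (crown not preserved) requires direction=form=0")
    if (record.caries_si is None) != (record.caries_sta is None):
        bad("caries_si", "caries site and stage must both be set or both absent")
    if record.impacted:
        if (record.wear_deg, record.wear_dir, record.wear_for) != (1, 1, 1):
            bad("wear_deg", "an impacted (unerupted) tooth cannot be worn: wear must be 1/1/1")
        if record.ant != 0:
            bad("ant", "antagonist is not scorable for an impacted tooth (ANT must be 0)")
        if record.caries_present:
            bad("caries_si", "an unerupted tooth cannot carry a carious lesion")
    # crownless root with terminal-stage caries: pulp is necessarily open
    if record.wear_deg == 0 and record.caries_sta == 4 and record.pulp_exp == "none":
        bad("pulp_exp", "crown lost to terminal caries implies pulp exposure (W/C/M)")
    return v


def score_hypercementosis(
    third_means_um: dict[int, float],
    max_thi_um: float,
    has_focal_component: bool,
    cej_present: bool = True,
    baseline_um: float = 500.0,
    marked_um: float = 1500.0,
) -> HCScore:
    """Derive the composite score from per-third mean thickness.

    ``third_means_um`` maps root third (1 apical, 2 middle, 3 cervical) to the
    mean cementum thickness of that third.  The stage is the longest apically
    anchored contiguous run of thirds whose mean exceeds ``baseline_um``;
    roots without a preserved cemento-enamel junction whose whole preserved
    length exceeds the baseline are stage 4.  Type is 1 (diffuse) without a
    focal shape component and 3 (mixed) with one; type 2 (purely focal) exists
    in the source scoring system but is never produced by this derivation.
    Form is M (marked) when the maximal thickness reaches ``marked_um``.

    Both thresholds are configuration keys: the source system's exact cuts
    are not published, so they are a parameterized reconstruction.
    """
    affected = {t for t, m in third_means_um.items() if m > baseline_um}
    span = 0
    for t in (1, 2, 3):
        if t in third_means_um and t in affected and span == t - 1:
            span = t
        elif t in third_means_um:
            break
    if not cej_present and affected == set(third_means_um):
        stage = 4
    else:
        stage = max(span, 1)
    hc_type = 3 if has_focal_component else 1
    form = "M" if max_thi_um >= marked_um else "m"
    return HCScore(hc_type, stage, form)
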