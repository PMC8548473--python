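"""Closed inventories of Hebrew verb morphology.

Hebrew verbs are built non-linearly from a consonantal *root* (usually
tri-literal, e.g. ``l-m-d`` "learn") interdigitated into one of seven
*binyan* conjugations.  Each binyan is a bundle of five temporal-category
templates (past, present, future, imperative, infinitive); two binyanim
(Hufal, Pual) lack imperative and infinitive forms, leaving 31 defined
binyan-temporal templates.  The verb stem is further inflected linearly
for person/number/gender agreement, whose applicability depends on the
temporal category (infinitives carry no agreement, present-tense forms
mark number and gender but not person, and several person/number cells
syncretize gender).  Enumerating the agreement cells per temporal
category yields 25 inflection categories for a binyan with a full
paradigm, 21 for Hufal and Pual.

This module encodes those closed inventories and the label grammar used
for network nodes: a root node is a hyphen-joined radical string
(``l-m-d``) and an inflected-pattern node is a dot-joined categorical
label (``Qal.Present.Fm.Sg``).  The two grammars are disjoint by
construction, so node labels never collide.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence


class Binyan(enum.Enum):
    """The seven binyan conjugations."""

    QAL = "Qal"
    NIFAL = "Nifal"
    HIFIL = "Hifil"
    HUFAL = "Hufal"
    PIEL = "Piel"
    PUAL = "Pual"
    HITPAEL = "Hitpael"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class TemporalCategory(enum.Enum):
    """The five temporal categories of a binyan paradigm."""

    PAST = "Past"
    PRESENT = "Present"
    FUTURE = "Future"
    IMPERATIVE = "Imperative"
    INFINITIVE = "Infinitive"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


BINYAN_ORDER: tuple[Binyan, ...] = tuple(Binyan)
TEMPORAL_ORDER: tuple[TemporalCategory, ...] = tuple(TemporalCategory)

#: Binyan-temporal stem templates; ``C`` slots stand for root radicals.
#: The four (Hufal/Pual x Imperative/Infinitive) cells are undefined.
TEMPLATES: dict[tuple[Binyan, TemporalCategory], str] = {
    (Binyan.QAL, TemporalCategory.PAST): "CaCaC",
    (Binyan.QAL, TemporalCategory.PRESENT): "CoCeC",
    (Binyan.QAL, TemporalCategory.FUTURE): "yiCCoC",
    (Binyan.QAL, TemporalCategory.IMPERATIVE): "CCoC",
    (Binyan.QAL, TemporalCategory.INFINITIVE): "liCCoC",
    (Binyan.NIFAL, TemporalCategory.PAST): "niCCaC",
    (Binyan.NIFAL, TemporalCategory.PRESENT): "niCCaC",
    (Binyan.NIFAL, TemporalCategory.FUTURE): "yiCaCeC",
    (Binyan.NIFAL, TemporalCategory.IMPERATIVE): "hiCaCeC",
    (Binyan.NIFAL, TemporalCategory.INFINITIVE): "lehiCaCeC",
    (Binyan.HIFIL, TemporalCategory.PAST): "hiCCiC",
    (Binyan.HIFIL, TemporalCategory.PRESENT): "maCCiC",
    (Binyan.HIFIL, TemporalCategory.FUTURE): "yaCCiC",
    (Binyan.HIFIL, TemporalCategory.IMPERATIVE): "haCCeC",
    (Binyan.HIFIL, TemporalCategory.INFINITIVE): "lehaCCiC",
    (Binyan.HUFAL, TemporalCategory.PAST): "huCCaC",
    (Binyan.HUFAL, TemporalCategory.PRESENT): "muCCaC",
    (Binyan.HUFAL, TemporalCategory.FUTURE): "yuCCaC",
    (Binyan.PIEL, TemporalCategory.PAST): "CiCeC",
    (Binyan.PIEL, TemporalCategory.PRESENT): "meCaCeC",
    (Binyan.PIEL, TemporalCategory.FUTURE): "yeCaCeC",
    (Binyan.PIEL, TemporalCategory.IMPERATIVE): "CaCeC",
    (Binyan.PIEL, TemporalCategory.INFINITIVE): "leCaCeC",
    (Binyan.PUAL, TemporalCategory.PAST): "CuCaC",
    (Binyan.PUAL, TemporalCategory.PRESENT): "meCuCaC",
    (Binyan.PUAL, TemporalCategory.FUTURE): "yeCuCaC",
    (Binyan.HITPAEL, TemporalCategory.PAST): "hitCaCeC",
    (Binyan.HITPAEL, TemporalCategory.PRESENT): "mitCaCeC",
    (Binyan.HITPAEL, TemporalCategory.FUTURE): "yitCaCeC",
    (Binyan.HITPAEL, TemporalCategory.IMPERATIVE): "hitCaCeC",
    (Binyan.HITPAEL, TemporalCategory.INFINITIVE): "lehitCaCeC",
}

#: Canonical ASCII romanization for glyphs that break naive encodings.
ROMANIZATION_MAP: dict[str, str] = {"ʔ": "?", "ˀ": "?", "ℏ": "H", "ḥ": "H"}

_RADICAL_RE = re.compile(r"^[a-zA-Z?]{1,2}$")


class MorphologyError(ValueError):
    """Raised for malformed roots, labels or template interpolations."""


@dataclass(frozen=True, order=True)
class Root:
    """A consonantal root skeleton, e.g. ``Root.parse("l-m-d")``."""

    radicals: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 2 <= len(self.radicals) <= 4:
            raise MorphologyError(
                f"a root needs 2-4 radicals, got {len(self.radicals)}: {self.radicals!r}"
            )
        for r in self.radicals:
            if not _RADICAL_RE.match(r):
                raise MorphologyError(f"invalid radical {r!r} in {self.radicals!r}")

    @property
    def label(self) -> str:
        return "-".join(self.radicals)

    @classmethod
    def parse(cls, label: str) -> "Root":
        for glyph, ascii_ in ROMANIZATION_MAP.items():
            label = label.replace(glyph, ascii_)
        parts = tuple(p for p in label.strip().split("-") if p)
        return cls(parts)

    def format(self, display_map: Optional[dict[str, str]] = None) -> str:
        """Render the label, optionally mapping ASCII stand-ins back to glyphs."""
        if not display_map:
            return self.label
        return "-".join("".join(display_map.get(c, c) for c in r) for r in self.radicals)

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class BinyanTemporalPattern:
    """One defined cell of the binyan x temporal-category template table."""

    binyan: Binyan
    temporal: TemporalCategory

    def __post_init__(self) -> None:
        if (self.binyan, self.temporal) not in TEMPLATES:
            raise MorphologyError(
                f"undefined binyan-temporal cell: {self.binyan.value}.{self.temporal.value}"
            )

    @property
    def template(self) -> str:
        return TEMPLATES[(self.binyan, self.temporal)]

    @property
    def label(self) -> str:
        return f"{self.binyan.value}.{self.temporal.value}"


@dataclass(frozen=True)
class AgreementFeatures:
    """Person/number/gender agreement; ``None`` marks an unexpressed feature."""

    person: Optional[int] = None
    number: Optional[str] = None
    gender: Optional[str] = None

    def __post_init__(self) -> None:
        if self.person not in (None, 1, 2, 3):
            raise MorphologyError(f"invalid person: {self.person!r}")
        if self.number not in (None, "Sg", "Pl"):
            raise MorphologyError(f"invalid number: {self.number!r}")
        if self.gender not in (None, "Masc", "Fm"):
            raise MorphologyError(f"invalid gender: {self.gender!r}")

    @property
    def label_parts(self) -> tuple[str, ...]:
        parts: list[str] = []
        if self.person is not None:
            parts.append(str(self.person))
        if self.gender is not None:
            parts.append(self.gender)
        if self.number is not None:
            parts.append(self.number)
        return tuple(parts)


# Agreement cells per temporal category.  Infinitives are uninflected;
# imperatives are implicitly 2nd person (person left unexpressed, and the
# plural imperative syncretizes gender); present tense marks number+gender
# only; 1st person and most plural non-present cells carry no gender.
AGREEMENT_CELLS: dict[TemporalCategory, tuple[AgreementFeatures, ...]] = {
    TemporalCategory.INFINITIVE: (AgreementFeatures(),),
    TemporalCategory.IMPERATIVE: (
        AgreementFeatures(number="Sg", gender="Masc"),
        AgreementFeatures(number="Sg", gender="Fm"),
        AgreementFeatures(number="Pl"),
    ),
    TemporalCategory.FUTURE: (
        AgreementFeatures(person=1, number="Sg"),
        AgreementFeatures(person=2, number="Sg", gender="Masc"),
        AgreementFeatures(person=2, number="Sg", gender="Fm"),
        AgreementFeatures(person=3, number="Sg", gender="Masc"),
        AgreementFeatures(person=3, number="Sg", gender="Fm"),
        AgreementFeatures(person=1, number="Pl"),
        AgreementFeatures(person=2, number="Pl"),
        AgreementFeatures(person=3, number="Pl"),
    ),
    TemporalCategory.PRESENT: (
        AgreementFeatures(number="Sg", gender="Masc"),
        AgreementFeatures(number="Sg", gender="Fm"),
        AgreementFeatures(number="Pl", gender="Masc"),
        AgreementFeatures(number="Pl", gender="Fm"),
    ),
    TemporalCategory.PAST: (
        AgreementFeatures(person=1, number="Sg"),
        AgreementFeatures(person=2, number="Sg", gender="Masc"),
        AgreementFeatures(person=2, number="Sg", gender="Fm"),
        AgreementFeatures(person=3, number="Sg", gender="Masc"),
        AgreementFeatures(person=3, number="Sg", gender="Fm"),
        AgreementFeatures(person=1, number="Pl"),
        AgreementFeatures(person=2, number="Pl", gender="Masc"),
        AgreementFeatures(person=2, number="Pl", gender="Fm"),
        AgreementFeatures(person=3, number="Pl"),
    ),
}


def agreement_applicability(temporal: TemporalCategory) -> tuple[bool, bool, bool]:
    """Whether (person, number, gender) agreement is marked for a temporal category.

    Returns the applicability row literally: imperatives count as
    person-marked (the addressee), even though the imperative cell labels
    leave the implicit 2nd person unexpressed.
    """
    table = {
        TemporalCategory.INFINITIVE: (False, False, False),
        TemporalCategory.IMPERATIVE: (True, True, True),
        TemporalCategory.FUTURE: (True, True, True),
        TemporalCategory.PRESENT: (False, True, True),
        TemporalCategory.PAST: (True, True, True),
    }
    return table[temporal]


@dataclass(frozen=True)
class InflectedPattern:
    """A binyan-temporal template plus agreement bundle; one node class."""

    pattern: BinyanTemporalPattern
    agreement: AgreementFeatures

    def __post_init__(self) -> None:
        if self.agreement not in AGREEMENT_CELLS[self.pattern.temporal]:
            raise MorphologyError(
                f"agreement {self.agreement} invalid for {self.pattern.temporal.value}"
            )

    @property
    def label(self) -> str:
        return ".".join((self.pattern.label,) + self.agreement.label_parts)

    @classmethod
    def parse(cls, label: str) -> "InflectedPattern":
        parts = label.split(".")
        if len(parts) < 2:
            raise MorphologyError(f"cannot parse pattern label: {label!r}")
        try:
            binyan = Binyan(parts[0])
            temporal = TemporalCategory(parts[1])
        except ValueError as exc:
            raise MorphologyError(f"cannot parse pattern label: {label!r}") from exc
        person: Optional[int] = None
        number: Optional[str] = None
        gender: Optional[str] = None
        for part in parts[2:]:
            if part in ("1", "2", "3"):
                person = int(part)
            elif part in ("Sg", "Pl"):
                number = part
            elif part in ("Masc", "Fm"):
                gender = part
            else:
                raise MorphologyError(f"unknown agreement token {part!r} in {label!r}")
        return cls(
            BinyanTemporalPattern(binyan, temporal),
            AgreementFeatures(person=person, number=number, gender=gender),
        )

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class WordformLink:
    """A root x inflected-pattern combination: one potential network edge."""

    root: Root
    inflected: InflectedPattern

    @property
    def labels(self) -> tuple[str, str]:
        return (self.root.label, self.inflected.label)


def build_pattern_inventory(binyan: Optional[Binyan] = None) -> list[BinyanTemporalPattern]:
    """All defined binyan-temporal templates, binyan-major / temporal-minor.

    The full inventory has 31 entries; four cells (Hufal and Pual
    imperative/infinitive) are undefined.
    """
    out = []
    for b in BINYAN_ORDER:
        if binyan is not None and b is not binyan:
            continue
        for t in TEMPORAL_ORDER:
            if (b, t) in TEMPLATES:
                out.append(BinyanTemporalPattern(b, t))
    return out


def build_inflection_inventory(binyan: Binyan) -> list[InflectedPattern]:
    """All inflected-pattern categories of one binyan.

    25 for a binyan with a full paradigm; 21 for Hufal and Pual, which
    lack the three imperative cells and the infinitive.
    """
    out = []
    for t in TEMPORAL_ORDER:
        if (binyan, t) not in TEMPLATES:
            continue
        btp = BinyanTemporalPattern(binyan, t)
        for agr in AGREEMENT_CELLS[t]:
            out.append(InflectedPattern(btp, agr))
    return out


def full_inflection_inventory() -> list[InflectedPattern]:
    """All inflected-pattern categories across the seven binyanim (167)."""
    out: list[InflectedPattern] = []
    for b in BINYAN_ORDER:
        out.extend(build_inflection_inventory(b))
    return out


def expand_paradigm(root: Root, binyan: Binyan) -> list[WordformLink]:
    """Cross one root with every inflected-pattern category of a binyan."""
    return [WordformLink(root, ip) for ip in build_inflection_inventory(binyan)]


def interpolate_template(template: str, root: Root) -> str:
    """Substitute root radicals into a template's C-slots, left to right.

    This is a naive symbolic rendering: real Hebrew surface forms undergo
    morpho-phonological stem changes (vowel alternation, spirantization)
    that are deliberately not modeled; node identity downstream is purely
    categorical and never uses this function.
    """
    n_slots = template.count("C")
    if n_slots != len(root.radicals):
        raise MorphologyError(
            f"template {template!r} has {n_slots} C-slots but root "
            f"{root.label!r} has {len(root.radicals)} radicals"
        )
    it = iter(root.radicals)
    return "".join(next(it) if ch == "C" else ch for ch in template)


def pattern_label(
    binyan: str, temporal: str, person: str = "", number: str = "", gender: str = ""
) -> str:
    """Canonical inflected-pattern node label from string-valued fields.

    Empty strings mark unexpressed features.  The label is validated by
    round-tripping through :meth:`InflectedPattern.parse`.
    """
    agr = AgreementFeatures(
        person=int(person) if person else None,
        number=number or None,
        gender=gender or None,
    )
    ip = InflectedPattern(
        BinyanTemporalPattern(Binyan(binyan), TemporalCategory(temporal)), agr
    )
    return ip.label


def inventory_to_json(path=None) -> dict:
    """Export templates, inflection categories and applicability as JSON."""
    doc = {
        "templates": {
            f"{b.value}.{t.value}": tmpl for (b, t), tmpl in TEMPLATES.items()
        },
        "inflection_categories": {
            b.value: [ip.label for ip in build_inflection_inventory(b)]
            for b in BINYAN_ORDER
        },
        "agreement_applicability": {
            t.value: dict(
                zip(("person", "number", "gender"), agreement_applicability(t))
            )
            for t in TEMPORAL_ORDER
        },
    }
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
    return doc
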