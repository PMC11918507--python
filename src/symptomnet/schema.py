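"""Item and scale metadata for questionnaire datasets.

An :class:`ItemSchema` records, for every questionnaire item, which scale it
belongs to (MADRS, YMRS, PRISE-M or a custom scale), its admissible integer
level range, and whether it only applies to one sex.  The default schema
bundled here describes the instrument set used to study residual mood
symptoms and self-reported side effects in euthymic bipolar disorder:

* PRISE-M — 32 patient-rated side-effect items coded 0 (absent),
  1 (bearable), 2 (painful); two items are sex-specific.
* MADRS — 10 clinician-rated depression items coded 0-6.
* YMRS — 11 clinician-rated mania items; seven coded 0-4 and four
  (irritability, speech, thought content, disruptive-aggressive behavior)
  coded 0-8.

After restricting to one sex and dropping the inapplicable sex-specific
item, 52 items remain — the analysis frame used throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

SCALES = ("MADRS", "YMRS", "PRISE-M", "custom")
SEX_SPECIFIC = ("none", "male_only", "female_only")


class SchemaError(ValueError):
    """Raised when a schema is malformed or inconsistent with data."""


@dataclass(frozen=True)
class Item:
    """A single questionnaire item."""

    item_id: str
    scale: str
    min_level: int = 0
    max_level: int = 2
    sex_specific: str = "none"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise SchemaError(f"unknown scale {self.scale!r} for item {self.item_id!r}")
        if self.sex_specific not in SEX_SPECIFIC:
            raise SchemaError(
                f"unknown sex_specific {self.sex_specific!r} for item {self.item_id!r}"
            )
        if self.min_level < 0 or self.max_level <= self.min_level:
            raise SchemaError(
                f"invalid level range [{self.min_level}, {self.max_level}] "
                f"for item {self.item_id!r}"
            )

    @property
    def n_levels(self) -> int:
        return self.max_level - self.min_level + 1

    def applies_to(self, sex: str) -> bool:
        """Whether this item is administered to subjects of the given sex."""
        if self.sex_specific == "none":
            return True
        return (self.sex_specific == "male_only") == (sex == "male")


@dataclass(frozen=True)
class ItemSchema:
    """Ordered collection of :class:`Item` with unique identifiers."""

    items: tuple[Item, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate item ids: {dupes}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def min_levels(self):
        import numpy as np

        return np.array([it.min_level for it in self.items], dtype=int)

    @property
    def max_levels(self):
        import numpy as np

        return np.array([it.max_level for it in self.items], dtype=int)

    def item(self, item_id: str) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise SchemaError(f"no item named {item_id!r}")

    def index(self, item_id: str) -> int:
        for k, it in enumerate(self.items):
            if it.item_id == item_id:
                return k
        raise SchemaError(f"no item named {item_id!r}")

    def scale_item_ids(self, scale: str) -> list[str]:
        return [it.item_id for it in self.items if it.scale == scale]

    @property
    def scales(self) -> list[str]:
        seen: list[str] = []
        for it in self.items:
            if it.scale not in seen:
                seen.append(it.scale)
        return seen

    def subset(self, item_ids: Sequence[str]) -> "ItemSchema":
        """Schema restricted to the given items, keeping schema order."""
        keep = set(item_ids)
        unknown = keep - set(self.item_ids)
        if unknown:
            raise SchemaError(f"unknown item ids: {sorted(unknown)}")
        return ItemSchema(tuple(it for it in self.items if it.item_id in keep))

    def for_sex(self, sex: str) -> "ItemSchema":
        """Drop items that do not apply to subjects of the given sex."""
        if sex not in ("male", "female"):
            raise SchemaError(f"sex must be 'male' or 'female', got {sex!r}")
        return ItemSchema(tuple(it for it in self.items if it.applies_to(sex)))

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return {
            "items": [
                {
                    "item_id": it.item_id,
                    "scale": it.scale,
                    "min_level": it.min_level,
                    "max_level": it.max_level,
                    "sex_specific": it.sex_specific,
                }
                for it in self.items
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ItemSchema":
        try:
            raw = d["items"]
        except (KeyError, TypeError) as exc:
            raise SchemaError("schema JSON must contain an 'items' list") from exc
        items = tuple(
            Item(
                item_id=str(r["item_id"]),
                scale=str(r["scale"]),
                min_level=int(r.get("min_level", 0)),
                max_level=int(r["max_level"]),
                sex_specific=str(r.get("sex_specific", "none")),
            )
            for r in raw
        )
        return cls(items)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ItemSchema":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _prise(item_id: str, sex_specific: str = "none") -> Item:
    return Item(item_id, "PRISE-M", 0, 2, sex_specific)


def _madrs(item_id: str) -> Item:
    return Item(item_id, "MADRS", 0, 6)


def _ymrs(item_id: str, max_level: int = 4) -> Item:
    return Item(item_id, "YMRS", 0, max_level)


#: 32 PRISE-M side-effect items (0-2), two of them sex-specific.
_PRISE_ITEMS = (
    _prise("asthenia"),
    _prise("loss_of_energy"),
    _prise("impaired_concentration"),
    _prise("trouble_falling_asleep"),
    _prise("increased_sleep"),
    _prise("restlessness"),
    _prise("agitation"),
    _prise("anxiety"),
    _prise("palpitations"),
    _prise("dizziness"),
    _prise("vertigo"),
    _prise("headache"),
    _prise("tremor"),
    _prise("impaired_motor_control"),
    _prise("sweating"),
    _prise("dry_mouth"),
    _prise("nausea"),
    _prise("vomiting"),
    _prise("diarrhea"),
    _prise("constipation"),
    _prise("weight_gain"),
    _prise("dry_skin"),
    _prise("itching"),
    _prise("rash"),
    _prise("blurred_vision"),
    _prise("ringing_in_ears"),
    _prise("painful_urination"),
    _prise("difficulty_urinating"),
    _prise("frequent_urination"),
    _prise("irregular_periods", "female_only"),
    _prise("erectile_dysfunction", "male_only"),
    _prise("reduced_sex_drive"),
)

#: 10 MADRS depression items (0-6).
_MADRS_ITEMS = (
    _madrs("apparent_sadness"),
    _madrs("reported_sadness"),
    _madrs("inner_tension"),
    _madrs("reduced_sleep"),
    _madrs("reduced_appetite"),
    _madrs("concentration_difficulties"),
    _madrs("lassitude"),
    _madrs("inability_to_feel"),
    _madrs("pessimistic_thoughts"),
    _madrs("suicidal_thoughts"),
)

#: 11 YMRS mania items: seven 0-4, four 0-8.
_YMRS_ITEMS = (
    _ymrs("elevated_mood"),
    _ymrs("increased_energy"),
    _ymrs("sexual_interest"),
    _ymrs("sleep"),
    _ymrs("irritability", 8),
    _ymrs("speech", 8),
    _ymrs("language_thought_disorder"),
    _ymrs("thought_content", 8),
    _ymrs("disruptive_aggressive_behavior", 8),
    _ymrs("appearance"),
    _ymrs("insight"),
)


def default_bd_schema() -> ItemSchema:
    """The 53-item bipolar-disorder schema (PRISE-M + MADRS + YMRS).

    Restricting to one sex via :meth:`ItemSchema.for_sex` drops the
    inapplicable sex-specific PRISE-M item and yields the 52-node
    analysis frame.
    """
    return ItemSchema(_PRISE_ITEMS + _MADRS_ITEMS + _YMRS_ITEMS)


def analysis_schema(sex: str = "male") -> ItemSchema:
    """The 52-item single-sex analysis schema."""
    return default_bd_schema().for_sex(sex)


def uniform_schema(p: int, max_level: int = 2, scale: str = "custom") -> ItemSchema:
    """A generic schema of ``p`` identically-ranged items, for simulations."""
    return ItemSchema(
        tuple(Item(f"item_{k:02d}", scale, 0, max_level) for k in range(p))
    )
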