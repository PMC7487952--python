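"""Weight-related diagnosis code dictionaries and BMI category scales.

Two families of ICD diagnosis codes carry body-weight information in
US administrative claims:

* **granular** codes denote narrow BMI ranges (ICD-9-CM ``V85.x``,
  ICD-10-CM ``Z68.x``, e.g. ``Z68.41`` = BMI 40.0-44.9 kg/m^2);
* **nonspecific** codes denote obesity status without a usable BMI level
  (e.g. ``278.01`` / ``E66.01`` morbid obesity).

This module maps codes to an ordered 10-level BMI scale and provides the
coarsened 5- and 4-level scales used in sensitivity analyses. Category
intervals are half-open ``[lower, upper)`` so the printed labels tile the
BMI axis without gaps ("30.0-34.9" means 30.0 <= BMI < 35.0).
"""

from __future__ import annotations

import csv
import enum
import math
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence


class CodingSystem(str, enum.Enum):
    ICD9CM = "ICD9CM"
    ICD10CM = "ICD10CM"


class Granularity(str, enum.Enum):
    GRANULAR = "granular"
    NONSPECIFIC = "nonspecific"


class CodeClass(str, enum.Enum):
    """Outcome of classifying a diagnosis code."""

    GRANULAR = "granular"
    NONSPECIFIC = "nonspecific"
    NOT_WEIGHT_RELATED = "not_weight_related"


class Scheme(str, enum.Enum):
    TEN_LEVEL = "ten_level"
    FIVE_LEVEL = "five_level"
    FOUR_LEVEL = "four_level"


@dataclass(frozen=True, order=True)
class BmiCategory:
    """One ordinal BMI bin: ``lower_bound <= BMI < upper_bound`` (kg/m^2)."""

    level_index: int
    lower_bound: float
    upper_bound: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.lower_bound < self.upper_bound:
            raise ValueError("lower_bound must be < upper_bound")

    def contains(self, value: float) -> bool:
        return self.lower_bound <= value < self.upper_bound


def _scale(bounds: Sequence[float], labels: Sequence[str]) -> tuple[BmiCategory, ...]:
    cats = []
    for i, label in enumerate(labels):
        cats.append(BmiCategory(i, bounds[i], bounds[i + 1], label))
    return tuple(cats)


TEN_LEVELS: tuple[BmiCategory, ...] = _scale(
    [0.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0, 60.0, 70.0, math.inf],
    ["<=19.9", "20.0-24.9", "25.0-29.9", "30.0-34.9", "35.0-39.9",
     "40.0-44.9", "45.0-49.9", "50.0-59.9", "60.0-69.9", ">=70.0"],
)

FIVE_LEVELS: tuple[BmiCategory, ...] = _scale(
    [0.0, 30.0, 40.0, 50.0, 60.0, math.inf],
    ["<=29.9", "30.0-39.9", "40.0-49.9", "50.0-59.9", ">=60.0"],
)

FOUR_LEVELS: tuple[BmiCategory, ...] = _scale(
    [0.0, 20.0, 25.0, 30.0, math.inf],
    ["<=19.9", "20.0-24.9", "25.0-29.9", ">=30.0"],
)

SCALES: dict[Scheme, tuple[BmiCategory, ...]] = {
    Scheme.TEN_LEVEL: TEN_LEVELS,
    Scheme.FIVE_LEVEL: FIVE_LEVELS,
    Scheme.FOUR_LEVEL: FOUR_LEVELS,
}

# fine level index -> coarse level index
_COARSEN: dict[Scheme, tuple[int, ...]] = {
    Scheme.TEN_LEVEL: tuple(range(10)),
    Scheme.FIVE_LEVEL: (0, 0, 0, 1, 1, 2, 2, 3, 4, 4),
    Scheme.FOUR_LEVEL: (0, 1, 2, 3, 3, 3, 3, 3, 3, 3),
}

_LABEL_TO_TEN = {c.label: c for c in TEN_LEVELS}

_CODE_RE = re.compile(r"^[A-Z0-9]{3,7}$")


def normalize_code(code: str) -> str:
    """Normalise an ICD code to dotless uppercase ("z68.41" -> "Z6841").

    Raises ``ValueError`` for empty strings or illegal characters.
    """
    if not isinstance(code, str):
        raise ValueError(f"diagnosis code must be a string, got {type(code)!r}")
    compact = code.strip().upper().replace(".", "")
    if not _CODE_RE.match(compact):
        raise ValueError(f"malformed diagnosis code: {code!r}")
    return compact


def categorize_bmi(value: float, scheme: Scheme = Scheme.TEN_LEVEL) -> BmiCategory:
    """Bin a BMI value (kg/m^2) into its half-open category."""
    for cat in SCALES[scheme]:
        if cat.contains(value):
            return cat
    raise ValueError(f"BMI value {value!r} outside scale")


def coarsen(category10: BmiCategory, scheme: Scheme) -> BmiCategory:
    """Merge a 10-level category into the 5- or 4-level scheme.

    The merge is the order-preserving surjection onto the coarser printed
    scale; ``ten_level`` is the identity.
    """
    if scheme not in _COARSEN:
        raise ValueError(f"unknown scheme: {scheme!r}")
    return SCALES[scheme][_COARSEN[scheme][category10.level_index]]


def coarsen_level(level10: int, scheme: Scheme) -> int:
    """Index-level counterpart of :func:`coarsen`."""
    return _COARSEN[scheme][level10]


@dataclass(frozen=True)
class WeightCode:
    """One dictionary entry for a weight-related diagnosis code."""

    code: str                       # dotted display form, e.g. "Z68.41"
    system: CodingSystem
    granularity: Granularity
    category10: Optional[BmiCategory]  # None for nonspecific codes

    def __post_init__(self) -> None:
        if self.granularity is Granularity.GRANULAR and self.category10 is None:
            raise ValueError(f"granular code {self.code} needs a category")
        if self.granularity is Granularity.NONSPECIFIC and self.category10 is not None:
            raise ValueError(f"nonspecific code {self.code} must not carry a category")


@dataclass(frozen=True)
class MapResult:
    """Classification of a single diagnosis code."""

    kind: CodeClass
    category: Optional[BmiCategory] = None
    entry: Optional[WeightCode] = None


class CodeDictionary:
    """Lookup table of weight-related diagnosis codes for both ICD eras."""

    def __init__(self, entries: Iterable[WeightCode]):
        self._by_key: dict[tuple[CodingSystem, str], WeightCode] = {}
        for e in entries:
            key = (e.system, normalize_code(e.code))
            if key in self._by_key:
                raise ValueError(f"duplicate code {e.code} in {e.system.value}")
            self._by_key[key] = e

    @classmethod
    def from_tsv(cls, path=None) -> "CodeDictionary":
        """Load the shipped (or a user-supplied) plain-text dictionary."""
        if path is None:
            src = resources.files("claimsbmi.data").joinpath("weight_codes.tsv")
            text = src.read_text(encoding="utf-8")
        else:
            with open(path, encoding="utf-8") as fh:
                text = fh.read()
        entries = []
        rows = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
        reader = csv.reader(rows, delimiter="\t")
        header = next(reader)
        if header[:3] != ["code", "system", "granularity"]:
            raise ValueError("unexpected dictionary header")
        for row in reader:
            code, system, gran = row[0], CodingSystem(row[1]), Granularity(row[2])
            cat = None
            if gran is Granularity.GRANULAR:
                cat = _LABEL_TO_TEN[row[3]]
            entries.append(WeightCode(code, system, gran, cat))
        return cls(entries)

    def entries(self) -> list[WeightCode]:
        return list(self._by_key.values())

    def granular_codes(self, system: CodingSystem) -> list[WeightCode]:
        return [e for e in self._by_key.values()
                if e.system is system and e.granularity is Granularity.GRANULAR]

    def nonspecific_codes(self, system: CodingSystem) -> list[WeightCode]:
        return [e for e in self._by_key.values()
                if e.system is system and e.granularity is Granularity.NONSPECIFIC]

    def codes_for_category(self, category10: BmiCategory,
                           system: CodingSystem) -> list[WeightCode]:
        return [e for e in self.granular_codes(system)
                if e.category10 == category10]

    def map_code(self, code: str, system: CodingSystem) -> MapResult:
        """Classify one diagnosis code.

        Unknown but well-formed codes are simply not weight-related; only
        malformed strings raise.
        """
        entry = self._by_key.get((CodingSystem(system), normalize_code(code)))
        if entry is None:
            return MapResult(CodeClass.NOT_WEIGHT_RELATED)
        if entry.granularity is Granularity.GRANULAR:
            return MapResult(CodeClass.GRANULAR, entry.category10, entry)
        return MapResult(CodeClass.NONSPECIFIC, None, entry)

    def indicates_bmi_at_least(self, code: str, system: CodingSystem,
                               threshold: float) -> bool:
        """True iff the code is granular and its whole BMI range lies at or
        above ``threshold`` (35 or 40 kg/m^2 in practice).

        Nonspecific codes never qualify under the base algorithm.
        """
        if threshold not in (35, 40):
            raise ValueError("threshold must be 35 or 40")
        res = self.map_code(code, system)
        return res.kind is CodeClass.GRANULAR and res.category.lower_bound >= threshold


_DEFAULT: Optional[CodeDictionary] = None


def default_dictionary() -> CodeDictionary:
    """The dictionary shipped with the package (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = CodeDictionary.from_tsv()
    return _DEFAULT


def map_code(code: str, system: CodingSystem) -> MapResult:
    return default_dictionary().map_code(code, system)


def indicates_bmi_at_least(code: str, system: CodingSystem, threshold: float) -> bool:
    return default_dictionary().indicates_bmi_at_least(code, system, threshold)
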