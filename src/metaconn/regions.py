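"""Canonical atlas region sets.

The default set mirrors the 28 volumes of interest of the Schiffer rat
brain atlas commonly used in small-animal FDG-PET studies of the
quinolinic-acid lesion model: 14 bilateral structures, split into a
cortical block (olfactory bulb through somatosensory cortex) and a
subcortical block (striatum through cerebellum).  The lesion in that
model is placed in the *right* striatum, so the right hemisphere is
ipsilesional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

CORTICAL = "cortical"
SUBCORTICAL = "subcortical"

#: (short code stem, display name, class)
_STRUCTURES = [
    ("OlfB", "olfactory bulb", CORTICAL),
    ("PFC", "prefrontal cortex", CORTICAL),
    ("Front", "frontal cortex", CORTICAL),
    ("OFC", "orbitofrontal cortex", CORTICAL),
    ("Cg", "cingulate cortex", CORTICAL),
    ("MC", "motor cortex", CORTICAL),
    ("SSC", "somatosensory cortex", CORTICAL),
    ("S", "striatum", SUBCORTICAL),
    ("AntHip", "anterior hippocampus", SUBCORTICAL),
    ("PostHip", "posterior hippocampus", SUBCORTICAL),
    ("Tha", "thalamus", SUBCORTICAL),
    ("HTha", "hypothalamus", SUBCORTICAL),
    ("MB", "midbrain", SUBCORTICAL),
    ("CRB", "cerebellum", SUBCORTICAL),
]


@dataclass(frozen=True)
class Region:
    code: str
    name: str
    hemisphere: str  # "L" or "R"
    region_class: str  # cortical | subcortical
    label: int  # integer atlas label value


@dataclass
class RegionSet:
    """Ordered collection of atlas regions with unique codes and labels."""

    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        codes = [r.code for r in self.regions]
        labels = [r.label for r in self.regions]
        if len(set(codes)) != len(codes):
            raise ValueError("region codes must be unique")
        if len(set(labels)) != len(labels):
            raise ValueError("atlas label values must be unique")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    @property
    def codes(self) -> list[str]:
        return [r.code for r in self.regions]

    @property
    def labels(self) -> list[int]:
        return [r.label for r in self.regions]

    def by_code(self, code: str) -> Region:
        for r in self.regions:
            if r.code == code:
                return r
        raise KeyError(code)

    def codes_of_class(self, region_class: str) -> list[str]:
        return [r.code for r in self.regions if r.region_class == region_class]

    @property
    def cortical_codes(self) -> list[str]:
        return self.codes_of_class(CORTICAL)

    @property
    def subcortical_codes(self) -> list[str]:
        return self.codes_of_class(SUBCORTICAL)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.code, r.name, r.hemisphere, r.region_class, r.label)
                for r in self.regions
            ],
            columns=["code", "name", "hemisphere", "class", "label"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionSet":
        return cls(
            [
                Region(
                    code=row["code"],
                    name=row.get("name", row["code"]) if hasattr(row, "get") else row["name"],
                    hemisphere=row["hemisphere"],
                    region_class=row["class"],
                    label=int(row["label"]),
                )
                for _, row in df.iterrows()
            ]
        )

    @classmethod
    def from_tsv(cls, path) -> "RegionSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def default_region_set() -> RegionSet:
    """The 28-region bilateral set (14 structures x L/R), left first.

    Atlas label values are assigned 1..28 in order.
    """
    regions = []
    label = 1
    for hemi in ("L", "R"):
        for stem, name, cls_ in _STRUCTURES:
            regions.append(
                Region(
                    code=f"{hemi}_{stem}",
                    name=f"{'left' if hemi == 'L' else 'right'} {name}",
                    hemisphere=hemi,
                    region_class=cls_,
                    label=label,
                )
            )
            label += 1
    return RegionSet(regions)


def validate_region_sets_match(a: RegionSet, b: RegionSet) -> None:
    if a.codes != b.codes:
        missing_a = [c for c in b.codes if c not in a.codes]
        missing_b = [c for c in a.codes if c not in b.codes]
        raise ValueError(
            "region sets differ: "
            f"only in second={missing_a!r}, only in first={missing_b!r}, "
            "or ordering differs"
        )
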