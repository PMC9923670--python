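"""Subject-by-region uptake tables, the pipeline's central data currency."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import RegionSet

UNITS_PID_G = "%ID/g"
UNITS_RATIO = "ratio_to_global"

ID_COLS = ["subject_id", "group"]


@dataclass
class UptakeTable:
    """Per-subject regional uptake values with group labels.

    ``data`` has one row per subject, columns ``subject_id``, ``group``,
    then one column per region code in region-set order.  ``units`` is
    either ``"%ID/g"`` (absolute quantification) or ``"ratio_to_global"``
    (each subject divided by its whole-brain mean).
    """

    data: pd.DataFrame
    region_set: RegionSet
    units: str = UNITS_PID_G
    tracer: str = "FDG"
    #: optional per-region voxel volumes used for volume-weighted means
    region_weights: dict[str, float] | None = field(default=None)

    def __post_init__(self) -> None:
        missing = [c for c in ID_COLS + self.region_set.codes if c not in self.data.columns]
        if missing:
            raise ValueError(f"uptake table missing columns: {missing}")
        vals = self.values
        if not np.all(np.isfinite(vals)):
            bad = self.data.loc[~np.isfinite(vals).all(axis=1), "subject_id"].tolist()
            raise ValueError(f"non-finite uptake values for subjects {bad}")
        if self.units == UNITS_RATIO:
            wb = self.whole_brain_means()
            if not np.allclose(wb, 1.0, atol=1e-9):
                raise ValueError(
                    "ratio_to_global table must have whole-brain mean 1 per subject "
                    f"(got range [{wb.min():.3g}, {wb.max():.3g}])"
                )

    @property
    def values(self) -> np.ndarray:
        """Subject x region matrix in region-set order."""
        return self.data[self.region_set.codes].to_numpy(dtype=float)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.data["group"]:
            if g not in seen:
                seen.append(g)
        return seen

    def group_values(self, group: str) -> np.ndarray:
        mask = self.data["group"] == group
        if not mask.any():
            raise KeyError(f"group {group!r} not present (have {self.groups})")
        return self.data.loc[mask, self.region_set.codes].to_numpy(dtype=float)

    def subset(self, groups: list[str]) -> "UptakeTable":
        mask = self.data["group"].isin(groups)
        return UptakeTable(
            self.data.loc[mask].reset_index(drop=True),
            self.region_set,
            units=self.units,
            tracer=self.tracer,
            region_weights=self.region_weights,
        )

    def _weights(self) -> np.ndarray:
        if self.region_weights is None:
            return np.ones(len(self.region_set))
        return np.array([self.region_weights[c] for c in self.region_set.codes], float)

    def whole_brain_means(self) -> np.ndarray:
        """Volume-weighted mean over regions, per subject.

        Uniform weights are used when no region volumes are attached, in
        which case this is the plain mean over the region columns.
        """
        w = self._weights()
        return self.values @ w / w.sum()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, region_set: RegionSet, units: str = UNITS_PID_G,
                 tracer: str = "FDG") -> "UptakeTable":
        return cls(pd.read_csv(path), region_set, units=units, tracer=tracer)
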