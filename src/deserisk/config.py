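"""Indicator configuration: factor assignment, orientation, grade boundaries, weights.

The canonical 19-indicator configuration (seven hazard, four each of exposure,
vulnerability and restorability indicators, with combined weights and the four
grade boundaries per indicator) ships with the package and anchors the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ValidationError

FACTORS = ("hazard", "exposure", "vulnerability", "restorability")
ORIENTATIONS = ("risk-increasing", "risk-decreasing")


@dataclass(frozen=True)
class IndicatorSpec:
    """Configuration of one assessment indicator.

    ``boundaries`` are the four grade split points in ascending numeric order
    as tabulated; ``envelope`` is the (level-1 lower, level-5 upper) value
    range. ``orientation`` is the indicator's effect on overall risk;
    ``membership_direction`` resolves it to the direction the five-grade
    membership functions use: grades measure the indicator's *factor* index,
    and restorability enters the risk index through its complement, so
    restorability indicators grade in the opposite sense of their risk
    orientation.
    """

    name: str
    factor: str
    orientation: str
    boundaries: tuple[float, float, float, float]
    envelope: tuple[float, float]
    weight: float | None = None
    subjective_weight: float | None = None

    def __post_init__(self):
        if self.factor not in FACTORS:
            raise ValidationError(
                f"indicator {self.name!r}: unknown factor {self.factor!r} "
                f"(expected one of {FACTORS})"
            )
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(
                f"indicator {self.name!r}: unknown orientation {self.orientation!r}"
            )
        b = self.boundaries
        if not (b[0] < b[1] < b[2] < b[3]):
            raise ValidationError(
                f"indicator {self.name!r}: boundaries {b} not strictly ascending"
            )
        if not (self.envelope[0] <= b[0] and b[3] <= self.envelope[1]):
            raise ValidationError(
                f"indicator {self.name!r}: envelope {self.envelope} does not "
                f"contain boundaries {b}"
            )
        for label, w in (("weight", self.weight), ("subjective_weight", self.subjective_weight)):
            if w is not None and not (0 < w < 1):
                raise ValidationError(
                    f"indicator {self.name!r}: {label} {w} outside (0, 1)"
                )

    @property
    def membership_direction(self) -> str:
        """'increasing' or 'decreasing' — direction used by the membership functions."""
        rises_with_risk = self.orientation == "risk-increasing"
        if self.factor == "restorability":
            # factor index measures restorability; risk falls as it rises
            rises_with_risk = not rises_with_risk
        return "increasing" if rises_with_risk else "decreasing"


class IndicatorConfigTable:
    """Ordered collection of :class:`IndicatorSpec` rows."""

    def __init__(self, specs: list[IndicatorSpec]):
        if not specs:
            raise ValidationError("indicator configuration is empty")
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate indicator names in configuration")
        self.specs = list(specs)
        self._by_name = {s.name: s for s in specs}

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    def __getitem__(self, name: str) -> IndicatorSpec:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def by_factor(self, factor: str) -> list[IndicatorSpec]:
        if factor not in FACTORS:
            raise ValidationError(f"unknown factor {factor!r}")
        return [s for s in self.specs if s.factor == factor]

    def factor_weight(self, factor: str) -> float:
        """Sum of the combined indicator weights within one factor."""
        specs = self.by_factor(factor)
        if any(s.weight is None for s in specs):
            raise ValidationError(f"factor {factor!r} has indicators without weights")
        return float(sum(s.weight for s in specs))

    def factor_weights(self) -> dict[str, float]:
        return {f: self.factor_weight(f) for f in FACTORS}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "indicator": s.name,
                "factor": s.factor,
                "orientation": s.orientation,
                "env_lo": s.envelope[0],
                "b1": s.boundaries[0],
                "b2": s.boundaries[1],
                "b3": s.boundaries[2],
                "b4": s.boundaries[3],
                "env_hi": s.envelope[1],
                "weight": s.weight,
            }
            for s in self.specs
        ]
        return pd.DataFrame(rows)


def load_indicator_config(path: str | Path) -> IndicatorConfigTable:
    """Load an indicator configuration table from CSV.

    Required columns: indicator, factor, orientation, env_lo, b1..b4, env_hi;
    optional: weight, subjective_weight.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"{path}: configuration file has no rows")
    required = ["indicator", "factor", "orientation", "env_lo", "b1", "b2", "b3", "b4", "env_hi"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    specs = []
    for _, row in df.iterrows():
        specs.append(
            IndicatorSpec(
                name=str(row["indicator"]),
                factor=str(row["factor"]),
                orientation=str(row["orientation"]),
                boundaries=(row["b1"], row["b2"], row["b3"], row["b4"]),
                envelope=(row["env_lo"], row["env_hi"]),
                weight=None if "weight" not in df.columns or pd.isna(row["weight"]) else float(row["weight"]),
                subjective_weight=(
                    None
                    if "subjective_weight" not in df.columns or pd.isna(row.get("subjective_weight"))
                    else float(row["subjective_weight"])
                ),
            )
        )
    return IndicatorConfigTable(specs)


def canonical_config() -> IndicatorConfigTable:
    """The packaged 19-indicator system with combined weights and grade boundaries."""
    with resources.as_file(
        resources.files("deserisk.data").joinpath("indicator_system.csv")
    ) as path:
        return load_indicator_config(path)
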