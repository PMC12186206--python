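"""Age-band schemas and the standard population used for direct standardization.

An age schema is an ordered list of :class:`AgeBand` objects that partition
``[0, inf)`` into contiguous, non-overlapping bands.  The default schema,
``{<5, 5-14, 15-49, 50-64, 65+}``, is the smallest partition that keeps the
two high-risk groups for diarrheal mortality (children under 5 and adults
over 65) as separate bands.  All panels, the age-period-cohort model and the
decomposition share whatever schema the configuration carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=False)
class AgeBand:
    """One age band ``[lower, upper]`` in whole years; ``upper=None`` is open-ended.

    ``upper`` is inclusive: the band 5-14 contains exact ages 5 through 14,
    so consecutive bands satisfy ``next.lower == this.upper + 1``.
    """

    label: str
    lower: int
    upper: int | None = None

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise ValueError(f"age band {self.label!r}: lower bound must be >= 0")
        if self.upper is not None and self.upper < self.lower:
            raise ValueError(f"age band {self.label!r}: upper < lower")

    @property
    def open_ended(self) -> bool:
        return self.upper is None

    @property
    def midpoint(self) -> float:
        """Representative age for cohort indexing; open bands use lower + 10."""
        if self.upper is None:
            return self.lower + 10.0
        return (self.lower + self.upper + 1) / 2.0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


DEFAULT_AGE_SCHEMA: tuple[AgeBand, ...] = (
    AgeBand("<5", 0, 4),
    AgeBand("5-14", 5, 14),
    AgeBand("15-49", 15, 49),
    AgeBand("50-64", 50, 64),
    AgeBand("65+", 65, None),
)


def validate_schema(schema: list[AgeBand] | tuple[AgeBand, ...]) -> tuple[AgeBand, ...]:
    """Check contiguity/ordering of an age schema and return it as a tuple.

    Bands must be ordered by lower bound, non-overlapping, jointly cover
    ``[0, inf)`` (first band starts at 0, last band open-ended, no gaps).
    """
    bands = tuple(schema)
    if not bands:
        raise ValueError("age schema is empty")
    if bands[0].lower != 0:
        raise ValueError("age schema must start at age 0")
    if not bands[-1].open_ended:
        raise ValueError("last age band must be open-ended")
    for a, b in zip(bands[:-1], bands[1:]):
        if a.open_ended:
            raise ValueError(f"open-ended band {a.label!r} is not last")
        if b.lower != a.upper + 1:
            raise ValueError(
                f"age schema gap/overlap between {a.label!r} and {b.label!r}"
            )
    labels = [b.label for b in bands]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate age-band labels")
    return bands


# WHO World Standard Population (Ahmad et al. standard), weights per 5-year
# band in percent.  Used as the default weights for age-standardized rates,
# aggregated onto whatever age schema the pipeline runs with.
_WHO_STANDARD_5YR: tuple[tuple[int, int | None, float], ...] = (
    (0, 4, 8.86),
    (5, 9, 8.69),
    (10, 14, 8.60),
    (15, 19, 8.47),
    (20, 24, 8.22),
    (25, 29, 7.93),
    (30, 34, 7.61),
    (35, 39, 7.15),
    (40, 44, 6.59),
    (45, 49, 6.04),
    (50, 54, 5.37),
    (55, 59, 4.55),
    (60, 64, 3.72),
    (65, 69, 2.96),
    (70, 74, 2.21),
    (75, 79, 1.52),
    (80, 84, 0.91),
    (85, None, 0.635),
)


@dataclass(frozen=True)
class StandardPopulation:
    """Age-band weights for direct standardization; weights sum to 1."""

    weights: dict[AgeBand, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"standard population weights sum to {total}, not 1")

    @classmethod
    def who_world(cls, schema: tuple[AgeBand, ...]) -> "StandardPopulation":
        """WHO World Standard weights aggregated onto ``schema`` and renormalized."""
        schema = validate_schema(schema)
        agg = {band: 0.0 for band in schema}
        for lo, hi, w in _WHO_STANDARD_5YR:
            for band in schema:
                b_hi = float("inf") if band.upper is None else band.upper
                s_hi = float("inf") if hi is None else hi
                if lo >= band.lower and s_hi <= b_hi:
                    agg[band] += w
                    break
            else:
                raise ValueError(
                    f"standard 5-year band [{lo},{hi}] straddles schema bands"
                )
        total = sum(agg.values())
        return cls({b: w / total for b, w in agg.items()})

    @classmethod
    def uniform(cls, schema: tuple[AgeBand, ...]) -> "StandardPopulation":
        schema = validate_schema(schema)
        w = 1.0 / len(schema)
        return cls({b: w for b in schema})

    @classmethod
    def single_band(cls, schema: tuple[AgeBand, ...], label: str) -> "StandardPopulation":
        schema = validate_schema(schema)
        if label not in {b.label for b in schema}:
            raise ValueError(f"unknown band {label!r}")
        return cls({b: (1.0 if b.label == label else 0.0) for b in schema})

    def as_series(self):
        import pandas as pd

        return pd.Series({b.label: w for b, w in self.weights.items()})
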