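"""Core domain types for regional immediate-early-gene activity analysis.

The pipeline's central objects are a per-study summary table (region x group
mean/SEM of c-Fos-positive cell counts) and a per-animal cohort matrix
(animal x region activity, with group labels and optional behavior or
tyrosine-hydroxylase measurements). Everything downstream — group statistics,
correlation networks, hub identification, behavior prediction — consumes one
of these two containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SUBDIVISIONS",
    "MOTOR_REGIONS",
    "DEFAULT_GROUPS",
    "BEHAVIOR_COLUMNS",
    "ROTAROD_MAX_S",
    "RegionInfo",
    "GroupSummaryTable",
    "CohortMatrix",
    "AnovaResult",
    "SchemaError",
    "ValidationError",
]

#: Anatomical subdivisions used to organize the 30-region panel.
SUBDIVISIONS = (
    "cortex",
    "basal_ganglia",
    "hippocampus",
    "thalamus",
    "hypothalamus",
    "midbrain",
    "hindbrain",
)

#: The seven motor-circuit regions used for the focused subnetwork analysis:
#: primary motor cortex, dorsolateral/dorsomedial striatum, globus pallidus,
#: submedius thalamic nucleus, and substantia nigra pars compacta/reticular.
MOTOR_REGIONS = ("M1", "DLS", "DMS", "Gp", "Sm", "SNpc", "SNr")

#: Default experimental groups: untreated controls, MPTP-lesioned mice,
#: MPTP + acupuncture, and MPTP + sham acupuncture.
DEFAULT_GROUPS = ("Naive", "MPTP", "Acu", "Sham")

#: Optional per-animal outcome columns: rotarod latency (s), cylinder-test
#: rearing count, striatal TH optical density, nigral TH-positive cell count.
BEHAVIOR_COLUMNS = ("rotarod_s", "cylinder_rearings", "th_st", "th_sn")

#: Rotarod trials are capped at this latency (seconds).
ROTAROD_MAX_S = 480.0


class SchemaError(ValueError):
    """A table is missing a required column or has a malformed layout."""


class ValidationError(ValueError):
    """A table violates a value-level invariant (the message names the row)."""


@dataclass(frozen=True)
class RegionInfo:
    """One brain region: short abbreviation, display name, subdivision."""

    abbreviation: str
    full_name: str
    subdivision: str

    def __post_init__(self) -> None:
        if self.subdivision not in SUBDIVISIONS:
            raise ValidationError(
                f"unknown subdivision {self.subdivision!r} for region "
                f"{self.abbreviation!r}; expected one of {SUBDIVISIONS}"
            )


@dataclass
class GroupSummaryTable:
    """Region x group summary of c-Fos counts: mean, SEM, and group size.

    ``mean`` and ``sem`` are DataFrames indexed by region abbreviation with
    one column per group; ``n`` maps each group to its animal count. Units
    are c-Fos-positive cells per counting frame.
    """

    regions: list[RegionInfo]
    groups: list[str]
    mean: pd.DataFrame
    sem: pd.DataFrame
    n: dict[str, int]

    def __post_init__(self) -> None:
        abbrevs = [r.abbreviation for r in self.regions]
        if len(set(abbrevs)) != len(abbrevs):
            dupes = sorted({a for a in abbrevs if abbrevs.count(a) > 1})
            raise ValidationError(f"duplicate region abbreviations: {dupes}")
        for df, what in ((self.mean, "mean"), (self.sem, "sem")):
            if list(df.index) != abbrevs or list(df.columns) != list(self.groups):
                raise SchemaError(f"{what} table not aligned to regions x groups")
        for group in self.groups:
            if group not in self.n:
                raise SchemaError(f"missing group size n for group {group!r}")
            if self.n[group] < 2:
                raise ValidationError(f"group {group!r} has n < 2")
        for region in abbrevs:
            for group in self.groups:
                m = self.mean.at[region, group]
                s = self.sem.at[region, group]
                if pd.isna(m) or pd.isna(s):
                    raise ValidationError(
                        f"blank mean/SEM for region {region!r}, group {group!r}"
                    )
                if m < 0:
                    raise ValidationError(
                        f"negative mean for region {region!r}, group {group!r}"
                    )
                if s < 0:
                    raise ValidationError(
                        f"negative SEM for region {region!r}, group {group!r}"
                    )

    @property
    def region_names(self) -> list[str]:
        return [r.abbreviation for r in self.regions]

    def region_info(self, abbreviation: str) -> RegionInfo:
        for r in self.regions:
            if r.abbreviation == abbreviation:
                return r
        raise KeyError(abbreviation)

    def sd(self) -> pd.DataFrame:
        """Per-animal standard deviation reconstructed as SEM * sqrt(n)."""
        out = self.sem.copy()
        for group in self.groups:
            out[group] = out[group] * np.sqrt(self.n[group])
        return out

    def row(self, region: str) -> tuple[list[float], list[float], list[int]]:
        """(means, sems, ns) for one region, ordered by ``groups``."""
        means = [float(self.mean.at[region, g]) for g in self.groups]
        sems = [float(self.sem.at[region, g]) for g in self.groups]
        ns = [int(self.n[g]) for g in self.groups]
        return means, sems, ns


@dataclass
class CohortMatrix:
    """Per-animal regional activity with group labels.

    ``data`` is indexed by ``animal_id`` and carries a ``group`` column,
    one column per region abbreviation, and optionally any of
    ``BEHAVIOR_COLUMNS``. ``meta`` holds generator provenance such as
    per-region truncation fractions.
    """

    data: pd.DataFrame
    regions: list[str]
    groups: list[str] = field(default_factory=lambda: list(DEFAULT_GROUPS))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise ValidationError(f"duplicate animal_id values: {dupes}")
        if "group" not in self.data.columns:
            raise SchemaError("cohort table is missing the 'group' column")
        bad = sorted(set(self.data["group"]) - set(self.groups))
        if bad:
            raise ValidationError(
                f"group labels {bad} outside the configured set {list(self.groups)}"
            )
        missing = [r for r in self.regions if r not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort table is missing region columns: {missing}")
        act = self.data[self.regions]
        if (act.to_numpy(dtype=float) < 0).any():
            rows = act.index[(act < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative activity values for animals {rows}")
        if "rotarod_s" in self.data.columns:
            col = self.data["rotarod_s"].dropna()
            bad_rows = col.index[(col < 0) | (col > ROTAROD_MAX_S)].tolist()
            if bad_rows:
                raise ValidationError(
                    f"rotarod_s outside [0, {ROTAROD_MAX_S:g}] for animals {bad_rows}"
                )

    @property
    def behavior_columns(self) -> list[str]:
        return [c for c in BEHAVIOR_COLUMNS if c in self.data.columns]

    @property
    def n_animals(self) -> int:
        return len(self.data)

    def activity(self, group: str | None = None) -> pd.DataFrame:
        """Animal x region activity block, optionally for one group."""
        df = self.data if group is None else self.data[self.data["group"] == group]
        if group is not None and df.empty:
            raise KeyError(f"no animals in group {group!r}")
        return df[self.regions]

    def group_sizes(self) -> dict[str, int]:
        counts = self.data["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in self.groups}

    def with_column(self, name: str, values: Iterable[float]) -> "CohortMatrix":
        data = self.data.copy()
        data[name] = list(values)
        return CohortMatrix(data=data, regions=list(self.regions),
                            groups=list(self.groups), meta=dict(self.meta))


@dataclass(frozen=True)
class AnovaResult:
    """Fixed-effects one-way ANOVA: F statistic, degrees of freedom, p.

    An infinite F (zero within-group variance with unequal means) is
    represented as ``F = inf`` with ``p = 0``.
    """

    F: float
    df_between: int
    df_within: int
    p: float

    def __post_init__(self) -> None:
        if not (np.isinf(self.F) or self.F >= 0):
            raise ValidationError(f"F must be non-negative, got {self.F}")
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"p must lie in [0, 1], got {self.p}")

    @property
    def is_infinite(self) -> bool:
        return bool(np.isinf(self.F))
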