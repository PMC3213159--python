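"""Per-strain fitness scores over the selection design's sample comparisons.

Fitness for a comparison is the log2 change in relative strain abundance
between a sample and its control; negative values mean decreased fitness.
The table is strains x (pretreatment, comparison, replicate, platform),
with platform one of Array / UP / DN, and is serialized as a tab-delimited
file with one space-joined header token per column.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

COMPARISONS = ("S1vS0", "S2vS1", "S3vS1", "S4vS3", "S4AvS3")
PLATFORMS = ("Array", "UP", "DN")
COLUMN_LEVELS = ["pretreatment", "comparison", "replicate", "platform"]


@dataclass(frozen=True)
class Comparison:
    """One named sample comparison measured on one platform."""

    pretreatment: str
    name: str
    replicate: int
    platform: str

    def __post_init__(self) -> None:
        if "v" not in self.name:
            raise ValueError(f"comparison name {self.name!r} must be '<num>v<den>'")

    @property
    def numerator(self) -> str:
        return self.name.split("v", 1)[0]

    @property
    def denominator(self) -> str:
        return self.name.split("v", 1)[1]

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.pretreatment, self.name, self.replicate, self.platform)

    @property
    def label(self) -> str:
        return f"{self.pretreatment} {self.name} {self.replicate} {self.platform}"


def half_count_floor(total_count: float) -> float:
    """Half-count pseudofrequency keeping log2 ratios finite for zeros."""
    if total_count <= 0:
        raise ValueError("total count must be positive")
    return 0.5 / total_count


def compute_fitness(
    abund_num: Mapping[str, float] | pd.Series,
    abund_den: Mapping[str, float] | pd.Series,
    floor: float = 0.0,
) -> pd.Series:
    """log2((a_num + floor) / (a_den + floor)) per strain.

    Strains absent from either side are missing in the result (the index is
    the union of both sides). ``floor=0`` gives exact ratios, with +/-inf
    where one side is zero; a positive floor keeps everything finite.
    """
    if floor < 0:
        raise ValueError("floor must be non-negative")
    num = pd.Series(abund_num, dtype=float)
    den = pd.Series(abund_den, dtype=float)
    union = num.index.union(den.index)
    num, den = num.reindex(union), den.reindex(union)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(num + floor) - np.log2(den + floor)
    out[num.isna() | den.isna()] = np.nan
    return out


def standardize(column: pd.Series, ddof: int = 0) -> pd.Series:
    """z-scores over the non-missing strains of one comparison column.

    Population standard deviation by default (``ddof=0``); configurable.
    Raises on a degenerate (constant or empty) column.
    """
    vals = column.dropna()
    if vals.empty:
        raise ValueError("cannot standardize an all-missing column")
    sd = vals.std(ddof=ddof)
    if sd == 0 or np.isnan(sd):
        raise ValueError("cannot standardize a zero-variance column")
    return (column - vals.mean()) / sd


def merge_platforms(values: Mapping[str, float]) -> tuple[float, int]:
    """Consensus fitness = mean of available platform values.

    Returns (consensus, n_supporting_platforms); (nan, 0) when all missing.
    """
    avail = [v for v in values.values() if v is not None and not np.isnan(v)]
    if not avail:
        return float("nan"), 0
    return float(np.mean(avail)), len(avail)


# -- table construction / IO ----------------------------------------------

def build_table(columns: Mapping[Comparison, Mapping[str, float] | pd.Series]) -> pd.DataFrame:
    """Assemble a fitness table from per-comparison strain->value maps."""
    data = {c.key: pd.Series(v, dtype=float) for c, v in columns.items()}
    df = pd.DataFrame(data)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=COLUMN_LEVELS)
    df.index.name = "strain"
    return df.sort_index(axis=1)


def consensus(table: pd.DataFrame) -> pd.DataFrame:
    """Average fitness across platforms for each comparison x replicate."""
    return table.T.groupby(level=COLUMN_LEVELS[:3], sort=True).mean().T


def platform_support(table: pd.DataFrame) -> pd.DataFrame:
    """Number of non-missing platform values behind each consensus cell."""
    return table.notna().T.groupby(level=COLUMN_LEVELS[:3], sort=True).sum().T


def standardize_table(table: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Column-wise z-scores (columns with zero variance raise)."""
    return table.apply(lambda col: standardize(col, ddof=ddof))


def replicates_for(table: pd.DataFrame, pretreatment: str,
                   comparison: str = "S4vS3") -> list[int]:
    cols = table.columns
    return sorted({
        rep for (pre, comp, rep, *_rest) in (c if len(c) == 4 else (*c, None)
                                             for c in cols)
        if pre == pretreatment and comp == comparison
    })


def write_table(table: pd.DataFrame, path) -> None:
    """Serialize with space-joined column headers and NA for missing."""
    flat = table.copy()
    flat.columns = [" ".join(str(part) for part in col) for col in table.columns]
    flat.to_csv(path, sep="\t", na_rep="NA", index_label="strain")


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="strain", na_values=["NA"])
    keys = []
    for col in df.columns:
        parts = col.split(" ")
        if len(parts) == 4:
            pre, comp, rep, platform = parts
        elif len(parts) == 3:  # consensus tables have no platform token
            pre, comp, rep = parts
            platform = ""
        else:
            raise ValueError(f"unparseable fitness column header {col!r}")
        keys.append((pre, comp, int(rep), platform))
    df.columns = pd.MultiIndex.from_tuples(keys, names=COLUMN_LEVELS)
    if (df.columns.get_level_values("platform") == "").all():
        df.columns = df.columns.droplevel("platform")
    return df


__all__ = [
    "Comparison",
    "COMPARISONS",
    "PLATFORMS",
    "COLUMN_LEVELS",
    "half_count_floor",
    "compute_fitness",
    "standardize",
    "merge_platforms",
    "build_table",
    "consensus",
    "platform_support",
    "standardize_table",
    "replicates_for",
    "write_table",
    "read_table",
]
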