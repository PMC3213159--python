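"""Scores for the two orthogonal validation assays.

Dose-summed survival scores from paired viability curves, and competition
fitness defects from GFP-marked mixture proportions.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import log2

import numpy as np
import pandas as pd


@dataclass
class ViabilityCurve:
    """Viable fraction across an ordered dose grid for one arm."""

    doses: tuple[float, ...]
    viable_fraction: tuple[float, ...]
    arm: str = "pretreated"  # pretreated | mock
    strain: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        frac = np.asarray(self.viable_fraction, dtype=float)
        if doses.size != frac.size:
            raise ValueError("doses and fractions must have equal length")
        if doses.size and not (np.diff(doses) > 0).all():
            raise ValueError("doses must be strictly increasing")
        if frac.size and ((frac < 0) | (frac > 1)).any():
            raise ValueError("viable fractions must be in [0, 1]")


def survival_score(pretreated: ViabilityCurve, mock: ViabilityCurve,
                   units: str = "fraction") -> float:
    """Sum over doses of (pretreated viability - mock viability).

    Both arms must share the dose grid. The score is linear in the curves
    and antisymmetric under swapping arms; range is +/- the number of doses
    (x100 with ``units='percent'``).
    """
    if tuple(pretreated.doses) != tuple(mock.doses):
        raise ValueError("pretreated and mock curves have mismatched dose grids")
    scale = {"fraction": 1.0, "percent": 100.0}.get(units)
    if scale is None:
        raise ValueError("units must be 'fraction' or 'percent'")
    diff = (np.asarray(pretreated.viable_fraction, dtype=float)
            - np.asarray(mock.viable_fraction, dtype=float))
    return float(diff.sum() * scale)


def competition_fitness(
    gfp_fraction_start: float,
    gfp_fraction_end: float,
    gfp_fraction_end_wt_control: float,
) -> float:
    """Competition defect from GFP-marked mixture proportions.

    The marked reference competes against the mutant and, in a parallel
    control, against wild type. The defect is the log2 change in GFP odds
    in the mutant mixture minus the same change in the wild-type control
    mixture; positive means the mutant lost ground relative to wild type.
    Being an odds-ratio, the score is invariant to the initial mixing ratio.
    """
    for name, f in (
        ("gfp_fraction_start", gfp_fraction_start),
        ("gfp_fraction_end", gfp_fraction_end),
        ("gfp_fraction_end_wt_control", gfp_fraction_end_wt_control),
    ):
        if not 0.0 < f < 1.0:
            raise ValueError(f"{name} = {f} is uninformative; need (0, 1)")

    def odds(f: float) -> float:
        return f / (1.0 - f)

    start = odds(gfp_fraction_start)
    return (log2(odds(gfp_fraction_end) / start)
            - log2(odds(gfp_fraction_end_wt_control) / start))


# -- TSV IO ----------------------------------------------------------------

def read_curves(path) -> list[ViabilityCurve]:
    """Long TSV: strain, replicate, arm, dose, viable_fraction."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for (strain, rep, arm), sub in df.groupby(["strain", "replicate", "arm"]):
        sub = sub.sort_values("dose")
        out.append(
            ViabilityCurve(
                doses=tuple(sub["dose"].astype(float)),
                viable_fraction=tuple(sub["viable_fraction"].astype(float)),
                arm=str(arm),
                strain=str(strain),
                replicate=int(rep),
            )
        )
    return out


def score_curve_table(curves: list[ViabilityCurve],
                      units: str = "fraction") -> pd.DataFrame:
    """Pair pretreated/mock arms per (strain, replicate) and score each."""
    by_key: dict[tuple[str, int], dict[str, ViabilityCurve]] = {}
    for c in curves:
        by_key.setdefault((c.strain, c.replicate), {})[c.arm] = c
    rows = []
    for (strain, rep), arms in sorted(by_key.items()):
        if "pretreated" in arms and "mock" in arms:
            rows.append(
                (strain, rep,
                 survival_score(arms["pretreated"], arms["mock"], units=units))
            )
    return pd.DataFrame(rows, columns=["strain", "replicate", "survival_score"])


__all__ = [
    "ViabilityCurve",
    "survival_score",
    "competition_fitness",
    "read_curves",
    "score_curve_table",
]
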