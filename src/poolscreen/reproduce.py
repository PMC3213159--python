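"""Headline-count reproduction from a deposited-style fitness table.

Given a fitness table shaped like the study's supplementary "measured
fitness defects" tables (converted to this package's TSV schema), runs the
full calling pipeline per pretreatment and returns the per-pretreatment,
union, triple-intersection, and low-dose-sensitive counts.
"""
from __future__ import annotations

import pandas as pd

from . import strain_calling as sc
from .fitness import consensus


def pretreatments_in(table: pd.DataFrame) -> list[str]:
    """Pretreatment labels, in NaCl / heat-shock / DTT order when present.

    The per-pretreatment targets are keyed to that conventional order; any
    label not recognized sorts alphabetically after the known ones.
    """
    cons = table if table.columns.nlevels == 3 else consensus(table)
    labels = {
        pre for (pre, comp, _rep) in cons.columns if comp == sc.SECONDARY
    }

    def rank(label: str) -> tuple[int, str]:
        low = label.lower()
        if "nacl" in low or "salt" in low:
            return (0, label)
        if low.startswith("h") and ("heat" in low or low in ("hs", "heatshock")):
            return (1, label)
        if "dtt" in low:
            return (2, label)
        return (3, label)

    return sorted(labels, key=rank)


def call_pretreatment(
    table: pd.DataFrame,
    pretreatment: str,
    expand: bool = True,
    r_min: float = 0.9,
    z_threshold: float = 1.0,
    min_replicates: int = 2,
    equal_tol: float = 0.0,
) -> sc.CallSet:
    """Stringent criteria + correlation expansion + exclusion rules."""
    calls = sc.call_stringent(table, pretreatment, z_threshold=z_threshold,
                              min_replicates=min_replicates)
    if expand:
        calls = sc.expand_by_correlation(calls, table, r_min=r_min,
                                         z_threshold=z_threshold)
    return sc.apply_exclusions(calls, set(), table, z_threshold=z_threshold,
                               equal_tol=equal_tol)


def compute_targets(
    table: pd.DataFrame,
    pretreatments: list[str] | None = None,
    q_max: float = 0.05,
    **call_kwargs,
) -> dict:
    """Recompute the headline screen counts from a fitness table.

    Returns a dict with keys t1..t6 (union of called strains, per-
    pretreatment counts for the first three pretreatments in sorted order,
    triple intersection, and low-dose-sensitive count at FDR < ``q_max``),
    plus ``<tN>_stringent`` counterparts computed without the correlation
    expansion, since the study's manual expansion step is not exactly
    reproducible.
    """
    pres = pretreatments if pretreatments is not None else pretreatments_in(table)
    if len(pres) < 3:
        raise ValueError(
            f"need three pretreatments for the headline counts, found {pres}"
        )
    expanded = {p: call_pretreatment(table, p, expand=True, **call_kwargs)
                for p in pres[:3]}
    stringent = {p: call_pretreatment(table, p, expand=False, **call_kwargs)
                 for p in pres[:3]}

    out: dict[str, int] = {}
    for label, calls in (("", expanded), ("_stringent", stringent)):
        sets = [calls[p].called for p in pres[:3]]
        out[f"t1{label}"] = len(set().union(*sets))
        for tid, p in zip(("t2", "t3", "t4"), pres[:3]):
            out[f"{tid}{label}"] = len(calls[p].called)
        out[f"t5{label}"] = len(sets[0] & sets[1] & sets[2])

    matrix = sc.lowdose_matrix(table)
    called, _ = sc.call_lowdose_sensitive(matrix, q_max=q_max)
    out["t6"] = len(called)
    return out


__all__ = ["pretreatments_in", "call_pretreatment", "compute_targets"]
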