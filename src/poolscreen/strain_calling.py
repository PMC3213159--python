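"""Multi-criterion identification of strains defective in acquired tolerance.

A strain is called by the stringent route when, in at least two replicates
(all on consensus fitness):

1. its severe-challenge z-score (S4vS3) is at least one standard deviation
   below the column mean,
2. its pretreatment-alone defect (S3vS1) is less than one standard
   deviation below the mean, and
3. its low-dose defect (S2vS1) is strictly smaller than its
   severe-challenge defect.

Called sets can then be expanded by fitness-profile correlation (guarded by
criterion 1), complemented by a two-dose rule for single-replicate
libraries, filtered by exclusion rules, and cross-checked against an
FDR-controlled low-dose sensitivity caller.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .fitness import COLUMN_LEVELS, consensus as _consensus, standardize

SECONDARY = "S4vS3"
SECONDARY_ALT = "S4AvS3"
PRETREAT_ALONE = "S3vS1"
LOW_DOSE = "S2vS1"

#: preference order when reconciling multiple libraries to one call per gene
LIBRARY_PRIORITY = ("homozygous", "damp", "heterozygous")


@dataclass
class StrainAudit:
    """Why a strain is (or is not) in a call set."""

    crit1_pass: bool = False
    crit2_pass: bool = False
    crit3_pass: bool = False
    n_replicates_passing: int = 0
    added_by_correlation: bool = False
    added_by_two_dose_rule: bool = False
    route: str = ""


@dataclass
class CallSet:
    """Strains called defective for one pretreatment, with audit flags."""

    pretreatment: str
    called: set[str] = field(default_factory=set)
    audit: dict[str, StrainAudit] = field(default_factory=dict)

    def copy(self) -> "CallSet":
        import copy

        return copy.deepcopy(self)


def _as_consensus(table: pd.DataFrame) -> pd.DataFrame:
    if table.columns.nlevels == 4:
        return _consensus(table)
    if table.columns.nlevels == 3:
        return table
    raise ValueError("fitness table must have 3 or 4 column levels")


def _column(cons: pd.DataFrame, pretreatment: str, comparison: str,
            replicate: int) -> pd.Series:
    key = (pretreatment, comparison, replicate)
    if key not in cons.columns:
        raise ConfigurationError(
            f"missing required comparison column {pretreatment} {comparison} "
            f"replicate {replicate}"
        )
    return cons[key]


def replicate_labels(cons: pd.DataFrame, pretreatment: str,
                     comparison: str = SECONDARY) -> list[int]:
    return sorted({
        rep for pre, comp, rep in cons.columns
        if pre == pretreatment and comp == comparison
    })


def criteria_frame(
    table: pd.DataFrame,
    pretreatment: str,
    z_threshold: float = 1.0,
    secondary: str = SECONDARY,
) -> pd.DataFrame:
    """Per-strain, per-replicate evaluation of criteria 1-3.

    Columns are a (replicate, criterion) MultiIndex of booleans; a missing
    fitness value fails the criterion that needs it.
    """
    cons = _as_consensus(table)
    reps = replicate_labels(cons, pretreatment, secondary)
    if not reps:
        raise ConfigurationError(
            f"no {secondary} columns for pretreatment {pretreatment!r}"
        )
    blocks = {}
    for rep in reps:
        f_sev = _column(cons, pretreatment, secondary, rep)
        f_pre = _column(cons, pretreatment, PRETREAT_ALONE, rep)
        f_low = _column(cons, pretreatment, LOW_DOSE, rep)
        z_sev = standardize(f_sev)
        z_pre = standardize(f_pre)
        blocks[(rep, "c1")] = (z_sev <= -z_threshold).fillna(False)
        blocks[(rep, "c2")] = (z_pre > -z_threshold).fillna(False)
        # larger defect = more negative; ties break toward exclusion
        blocks[(rep, "c3")] = (f_low > f_sev).fillna(False)
    out = pd.DataFrame(blocks)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["replicate", "criterion"])
    return out


def call_stringent(
    table: pd.DataFrame,
    pretreatment: str,
    z_threshold: float = 1.0,
    min_replicates: int = 2,
    secondary: str = SECONDARY,
) -> CallSet:
    """Stringent caller: criteria 1-3 jointly true in >= ``min_replicates``."""
    crit = criteria_frame(table, pretreatment, z_threshold, secondary)
    reps = crit.columns.get_level_values("replicate").unique()
    joint = pd.DataFrame({
        rep: crit[(rep, "c1")] & crit[(rep, "c2")] & crit[(rep, "c3")]
        for rep in reps
    })
    n_pass = joint.sum(axis=1)

    cs = CallSet(pretreatment=pretreatment)
    for strain in crit.index:
        audit = StrainAudit(
            crit1_pass=int(sum(crit[(r, "c1")][strain] for r in reps)) >= min_replicates,
            crit2_pass=int(sum(crit[(r, "c2")][strain] for r in reps)) >= min_replicates,
            crit3_pass=int(sum(crit[(r, "c3")][strain] for r in reps)) >= min_replicates,
            n_replicates_passing=int(n_pass[strain]),
        )
        if audit.n_replicates_passing >= min_replicates:
            audit.route = "stringent"
            cs.called.add(strain)
        cs.audit[strain] = audit
    return cs


def uncentered_correlation_candidates(
    table: pd.DataFrame, pretreatment: str
) -> pd.DataFrame:
    """All consensus columns for one pretreatment (the fitness vectors)."""
    cons = _as_consensus(table)
    cols = [c for c in cons.columns if c[0] == pretreatment]
    return cons[cols]


def expand_by_correlation(
    calls: CallSet,
    table: pd.DataFrame,
    r_min: float = 0.9,
    z_threshold: float = 1.0,
) -> CallSet:
    """Add uncalled strains whose fitness profile tracks a called strain.

    A strain joins the set when its uncentered Pearson correlation with any
    called strain's fitness vector reaches ``r_min`` AND it passes
    criterion 1 in at least one replicate (the guard that keeps the
    expansion bounded). No-op when the stringent set is empty.
    """
    if not 0.0 < r_min <= 1.0:
        raise ValueError("r_min must be in (0, 1]")
    out = calls.copy()
    if not calls.called:
        return out

    from .set_analysis import uncentered_pearson

    vectors = uncentered_correlation_candidates(table, calls.pretreatment)
    crit = criteria_frame(table, calls.pretreatment, z_threshold)
    reps = crit.columns.get_level_values("replicate").unique()
    guard = pd.DataFrame({r: crit[(r, "c1")] for r in reps}).any(axis=1)

    called_vecs = vectors.loc[sorted(calls.called & set(vectors.index))]
    for strain in vectors.index:
        if strain in out.called or not guard.get(strain, False):
            continue
        x = vectors.loc[strain]
        for _, y in called_vecs.iterrows():
            ok = x.notna() & y.notna()
            if ok.sum() < 2:
                continue
            r = uncentered_pearson(x[ok].to_numpy(), y[ok].to_numpy())
            if not np.isnan(r) and r >= r_min:
                out.called.add(strain)
                audit = out.audit.setdefault(strain, StrainAudit())
                audit.added_by_correlation = True
                audit.route = "correlation"
                break
    return out


def call_single_replicate(
    table: pd.DataFrame,
    pretreatment: str,
    library: str,
    library_of: Mapping[str, str],
    gene_of: Mapping[str, str],
    z_threshold: float = 1.0,
) -> CallSet:
    """Caller for libraries assayed once: two doses, or multiple libraries.

    A strain of the single-replicate ``library`` is called when criteria
    1-3 hold for both the 1.0 mM (S4vS3) and the 1.2 mM (S4AvS3) severe
    doses in its replicate, or when mutants of the same gene pass the
    criteria in at least two libraries. Raises when the library actually
    has more than one replicate (use :func:`call_stringent` there).
    """
    cons = _as_consensus(table)
    lib_strains = [s for s in cons.index if library_of.get(s) == library]
    if not lib_strains:
        raise ConfigurationError(f"no strains of library {library!r} in table")

    reps_with_data = [
        rep for rep in replicate_labels(cons, pretreatment)
        if cons[(pretreatment, SECONDARY, rep)].reindex(lib_strains).notna().any()
    ]
    if len(reps_with_data) > 1:
        raise ConfigurationError(
            f"library {library!r} has {len(reps_with_data)} replicates; "
            "the single-replicate caller does not apply"
        )

    crit_main = criteria_frame(cons, pretreatment, z_threshold, SECONDARY)
    crit_alt = criteria_frame(cons, pretreatment, z_threshold, SECONDARY_ALT)

    def passes(crit: pd.DataFrame, strain: str) -> bool:
        reps = crit.columns.get_level_values("replicate").unique()
        return any(
            bool(crit[(r, "c1")][strain] and crit[(r, "c2")][strain]
                 and crit[(r, "c3")][strain])
            for r in reps
        )

    # gene -> libraries whose mutant passes the criteria at the 1.0 mM dose
    passing_libs: dict[str, set[str]] = {}
    for strain in cons.index:
        if passes(crit_main, strain):
            gene = gene_of.get(strain)
            lib = library_of.get(strain)
            if gene and lib:
                passing_libs.setdefault(gene, set()).add(lib)

    cs = CallSet(pretreatment=pretreatment)
    for strain in lib_strains:
        audit = StrainAudit()
        main_ok = passes(crit_main, strain)
        if main_ok and passes(crit_alt, strain):
            audit.added_by_two_dose_rule = True
            audit.route = "two_dose"
            cs.called.add(strain)
        elif main_ok and len(passing_libs.get(gene_of.get(strain, ""), ())) >= 2:
            audit.route = "multi_library"
            cs.called.add(strain)
        audit.n_replicates_passing = int(main_ok)
        cs.audit[strain] = audit
    return cs


def lowdose_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Collect every low-dose (S2vS1) consensus column across replicates."""
    cons = _as_consensus(table)
    cols = [c for c in cons.columns if c[1] == LOW_DOSE]
    return cons[cols]


def call_lowdose_sensitive(
    matrix: pd.DataFrame,
    q_max: float = 0.05,
    method: str = "t",
) -> tuple[set[str], pd.DataFrame]:
    """Strains with a significant mean low-dose fitness defect.

    One-sample test of mean fitness < 0 per strain across replicate
    columns (``method='t'`` for the t-test, ``'wilcoxon'`` for the
    rank-based alternative), Benjamini-Hochberg q-values, and a q < q_max
    cutoff with a negative-mean requirement. Requires >= 3 replicates.
    """
    if matrix.shape[1] < 3:
        raise ValueError("low-dose calling requires at least 3 replicates")
    values = matrix.to_numpy(dtype=float)
    means = np.nanmean(values, axis=1)
    pvals = np.full(len(matrix), np.nan)
    for i, row in enumerate(values):
        vals = row[~np.isnan(row)]
        if vals.size < 2:
            continue
        if np.ptp(vals) == 0:
            # zero-variance limit of the t statistic: +/-inf
            pvals[i] = 0.0 if vals[0] < 0 else 1.0
            continue
        if method == "t":
            pvals[i] = stats.ttest_1samp(vals, 0.0, alternative="less").pvalue
        elif method == "wilcoxon":
            pvals[i] = stats.wilcoxon(vals, alternative="less").pvalue
        else:
            raise ValueError(f"unknown method {method!r}")
    tested = ~np.isnan(pvals)
    qvals = np.full(len(matrix), np.nan)
    if tested.any():
        qvals[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    result = pd.DataFrame(
        {"mean_fitness": means, "p": pvals, "q": qvals}, index=matrix.index
    )
    called = set(result.index[(result["q"] < q_max) & (result["mean_fitness"] < 0)])
    return called, result


def apply_exclusions(
    acquired: CallSet,
    lowdose: set[str],
    table: pd.DataFrame,
    z_threshold: float = 1.0,
    equal_tol: float = 0.0,
) -> CallSet:
    """Drop strains whose defect is not specific to acquisition.

    Removes (a) strains whose mean low-dose defect is as large as (within
    ``equal_tol`` of) their mean severe-challenge defect, and (b) strains
    sensitive to the pretreatment alone (mean pretreatment z-score at or
    below the criterion-2 threshold). Idempotent.
    """
    cons = _as_consensus(table)
    pre = acquired.pretreatment
    reps = replicate_labels(cons, pre)
    f_sev = pd.concat([_column(cons, pre, SECONDARY, r) for r in reps], axis=1)
    f_low = pd.concat([_column(cons, pre, LOW_DOSE, r) for r in reps], axis=1)
    z_pre = pd.concat(
        [standardize(_column(cons, pre, PRETREAT_ALONE, r)) for r in reps], axis=1
    )
    mean_sev = f_sev.mean(axis=1)
    mean_low = f_low.mean(axis=1)
    mean_zpre = z_pre.mean(axis=1)

    out = acquired.copy()
    for strain in sorted(out.called):
        equal_defect = (
            not np.isnan(mean_low.get(strain, np.nan))
            and mean_low[strain] <= mean_sev[strain] + equal_tol
        )
        pre_sensitive = (
            not np.isnan(mean_zpre.get(strain, np.nan))
            and mean_zpre[strain] <= -z_threshold
        )
        if equal_defect or pre_sensitive:
            out.called.discard(strain)
            audit = out.audit.setdefault(strain, StrainAudit())
            audit.route = ("excluded_equal_defect" if equal_defect
                           else "excluded_pretreatment_sensitive")
    _ = lowdose  # membership is informational; exclusions act on fitness
    return out


def reconcile_genes(
    calls: CallSet, gene_of: Mapping[str, str], library_of: Mapping[str, str]
) -> dict[str, str]:
    """One representative called strain per gene, preferring
    homozygous > DAmP > heterozygous."""
    rank = {lib: i for i, lib in enumerate(LIBRARY_PRIORITY)}
    best: dict[str, str] = {}
    for strain in sorted(calls.called):
        gene = gene_of.get(strain, strain)
        cur = best.get(gene)
        if cur is None or (rank.get(library_of.get(strain, ""), 99)
                           < rank.get(library_of.get(cur, ""), 99)):
            best[gene] = strain
    return best


def write_calls(callsets: list[CallSet], gene_of: Mapping[str, str], path) -> None:
    """TSV call list: gene, strain, pretreatment, route, audit flags."""
    rows = []
    for cs in callsets:
        for strain in sorted(cs.called):
            a = cs.audit.get(strain, StrainAudit())
            rows.append(
                (gene_of.get(strain, strain), strain, cs.pretreatment, a.route,
                 a.crit1_pass, a.crit2_pass, a.crit3_pass,
                 a.n_replicates_passing, a.added_by_correlation,
                 a.added_by_two_dose_rule)
            )
    pd.DataFrame(
        rows,
        columns=["gene", "strain", "pretreatment", "route", "crit1_pass",
                 "crit2_pass", "crit3_pass", "n_replicates_passing",
                 "added_by_correlation", "added_by_two_dose_rule"],
    ).to_csv(path, sep="\t", index=False)


__all__ = [
    "StrainAudit",
    "CallSet",
    "criteria_frame",
    "call_stringent",
    "expand_by_correlation",
    "call_single_replicate",
    "lowdose_matrix",
    "call_lowdose_sensitive",
    "apply_exclusions",
    "reconcile_genes",
    "write_calls",
    "SECONDARY",
    "SECONDARY_ALT",
    "PRETREAT_ALONE",
    "LOW_DOSE",
]
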