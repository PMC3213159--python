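"""End-to-end screen orchestration on synthetic inputs.

Chains the simulator, quantification, and fitness stages into one call so
tests, the CLI, and the acceptance report can produce a fitness table (and
known planted truth) from nothing but a seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tag_quant
from .fitness import Comparison, build_table, compute_fitness, half_count_floor
from .saturation import desaturate
from .synthetic_pool import (
    PoolState,
    SelectionDesign,
    StrainSpec,
    generate_array,
    generate_reads,
    make_indexes,
    simulate_selection,
    standard_design,
)

LOW_DOSE_LABEL = "H2O2_0.4mM"


def severe_label(pretreatment: str, dose: str = "1.0") -> str:
    """Stress label for the severe challenge given after a pretreatment.

    Acquired-resistance defects are pretreatment context dependent, so the
    severe dose is labelled per pretreatment arm.
    """
    return f"H2O2_{dose}mM:{pretreatment}"


def design_for(pretreatment: str, generations: int = 10) -> SelectionDesign:
    return standard_design(
        pretreatment=pretreatment,
        low_dose=LOW_DOSE_LABEL,
        severe=severe_label(pretreatment, "1.0"),
        severe_alt=severe_label(pretreatment, "1.2"),
        generations=generations,
    )


@dataclass
class PlantedTruth:
    """Which strains carry which planted defect."""

    acquired: dict[str, set[str]] = field(default_factory=dict)  # per pretreatment
    pretreat_sensitive: set[str] = field(default_factory=set)
    uniform_sensitive: set[str] = field(default_factory=set)

    def acquired_any(self) -> set[str]:
        out: set[str] = set()
        for s in self.acquired.values():
            out |= s
        return out


def plant_defects(
    catalog: list[StrainSpec],
    pretreatments: list[str],
    seed: int = 0,
    n_acquired: int = 0,
    acquired_survival: float = 0.2,
    n_pretreat_sensitive: int = 0,
    pretreat_survival: float = 0.3,
    n_uniform_sensitive: int = 0,
    uniform_survival: float = 0.5,
    acquired_pretreatments: list[str] | None = None,
) -> PlantedTruth:
    """Assign planted survival defects to disjoint random strain subsets.

    * acquired defect: reduced survival at the severe doses (all listed
      pretreatment arms), wild type everywhere else;
    * pretreatment-sensitive: reduced survival of the mild stress itself;
    * uniformly sensitive: the same reduced survival at the low and severe
      doses (no acquisition-specific signal).
    Mutates the catalog's survival maps in place and returns the truth.
    """
    rng = np.random.default_rng(seed)
    n_total = n_acquired + n_pretreat_sensitive + n_uniform_sensitive
    if n_total > len(catalog):
        raise ValueError("more planted strains than catalog members")
    picks = rng.choice(len(catalog), size=n_total, replace=False)
    acq = picks[:n_acquired]
    pre_sens = picks[n_acquired:n_acquired + n_pretreat_sensitive]
    uni = picks[n_acquired + n_pretreat_sensitive:]

    truth = PlantedTruth()
    arms = acquired_pretreatments if acquired_pretreatments is not None else pretreatments
    for i in acq:
        strain = catalog[i]
        for pre in arms:
            strain.survival[severe_label(pre, "1.0")] = acquired_survival
            strain.survival[severe_label(pre, "1.2")] = acquired_survival
            truth.acquired.setdefault(pre, set()).add(strain.strain_id)
    for pre in arms:
        truth.acquired.setdefault(pre, set())
    for i in pre_sens:
        strain = catalog[i]
        for pre in pretreatments:
            strain.survival[pre] = pretreat_survival
        truth.pretreat_sensitive.add(strain.strain_id)
    for i in uni:
        strain = catalog[i]
        strain.survival[LOW_DOSE_LABEL] = uniform_survival
        for pre in pretreatments:
            strain.survival[severe_label(pre, "1.0")] = uniform_survival
            strain.survival[severe_label(pre, "1.2")] = uniform_survival
        truth.uniform_sensitive.add(strain.strain_id)
    return truth


def needed_samples(comparisons: tuple[str, ...]) -> list[str]:
    out: set[str] = set()
    for name in comparisons:
        num, den = name.split("v", 1)
        out |= {num, den}
    return sorted(out)


def simulate_states(
    catalog: list[StrainSpec],
    pretreatments: list[str],
    generations: int = 10,
) -> dict[str, dict[str, PoolState]]:
    """Deterministic pool states per pretreatment arm."""
    states = {}
    for pre in pretreatments:
        design = design_for(pre, generations=generations)
        states[pre] = simulate_selection(
            catalog, design, stresses=design.stresses
        )
    return states


def run_screen(
    catalog: list[StrainSpec],
    pretreatments: list[str],
    n_replicates: int = 2,
    depth: int = 100_000,
    error_rate: float = 0.0,
    seed: int = 0,
    tag_classes: tuple[str, ...] = ("up", "down"),
    comparisons: tuple[str, ...] = ("S2vS1", "S3vS1", "S4vS3"),
    floor: float | None = None,
) -> pd.DataFrame:
    """Sequencing-platform screen: reads -> counts -> abundances -> fitness.

    Replicate-to-replicate variability comes from independent read draws.
    Returns a 4-level fitness table with platforms UP/DN.
    """
    if floor is None:
        floor = half_count_floor(depth)
    rng = np.random.default_rng(seed)
    arm_states = simulate_states(catalog, pretreatments)
    samples = needed_samples(comparisons)

    labels = [f"{pre}{rep}:{s}" for pre in pretreatments
              for rep in range(1, n_replicates + 1) for s in samples]
    idx_seqs = make_indexes(len(labels), seed=seed)
    samplesheet = dict(zip(idx_seqs, labels))
    index_of = dict(zip(labels, idx_seqs))

    platform_of = {"up": "UP", "down": "DN"}
    columns: dict[Comparison, pd.Series] = {}
    for pre in pretreatments:
        for rep in range(1, n_replicates + 1):
            abundances: dict[str, dict[str, pd.Series]] = {}
            for s in samples:
                label = f"{pre}{rep}:{s}"
                per_class = {}
                for cls in tag_classes:
                    reads = generate_reads(
                        arm_states[pre][s],
                        catalog,
                        depth=depth,
                        error_rate=error_rate,
                        multiplex_index=index_of[label],
                        seed=int(rng.integers(2**31)),
                        tag_class=cls,
                        as_matrix=True,
                    )
                    counts = tag_quant.count_tags(
                        reads, catalog, samplesheet, label, tag_class=cls
                    )
                    ab = tag_quant.to_abundance(counts, catalog)
                    per_class[cls] = ab.per_class[cls]
                abundances[s] = per_class
            for name in comparisons:
                num, den = name.split("v", 1)
                for cls in tag_classes:
                    comp = Comparison(pre, name, rep, platform_of[cls])
                    columns[comp] = compute_fitness(
                        abundances[num][cls], abundances[den][cls], floor=floor
                    )
    return build_table(columns)


def array_abundances(
    states: dict[str, PoolState],
    catalog: list[StrainSpec],
    scale: float = 1e6,
    saturation_K: float | None = None,
    imax: float = 65535.0,
    noise_cv: float = 0.0,
    outlier_rate: float = 0.0,
    min_features: int = 3,
    quantile: bool = True,
    seed: int = 0,
) -> dict[str, dict[str, pd.Series]]:
    """Array-platform quantification for a set of samples.

    Feature tables -> outlier-robust per-tag means -> (optional) quantile
    normalization across arrays per tag class -> saturation correction ->
    per-class relative abundances.
    """
    rng = np.random.default_rng(seed)
    summaries = {}
    for label, state in states.items():
        table = generate_array(
            state, catalog, scale=scale, saturation_K=saturation_K,
            noise_cv=noise_cv, outlier_rate=outlier_rate,
            seed=int(rng.integers(2**31)), imax=imax,
        )
        summaries[label] = tag_quant.summarize_features(
            table, min_features=min_features
        )["mean_intensity"]

    out: dict[str, dict[str, pd.Series]] = {label: {} for label in states}
    for cls in ("up", "down"):
        mat = pd.DataFrame({
            label: summ.xs(cls, level="tag_class")
            for label, summ in summaries.items()
        })
        if quantile:
            mat = tag_quant.quantile_normalize(mat)
        corrected = pd.DataFrame(
            desaturate(mat.to_numpy(), imax=imax, k=saturation_K),
            index=mat.index, columns=mat.columns,
        )
        for label in states:
            col = corrected[label]
            total = col.sum(skipna=True)
            if total <= 0:
                raise ValueError(f"zero total corrected intensity in {label}")
            out[label][cls] = col / total
    return out


def run_screen_arrays(
    catalog: list[StrainSpec],
    pretreatments: list[str],
    n_replicates: int = 1,
    seed: int = 0,
    comparisons: tuple[str, ...] = ("S2vS1", "S3vS1", "S4vS3"),
    floor: float = 0.0,
    **array_kwargs,
) -> pd.DataFrame:
    """Array-platform screen returning a 4-level table (platform 'Array')."""
    arm_states = simulate_states(catalog, pretreatments)
    samples = needed_samples(comparisons)
    rng = np.random.default_rng(seed)

    columns: dict[Comparison, pd.Series] = {}
    for pre in pretreatments:
        for rep in range(1, n_replicates + 1):
            states = {s: arm_states[pre][s] for s in samples}
            ab = array_abundances(
                states, catalog, seed=int(rng.integers(2**31)), **array_kwargs
            )
            for name in comparisons:
                num, den = name.split("v", 1)
                comp = Comparison(pre, name, rep, "Array")
                per_strain = {}
                for cls in ("up", "down"):
                    per_strain[cls] = compute_fitness(
                        ab[num][cls], ab[den][cls], floor=floor
                    )
                columns[comp] = pd.concat(per_strain.values(), axis=1).mean(
                    axis=1, skipna=True
                )
    return build_table(columns)


__all__ = [
    "LOW_DOSE_LABEL",
    "severe_label",
    "design_for",
    "PlantedTruth",
    "plant_defects",
    "needed_samples",
    "simulate_states",
    "run_screen",
    "array_abundances",
    "run_screen_arrays",
]
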