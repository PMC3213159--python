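"""Synthetic pooled-selection screens with planted ground truth.

Generates everything a barcode screen produces — a strain catalog with
unique 20-bp up/down tags, deterministic selection/outgrowth population
dynamics over a sample design, multiplexed barcode reads (FASTQ), and
replicated array feature intensities — so the downstream quantification,
fitness, and calling stages can be tested end to end with known answers.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import (
    decode,
    encode,
    encode_many,
    random_unique_tags,
)
from .errors import ConfigurationError
from .saturation import saturate

# -- read layout ------------------------------------------------------------
# index + common flank + tag, positional; one tag class per read set.
INDEX_LEN = 6
TAG_LEN = 20
UP_FLANK = "GATGTCCACGAGGTCTCT"
DOWN_FLANK = "CGAGCTCGAATTCATCGA"
FLANKS = {"up": UP_FLANK, "down": DOWN_FLANK}
READ_LEN = INDEX_LEN + len(UP_FLANK) + TAG_LEN
TAG_SLICE = slice(INDEX_LEN + len(UP_FLANK), READ_LEN)

LIBRARIES = ("homozygous", "heterozygous", "damp")

DEFAULT_LIBRARY_SIZES = {"homozygous": 4800, "heterozygous": 1300, "damp": 1140}


@dataclass
class StrainSpec:
    """One pooled-library member with its simulation-truth parameters.

    ``survival`` maps a stress label to the fraction of cells surviving that
    treatment; labels absent from the map behave like wild type (1.0).
    ``growth_rate`` is relative doublings per outgrowth generation.
    """

    strain_id: str
    gene: str
    library: str
    up_tag: str
    down_tag: str
    growth_rate: float = 1.0
    survival: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.library not in LIBRARIES:
            raise ValueError(f"unknown library {self.library!r}")
        for tag in (self.up_tag, self.down_tag):
            if len(tag) != TAG_LEN:
                raise ValueError(f"tags must be {TAG_LEN} bp, got {tag!r}")
        if not self.growth_rate > 0:
            raise ValueError("growth_rate must be positive")
        for label, frac in self.survival.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"survival[{label!r}] = {frac} outside [0, 1]")


@dataclass(frozen=True)
class Edge:
    """One treatment step: an optional stress followed by outgrowth."""

    src: str
    dst: str
    stress: str | None = None
    generations: int = 0

    def __post_init__(self) -> None:
        if self.generations < 0:
            raise ValueError("generations must be non-negative")


@dataclass
class SelectionDesign:
    """Directed acyclic sample graph rooted at a single start sample."""

    edges: list[Edge]

    def __post_init__(self) -> None:
        dsts = [e.dst for e in self.edges]
        if len(set(dsts)) != len(dsts):
            raise ConfigurationError("each sample may be produced by one edge only")
        srcs = {e.src for e in self.edges}
        roots = srcs - set(dsts)
        if len(roots) != 1:
            raise ConfigurationError(
                f"design must have exactly one root sample, found {sorted(roots)}"
            )
        self.root = roots.pop()

    @property
    def nodes(self) -> list[str]:
        seen = [self.root]
        for e in self._ordered():
            seen.append(e.dst)
        return seen

    def _ordered(self) -> list[Edge]:
        """Edges in a parent-before-child order."""
        ready = {self.root}
        pending = list(self.edges)
        out: list[Edge] = []
        while pending:
            progress = False
            for e in list(pending):
                if e.src in ready:
                    out.append(e)
                    ready.add(e.dst)
                    pending.remove(e)
                    progress = True
            if not progress:
                raise ConfigurationError("design graph is not reachable from root")
        return out

    @property
    def stresses(self) -> set[str]:
        return {e.stress for e in self.edges if e.stress is not None}


def standard_design(
    pretreatment: str = "NaCl",
    low_dose: str = "H2O2_0.4mM",
    severe: str = "H2O2_1.0mM",
    severe_alt: str = "H2O2_1.2mM",
    generations: int = 10,
) -> SelectionDesign:
    """The six-sample selection design.

    S0 (log-phase pool) -> S1 (outgrowth control), S2 (low-dose challenge),
    S3 (pretreatment alone); S3 -> S4/S4A (severe challenge at two doses).
    Every outgrowth is a fixed number of generations so dead cells are
    diluted identically in every arm.
    """
    return SelectionDesign(
        edges=[
            Edge("S0", "S1", None, generations),
            Edge("S0", "S2", low_dose, generations),
            Edge("S0", "S3", pretreatment, generations),
            Edge("S3", "S4", severe, generations),
            Edge("S3", "S4A", severe_alt, generations),
        ]
    )


@dataclass
class PoolState:
    """Relative strain frequencies for one sample."""

    sample: str
    abundance: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.fromiter(self.abundance.values(), dtype=float)
        if vals.size and (vals < 0).any():
            raise ValueError("frequencies must be non-negative")
        if vals.size and abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {vals.sum()}, expected 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.abundance, dtype=float)


# -- catalog ---------------------------------------------------------------

def make_catalog(
    n_homozygous: int = 100,
    n_heterozygous: int = 0,
    n_damp: int = 0,
    seed: int = 0,
    tag_len: int = TAG_LEN,
    min_tag_dist: int = 5,
) -> list[StrainSpec]:
    """Build a catalog with unique tags (pairwise Hamming distance >= 5).

    DAmP strains reuse the heterozygous genes when both libraries are
    requested (matching how DAmP alleles target essential genes); otherwise
    every strain gets its own gene.
    """
    rng = np.random.default_rng(seed)
    n_total = n_homozygous + n_heterozygous + n_damp
    tags = random_unique_tags(rng, 2 * n_total, length=tag_len, min_dist=min_tag_dist)
    catalog: list[StrainSpec] = []
    i = 0
    gene_counter = 0

    def next_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"GENE{gene_counter:05d}"

    het_genes: list[str] = []
    for library, n in (
        ("homozygous", n_homozygous),
        ("heterozygous", n_heterozygous),
        ("damp", n_damp),
    ):
        for j in range(n):
            if library == "damp" and j < len(het_genes):
                gene = het_genes[j]
            else:
                gene = next_gene()
            if library == "heterozygous":
                het_genes.append(gene)
            catalog.append(
                StrainSpec(
                    strain_id=f"{library[:3]}_{gene}",
                    gene=gene,
                    library=library,
                    up_tag=tags[2 * i],
                    down_tag=tags[2 * i + 1],
                )
            )
            i += 1
    return catalog


def make_indexes(n: int, seed: int = 0, length: int = INDEX_LEN,
                 min_dist: int = 3) -> list[str]:
    """Multiplex indexes separated enough for one-mismatch demultiplexing."""
    rng = np.random.default_rng(seed)
    return random_unique_tags(rng, n, length=length, min_dist=min_dist)


# -- selection dynamics ----------------------------------------------------

def simulate_selection(
    catalog: list[StrainSpec],
    design: SelectionDesign,
    seed: int = 0,
    start: dict[str, float] | None = None,
    bottleneck_size: int | None = None,
    stresses: set[str] | None = None,
) -> dict[str, PoolState]:
    """Propagate strain frequencies through the selection design.

    A stress edge multiplies each strain's frequency by its surviving
    fraction (dead cells are removed immediately; the later outgrowth then
    only expresses growth-rate differences) and renormalizes. An outgrowth
    of ``g`` generations multiplies by ``2**(g*(growth_rate-1))`` and
    renormalizes. Deterministic given ``seed``; the seed only matters when
    ``bottleneck_size`` switches on multinomial resampling after each edge.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    known = set(stresses or ())
    for s in catalog:
        known.update(s.survival)
    for label in design.stresses:
        if label not in known:
            raise ConfigurationError(
                f"stress label {label!r} in design is not defined for any strain "
                "(pass stresses=... to allow labels with all-wild-type survival)"
            )

    ids = [s.strain_id for s in catalog]
    n = len(ids)
    if start is None:
        freq = np.full(n, 1.0 / n)
    else:
        freq = np.array([start.get(i, 0.0) for i in ids], dtype=float)
        if (freq < 0).any() or freq.sum() <= 0:
            raise ValueError("start frequencies must be non-negative with positive sum")
        freq = freq / freq.sum()

    growth = np.array([s.growth_rate for s in catalog])
    rng = np.random.default_rng(seed)

    def renorm(f: np.ndarray, where: str) -> np.ndarray:
        total = f.sum()
        if total <= 0:
            raise ConfigurationError(f"pool went extinct at sample {where}")
        return f / total

    states = {design.root: PoolState(design.root, dict(zip(ids, freq)))}
    freqs = {design.root: freq}
    for edge in design._ordered():
        f = freqs[edge.src].copy()
        if edge.stress is not None:
            surv = np.array([s.survival.get(edge.stress, 1.0) for s in catalog])
            f = renorm(f * surv, edge.dst)
        if edge.generations:
            f = renorm(f * 2.0 ** (edge.generations * (growth - 1.0)), edge.dst)
        if bottleneck_size:
            f = renorm(
                rng.multinomial(bottleneck_size, f).astype(float), edge.dst
            )
        freqs[edge.dst] = f
        states[edge.dst] = PoolState(edge.dst, dict(zip(ids, f)))
    return states


# -- barcode reads ---------------------------------------------------------

def generate_reads(
    state: PoolState,
    catalog: list[StrainSpec],
    depth: int,
    error_rate: float,
    multiplex_index: str,
    seed: int = 0,
    tag_class: str = "up",
    as_matrix: bool = False,
):
    """Draw ``depth`` barcode reads from a pool state.

    Each read is index + common flank + tag. The strain of each read is
    drawn multinomially from the state's frequencies; substitution errors
    hit every base i.i.d. at ``error_rate`` (no indels — tags are fixed
    length so mapping stays positional).

    Returns a list of read strings, or the raw (depth, read_len) uint8
    matrix when ``as_matrix`` is set (cheaper for large simulations).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    if len(multiplex_index) != INDEX_LEN:
        raise ValueError(f"multiplex index must be {INDEX_LEN} bp")
    if tag_class not in FLANKS:
        raise ValueError("tag_class must be 'up' or 'down'")

    rng = np.random.default_rng(seed)
    p = np.array([state.abundance[s.strain_id] for s in catalog])
    p = p / p.sum()
    counts = rng.multinomial(depth, p)

    tag_mat = encode_many(
        [s.up_tag if tag_class == "up" else s.down_tag for s in catalog]
    )
    strain_of_read = np.repeat(np.arange(len(catalog)), counts)
    rng.shuffle(strain_of_read)

    reads = np.empty((depth, READ_LEN), dtype=np.uint8)
    prefix = encode(multiplex_index + FLANKS[tag_class])
    reads[:, : len(prefix)] = prefix
    reads[:, TAG_SLICE] = tag_mat[strain_of_read]

    if error_rate > 0:
        mask = rng.random(reads.shape, dtype=np.float32) < error_rate
        n_err = int(mask.sum())
        if n_err:
            from ._seq import _BASE_ARR, base_indices

            old = base_indices(reads[mask])
            new = (old + rng.integers(1, 4, size=n_err)) % 4
            reads[mask] = _BASE_ARR[new]

    if as_matrix:
        return reads
    return [decode(row) for row in reads]


def write_fastq(path, reads, prefix: str = "read", quality: str = "I") -> None:
    """Write reads (strings or a uint8 matrix) as FASTQ with constant quality."""
    if isinstance(reads, np.ndarray):
        reads = [decode(row) for row in reads]
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{quality * len(seq)}\n")


# -- array intensities -----------------------------------------------------

def generate_array(
    state: PoolState,
    catalog: list[StrainSpec],
    scale: float = 1e6,
    saturation_K: float | None = None,
    features_per_tag: int = 5,
    noise_cv: float = 0.0,
    outlier_rate: float = 0.0,
    seed: int = 0,
    imax: float = 65535.0,
    background: float = 0.0,
) -> pd.DataFrame:
    """Simulate replicated array feature intensities for one sample.

    True signal ``s = scale * frequency`` goes through the saturating
    response ``I = Imax*s/(s+K)`` (linear when K is None/inf), then each of
    the ``features_per_tag`` features gets multiplicative log-normal noise
    of coefficient ``noise_cv``; with probability ``outlier_rate`` a feature
    is replaced by a uniform outlier in [0, Imax].

    Returns a long table: feature_id, tag_id, tag_class, replicate, intensity.
    """
    if features_per_tag < 1:
        raise ValueError("features_per_tag must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if not 0.0 <= outlier_rate <= 1.0:
        raise ValueError("outlier_rate must be in [0, 1]")

    rng = np.random.default_rng(seed)
    rows = []
    freq = np.array([state.abundance[s.strain_id] for s in catalog])
    for tag_class in ("up", "down"):
        signal = saturate(scale * freq, imax=imax, k=saturation_K) + background
        intens = np.repeat(signal, features_per_tag).reshape(len(catalog),
                                                            features_per_tag)
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv**2))
            noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma,
                                  size=intens.shape)
            intens = intens * noise
        if outlier_rate > 0:
            out_mask = rng.random(intens.shape) < outlier_rate
            intens = np.where(out_mask, rng.uniform(0, imax, size=intens.shape),
                              intens)
        for i, strain in enumerate(catalog):
            for r in range(features_per_tag):
                rows.append(
                    (
                        f"{strain.strain_id}_{tag_class}_f{r + 1}",
                        strain.strain_id,
                        tag_class,
                        r + 1,
                        float(intens[i, r]),
                    )
                )
    return pd.DataFrame(
        rows, columns=["feature_id", "tag_id", "tag_class", "replicate", "intensity"]
    )


# -- plain-text IO ---------------------------------------------------------

def write_catalog(catalog: list[StrainSpec], path, include_truth: bool = False) -> None:
    rows = []
    for s in catalog:
        row = {
            "strain_id": s.strain_id,
            "gene": s.gene,
            "library": s.library,
            "up_tag": s.up_tag,
            "down_tag": s.down_tag,
        }
        if include_truth:
            row["growth_rate"] = s.growth_rate
            row["survival"] = json.dumps(s.survival)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_catalog(path) -> list[StrainSpec]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        out.append(
            StrainSpec(
                strain_id=row["strain_id"],
                gene=row["gene"],
                library=row["library"],
                up_tag=row["up_tag"],
                down_tag=row["down_tag"],
                growth_rate=float(row.get("growth_rate", 1.0) or 1.0),
                survival=json.loads(row["survival"]) if "survival" in df.columns
                and isinstance(row.get("survival"), str) else {},
            )
        )
    return out


def write_samplesheet(indexes: dict[str, str], path) -> None:
    """TSV mapping sample label -> 6-bp multiplex index."""
    pd.DataFrame(
        sorted(indexes.items()), columns=["sample", "index"]
    ).to_csv(path, sep="\t", index=False)


def read_samplesheet(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample"], df["index"]))


def write_truth(states: dict[str, PoolState], path) -> None:
    rows = [
        (label, sid, freq)
        for label, st in states.items()
        for sid, freq in st.abundance.items()
    ]
    pd.DataFrame(rows, columns=["sample", "strain_id", "frequency"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path) -> dict[str, PoolState]:
    df = pd.read_csv(path, sep="\t")
    states = {}
    for label, sub in df.groupby("sample"):
        states[label] = PoolState(
            str(label), dict(zip(sub["strain_id"], sub["frequency"]))
        )
    return states


__all__ = [
    "StrainSpec",
    "Edge",
    "SelectionDesign",
    "PoolState",
    "standard_design",
    "make_catalog",
    "make_indexes",
    "simulate_selection",
    "generate_reads",
    "generate_array",
    "write_fastq",
    "write_catalog",
    "read_catalog",
    "write_samplesheet",
    "read_samplesheet",
    "write_truth",
    "read_truth",
    "INDEX_LEN",
    "TAG_LEN",
    "READ_LEN",
    "UP_FLANK",
    "DOWN_FLANK",
    "TAG_SLICE",
    "LIBRARIES",
    "DEFAULT_LIBRARY_SIZES",
]
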