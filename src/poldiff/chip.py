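"""Input-subtracted, TSS-anchored aggregate ChIP occupancy profiles.

Starting from aligned read intervals (BED), the module bins per-base
coverage, subtracts the input-library signal from the ChIP signal (both on a
reads-per-million scale), and averages the result over fixed windows flanking
the transcription start sites of a gene class — 100 windows of 10 bp on each
side of the TSS by default.  Comparing the wild-type and mutant aggregate
profiles per class yields a single occupancy ratio per class, the quantity
that separates polymerase-III target genes (tRNA, 5S, type-3 promoters) from
the polymerase-I rDNA control.

Coordinates are BED-style 0-based half-open throughout; the TSS of a
minus-strand gene is its highest coordinate and window index 0 is always the
most-upstream window in gene orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    ComparisonError,
    EmptyClassError,
    FormatError,
    GridError,
    ValidationError,
)

__all__ = [
    "GENE_CLASSES",
    "GeneAnnotation",
    "BinnedSignal",
    "ProfileConfig",
    "AggregateProfile",
    "OccupancyComparison",
    "read_chrom_sizes",
    "read_annotations",
    "load_signal",
    "normalize_subtract_input",
    "aggregate_profile",
    "compare_occupancy",
]

GENE_CLASSES = ("type1", "type2", "type3", "rDNA")


@dataclass(frozen=True)
class GeneAnnotation:
    """A TSS anchor: gene id, chromosome, 0-based TSS, strand, promoter class.

    Classes: type1 = internal A+C-box promoters (5S rRNA), type2 = internal
    A+B-box promoters (tRNAs), type3 = upstream promoters (U6, 7SK, RNase P),
    rDNA = the polymerase-I ribosomal repeat control.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    gene_class: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValidationError(f"gene {self.gene_id!r}: tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id!r}: strand must be + or -")
        if self.gene_class not in GENE_CLASSES:
            raise ValidationError(
                f"gene {self.gene_id!r}: unknown class {self.gene_class!r}"
            )


@dataclass(frozen=True)
class ProfileConfig:
    n_windows_per_side: int = 100
    window_width: int = 10

    def __post_init__(self) -> None:
        if self.n_windows_per_side <= 0 or self.window_width <= 0:
            raise ValidationError("profile window parameters must be positive")

    @property
    def n_windows(self) -> int:
        return 2 * self.n_windows_per_side


@dataclass
class BinnedSignal:
    """Per-chromosome binned coverage.

    ``bins[chrom][i]`` is the mean per-base read depth over bases
    ``[i*bin_width, (i+1)*bin_width)`` (a trailing partial bin averages over
    its actual width).  ``state`` tracks the normalization applied.
    """

    bins: dict[str, np.ndarray]
    bin_width: int
    library_size: float
    chrom_sizes: dict[str, int]
    state: str = "raw"  # raw | rpm | input_subtracted

    def value_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Per-base signal (the containing bin's mean) at 0-based positions."""
        return self.bins[chrom][positions // self.bin_width]


@dataclass
class AggregateProfile:
    gene_class: str
    values: np.ndarray  # length 2 * n_windows_per_side, upstream first
    n_genes: int
    config: ProfileConfig

    def offsets_bp(self) -> np.ndarray:
        """Start offset of each window relative to the TSS, gene orientation."""
        n, w = self.config.n_windows_per_side, self.config.window_width
        return (np.arange(2 * n) - n) * w


@dataclass
class OccupancyComparison:
    gene_class: str
    mean_a: float
    mean_b: float
    ratio: float
    log2_ratio: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Readers


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad size {parts[1]!r}") from exc
    return sizes


def read_annotations(path) -> list[GeneAnnotation]:
    """Read the gene annotation TSV: gene_id, chrom, tss, strand, gene_class."""
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene_id", "chrom", "tss", "strand", "gene_class"]
        if header != expected:
            raise FormatError(f"{path}: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 fields")
            gene = GeneAnnotation(
                gene_id=parts[0],
                chrom=parts[1],
                tss=int(parts[2]),
                strand=parts[3],
                gene_class=parts[4],
            )
            if gene.gene_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene {gene.gene_id!r}")
            seen.add(gene.gene_id)
            genes.append(gene)
    return genes


# ---------------------------------------------------------------------------
# Coverage


def load_signal(path, bin_width: int, chrom_sizes: dict[str, int]) -> BinnedSignal:
    """Bin per-base read coverage from a BED file of aligned intervals.

    Each read contributes 1x depth over its interval; a bin's value is the
    mean per-base depth over the bases it covers, so reads spanning bin
    boundaries contribute proportionally to their overlap with each bin.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    starts: dict[str, list[int]] = {c: [] for c in chrom_sizes}
    ends: dict[str, list[int]] = {c: [] for c in chrom_sizes}
    n_reads = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if chrom not in chrom_sizes:
                raise ValidationError(f"{path}:{lineno}: unknown chrom {chrom!r}")
            if start < 0 or end <= start:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            if end > chrom_sizes[chrom]:
                raise ValidationError(
                    f"{path}:{lineno}: interval end {end} beyond {chrom!r} "
                    f"size {chrom_sizes[chrom]}"
                )
            starts[chrom].append(start)
            ends[chrom].append(end)
            n_reads += 1
    bins: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        diff = np.zeros(size + 1, dtype=np.float64)
        if starts[chrom]:
            np.add.at(diff, np.asarray(starts[chrom]), 1.0)
            np.add.at(diff, np.asarray(ends[chrom]), -1.0)
        cov = np.cumsum(diff)[:size]
        n_bins = math.ceil(size / bin_width)
        edges = np.arange(0, n_bins * bin_width, bin_width)
        sums = np.add.reduceat(cov, edges)
        widths = np.minimum(edges + bin_width, size) - edges
        bins[chrom] = sums / widths
    return BinnedSignal(
        bins=bins,
        bin_width=bin_width,
        library_size=float(n_reads),
        chrom_sizes=dict(chrom_sizes),
        state="raw",
    )


def normalize_subtract_input(
    chip: BinnedSignal,
    input_: BinnedSignal,
    scale_per_million: bool = True,
    clamp: bool = True,
) -> BinnedSignal:
    """Subtract the input-library signal from the ChIP signal.

    Both tracks are first scaled to reads-per-million (per-base depth times
    1e6 / library size) unless ``scale_per_million`` is off; the per-bin
    difference is clamped at zero by default since occupancy is non-negative.
    """
    if chip.bin_width != input_.bin_width:
        raise GridError(
            f"bin widths differ: {chip.bin_width} vs {input_.bin_width}"
        )
    if chip.chrom_sizes != input_.chrom_sizes:
        raise GridError("chromosome sets/sizes differ between ChIP and input")
    if scale_per_million and (chip.library_size == 0 or input_.library_size == 0):
        raise ValidationError("cannot scale an empty library to reads-per-million")
    bins: dict[str, np.ndarray] = {}
    for chrom in chip.bins:
        c = chip.bins[chrom]
        i = input_.bins[chrom]
        if scale_per_million:
            c = c * (1e6 / chip.library_size)
            i = i * (1e6 / input_.library_size)
        diff = c - i
        if clamp:
            diff = np.maximum(diff, 0.0)
        bins[chrom] = diff
    return BinnedSignal(
        bins=bins,
        bin_width=chip.bin_width,
        library_size=chip.library_size,
        chrom_sizes=dict(chip.chrom_sizes),
        state="input_subtracted",
    )


# ---------------------------------------------------------------------------
# Aggregation


def _gene_window_means(
    signal: BinnedSignal, gene: GeneAnnotation, config: ProfileConfig
) -> np.ndarray:
    """Per-window mean per-base signal for one gene (NaN if fully out of bounds)."""
    n, w = config.n_windows_per_side, config.window_width
    size = signal.chrom_sizes[gene.chrom]
    positions = gene.tss + np.arange(-n * w, n * w)
    in_bounds = (positions >= 0) & (positions < size)
    vals = np.full(positions.shape, np.nan)
    vals[in_bounds] = signal.value_at(gene.chrom, positions[in_bounds])
    grid = vals.reshape(2 * n, w)
    n_valid = np.sum(~np.isnan(grid), axis=1)
    sums = np.nansum(grid, axis=1)
    per_window = np.where(n_valid > 0, sums / np.maximum(n_valid, 1), np.nan)
    if gene.strand == "-":
        per_window = per_window[::-1]
    return per_window


def aggregate_profile(
    signal: BinnedSignal,
    annotations: list[GeneAnnotation],
    gene_class: str,
    config: ProfileConfig = ProfileConfig(),
) -> AggregateProfile:
    """Unweighted mean TSS-anchored profile over all genes of a class.

    Windows run from TSS - n*w to TSS + n*w; per-window value is the mean
    per-base signal over the window's in-bounds bases, and the profile is
    the per-window mean across genes (each gene counting equally).
    """
    genes = [g for g in annotations if g.gene_class == gene_class]
    if not genes:
        raise EmptyClassError(f"no genes of class {gene_class!r}")
    stack = np.vstack([_gene_window_means(signal, g, config) for g in genes])
    n_valid = np.sum(~np.isnan(stack), axis=0)
    values = np.where(
        n_valid > 0, np.nansum(stack, axis=0) / np.maximum(n_valid, 1), np.nan
    )
    return AggregateProfile(
        gene_class=gene_class, values=values, n_genes=len(genes), config=config
    )


def compare_occupancy(
    profile_a: AggregateProfile, profile_b: AggregateProfile
) -> OccupancyComparison:
    """Mean-occupancy ratio b/a between two profiles of the same class."""
    if profile_a.gene_class != profile_b.gene_class:
        raise ComparisonError(
            f"class mismatch: {profile_a.gene_class!r} vs {profile_b.gene_class!r}"
        )
    if profile_a.config != profile_b.config:
        raise ComparisonError("profiles built with different window layouts")
    mean_a = float(np.nanmean(profile_a.values))
    mean_b = float(np.nanmean(profile_b.values))
    if mean_a == 0.0:
        return OccupancyComparison(
            gene_class=profile_a.gene_class,
            mean_a=mean_a,
            mean_b=mean_b,
            ratio=math.nan,
            log2_ratio=math.nan,
            degenerate=True,
        )
    ratio = mean_b / mean_a
    log2 = math.log2(ratio) if ratio > 0 else -math.inf
    return OccupancyComparison(
        gene_class=profile_a.gene_class,
        mean_a=mean_a,
        mean_b=mean_b,
        ratio=ratio,
        log2_ratio=log2,
    )
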