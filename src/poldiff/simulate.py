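"""Synthetic AP-MS count tables and ChIP read sets.

The generator emulates the statistical structure the analyses assume, not the
raw instruments: spectral counts come out as Poisson draws around a
lognormal-perturbed per-protein abundance (the simplest over-dispersed count
model, with the replicate coefficient of variation as the single noise knob),
and ChIP libraries are background reads scattered uniformly over a scaled-down
genome plus TSS-centred enriched reads per gene, each library sampled to the
same fixed total read count the way a sequencer delivers a target depth.

Two AP-MS scenarios ship as module constants: ``LEUKODYSTROPHY`` (the mutant
bait loses three quarters of its polymerase-III-specific partners, everything
else unchanged) and ``TCS`` (all interactions intact — the null scenario).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chip import GENE_CLASSES, GeneAnnotation
from .errors import ModelError, PlacementError, ValidationError
from .io import RAW, RunDesign, SpectralCountTable

__all__ = [
    "ComplexModel",
    "Scenario",
    "LEUKODYSTROPHY",
    "TCS",
    "simulate_apms_dataset",
    "ChipOccupancySpec",
    "ChipGenomeSpec",
    "ChipReadSpec",
    "ChipDataset",
    "simulate_chip_dataset",
]

# ---------------------------------------------------------------------------
# AP-MS


@dataclass(frozen=True)
class ComplexModel:
    """Subunit composition and abundances of the two-polymerase bait model.

    The bait is a subunit shared between polymerase I and polymerase III, so
    a pull-down captures three protein categories — polymerase-I-specific,
    shared, polymerase-III-specific — plus nonspecific background binders
    that also appear in the empty-vector control.  ``subunit_abundance`` is
    the expected raw spectral count of a complex subunit in a wild-type
    pull-down; per-protein overrides go in ``abundance_overrides``.
    """

    pol1_specific: tuple[str, ...] = (
        "POLR1A", "POLR1B", "POLR1E", "CD3EAP", "TWISTNB", "ZNRD1",
    )
    shared: tuple[str, ...] = (
        "POLR2E", "POLR2F", "POLR2H", "POLR2K", "POLR2L", "POLR1C", "POLR1D",
    )
    pol3_specific: tuple[str, ...] = (
        "POLR3A", "POLR3B", "POLR3C", "POLR3D", "POLR3E",
        "POLR3F", "POLR3G", "POLR3GL", "POLR3H", "POLR3K",
    )
    bait_id: str = "POLR1C"
    n_background: int = 150
    subunit_abundance: float = 60.0
    bait_abundance: float = 200.0
    #: lognormal parameters of background-protein abundances (natural log).
    background_log_mean: float = math.log(6.0)
    background_log_sigma: float = 1.0
    abundance_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cats = [set(self.pol1_specific), set(self.shared), set(self.pol3_specific)]
        if sum(len(c) for c in cats) != len(set().union(*cats)):
            raise ModelError("subunit categories must be disjoint")
        if self.bait_id not in self.shared:
            raise ModelError("bait must belong to the shared category")
        if self.subunit_abundance <= 0 or self.bait_abundance <= 0:
            raise ModelError("abundances must be positive")
        if any(v <= 0 for v in self.abundance_overrides.values()):
            raise ModelError("abundances must be positive")

    @property
    def subunits(self) -> tuple[str, ...]:
        return self.pol1_specific + self.shared + self.pol3_specific

    def category_of(self, protein: str) -> str:
        if protein in self.pol1_specific:
            return "pol1_specific"
        if protein in self.shared:
            return "shared"
        if protein in self.pol3_specific:
            return "pol3_specific"
        return "background"

    def abundance_of(self, protein: str) -> float:
        if protein in self.abundance_overrides:
            return self.abundance_overrides[protein]
        if protein == self.bait_id:
            return self.bait_abundance
        return self.subunit_abundance


@dataclass(frozen=True)
class Scenario:
    """Per-category MUT-vs-WT fold effects plus replicate noise.

    ``cv`` is the lognormal coefficient of variation of the multiplicative
    replicate factor; ``dropout`` is the probability that a protein with
    expected count below ``dropout_threshold`` yields a zero in a run
    (search-engine missingness at the noise floor).
    """

    name: str
    variant: str
    fold_pol3: float = 1.0
    fold_pol1: float = 1.0
    fold_shared: float = 1.0
    cv: float = 0.10
    dropout: float = 0.30
    dropout_threshold: float = 5.0

    def __post_init__(self) -> None:
        if min(self.fold_pol3, self.fold_pol1, self.fold_shared) <= 0:
            raise ValidationError("fold effects must be positive")
        if not 0 <= self.dropout < 1:
            raise ValidationError("dropout must be in [0, 1)")
        if self.cv < 0:
            raise ValidationError("cv must be non-negative")

    def fold_for(self, category: str) -> float:
        return {
            "pol3_specific": self.fold_pol3,
            "pol1_specific": self.fold_pol1,
            "shared": self.fold_shared,
            "background": 1.0,
        }[category]


#: The mutant bait assembles into polymerase I but not polymerase III.
LEUKODYSTROPHY = Scenario("leukodystrophy", variant="N32I", fold_pol3=0.25)
#: The mutant bait assembles into both polymerases (null scenario).
TCS = Scenario("tcs", variant="R279Q")


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative replicate noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_apms_dataset(
    model: ComplexModel,
    scenario: Scenario,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[SpectralCountTable, RunDesign]:
    """Simulate paired WT / MUT / EV purification runs.

    Counts per protein and run are Poisson with mean = base abundance x
    category fold (MUT runs only; the bait itself is never fold-affected) x
    a lognormal replicate factor.  EV runs contain only background proteins.
    Zero counts are simply absent from the long table.  Deterministic given
    ``seed``.
    """
    if n_replicates < 2:
        raise ValidationError("n_replicates must be >= 2")
    for cat, fold in (
        ("pol1_specific", scenario.fold_pol1),
        ("shared", scenario.fold_shared),
        ("pol3_specific", scenario.fold_pol3),
    ):
        if fold != 1.0 and not getattr(model, cat):
            raise ModelError(f"fold effect requested for empty category {cat!r}")
    rng = np.random.default_rng(seed)
    background = tuple(f"BG{i:04d}" for i in range(1, model.n_background + 1))
    bg_abundance = dict(
        zip(
            background,
            rng.lognormal(
                model.background_log_mean,
                model.background_log_sigma,
                size=len(background),
            ),
        )
    )
    proteins = list(model.subunits) + list(background)
    base = np.array(
        [
            bg_abundance[p] if p in bg_abundance else model.abundance_of(p)
            for p in proteins
        ]
    )
    categories = np.array([model.category_of(p) for p in proteins])
    is_background = categories == "background"

    runs: list[tuple[str, str, int, str]] = []
    for k in range(1, n_replicates + 1):
        runs.append((f"WT_{k}", "WT", k, f"p{k}"))
    for k in range(1, n_replicates + 1):
        runs.append((f"{scenario.variant}_{k}", f"MUT:{scenario.variant}", k, f"p{k}"))
    for k in range(1, n_replicates + 1):
        runs.append((f"EV_{k}", "EV", k, ""))

    rows = []
    for run_id, condition, _, _ in runs:
        if condition == "EV":
            mean = np.where(is_background, base, 0.0)
        elif condition.startswith("MUT:"):
            fold = np.array([scenario.fold_for(c) for c in categories])
            fold[np.array(proteins) == model.bait_id] = 1.0
            mean = base * fold
        else:
            mean = base
        noisy = mean * _lognormal_factor(rng, scenario.cv, len(proteins))
        counts = rng.poisson(noisy)
        low = (mean > 0) & (mean < scenario.dropout_threshold)
        dropped = low & (rng.random(len(proteins)) < scenario.dropout)
        counts = np.where(dropped, 0, counts)
        for p, c in zip(proteins, counts):
            if c > 0:
                rows.append((p, run_id, int(c)))

    table = SpectralCountTable(
        data=pd.DataFrame(rows, columns=["protein_id", "run_id", "count"]), kind=RAW
    )
    design = RunDesign(
        data=pd.DataFrame(
            runs, columns=["run_id", "condition", "replicate_index", "pair_id"]
        )
    )
    return table, design


# ---------------------------------------------------------------------------
# ChIP


@dataclass(frozen=True)
class ChipOccupancySpec:
    """Expected enriched reads per gene (WT) and the MUT fold per class.

    rDNA keeps fold 1.0 in the default mutant scenario: the mutation spares
    the polymerase-I enzyme, so its occupancy over the ribosomal repeat is
    unchanged while all three polymerase-III classes lose binding.
    """

    wt_depth: dict[str, float] = field(
        default_factory=lambda: {
            "type1": 1500.0, "type2": 1500.0, "type3": 1500.0, "rDNA": 8000.0,
        }
    )
    mut_fold: dict[str, float] = field(
        default_factory=lambda: {
            "type1": 0.4, "type2": 0.4, "type3": 0.4, "rDNA": 1.0,
        }
    )

    def __post_init__(self) -> None:
        for cls in self.wt_depth:
            if cls not in GENE_CLASSES:
                raise ValidationError(f"unknown gene class {cls!r}")
        if any(v <= 0 for v in self.wt_depth.values()):
            raise ValidationError("depths must be positive")
        if any(v <= 0 for v in self.mut_fold.values()):
            raise ValidationError("folds must be positive")


@dataclass(frozen=True)
class ChipGenomeSpec:
    """A scaled-down genome: one gene-bearing chromosome + a dedicated rDNA
    contig (mirroring alignment of reads directly to the ribosomal repeat)."""

    n_genes: dict[str, int] = field(
        default_factory=lambda: {"type1": 15, "type2": 40, "type3": 10}
    )
    chrom: str = "chrS"
    chrom_length: int = 1_000_000
    rdna_contig: str = "rDNA"
    rdna_length: int = 45_000
    rdna_tss: int = 20_000
    flank: int = 2_000
    margin: int = 5_000

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_genes.values()):
            raise ValidationError("need >= 1 gene per requested class")
        if "rDNA" in self.n_genes:
            raise ValidationError("rDNA lives on its own contig, not in n_genes")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {self.chrom: self.chrom_length, self.rdna_contig: self.rdna_length}


@dataclass(frozen=True)
class ChipReadSpec:
    read_length: int = 50
    reads_per_library: int = 150_000
    peak_sd: float = 120.0

    def __post_init__(self) -> None:
        if self.read_length <= 0 or self.reads_per_library <= 0:
            raise ValidationError("read spec values must be positive")


@dataclass
class ChipDataset:
    chip_wt: Path
    chip_mut: Path
    input: Path
    annotations_path: Path
    chrom_sizes_path: Path
    annotations: list[GeneAnnotation]
    chrom_sizes: dict[str, int]


def _place_genes(
    genome: ChipGenomeSpec, reads: ChipReadSpec, rng: np.random.Generator
) -> list[GeneAnnotation]:
    total = sum(genome.n_genes.values())
    usable = genome.chrom_length - 2 * genome.margin
    step = usable // total if total else 0
    min_step = 2 * genome.flank + reads.read_length
    if step < min_step:
        raise PlacementError(
            f"cannot place {total} non-overlapping genes with {genome.flank} bp "
            f"flanks on a {genome.chrom_length} bp chromosome"
        )
    labels = [c for c, n in sorted(genome.n_genes.items()) for _ in range(n)]
    labels = list(rng.permutation(labels))
    jitter_max = max(1, step - min_step)
    genes: list[GeneAnnotation] = []
    for i, cls in enumerate(labels):
        tss = genome.margin + i * step + int(rng.integers(0, jitter_max))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneAnnotation(
                gene_id=f"{cls}_g{i:03d}",
                chrom=genome.chrom,
                tss=tss,
                strand=strand,
                gene_class=cls,
            )
        )
    genes.append(
        GeneAnnotation(
            gene_id="rDNA_unit",
            chrom=genome.rdna_contig,
            tss=genome.rdna_tss,
            strand="+",
            gene_class="rDNA",
        )
    )
    return genes


def _library_reads(
    genes: list[GeneAnnotation],
    occupancy: ChipOccupancySpec,
    genome: ChipGenomeSpec,
    reads: ChipReadSpec,
    condition: str,  # "wt" | "mut" | "input"
    rng: np.random.Generator,
) -> pd.DataFrame:
    rl = reads.read_length
    sizes = genome.chrom_sizes
    chroms: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    n_enriched = 0
    if condition != "input":
        for gene in genes:
            depth = occupancy.wt_depth[gene.gene_class]
            if condition == "mut":
                depth *= occupancy.mut_fold[gene.gene_class]
            n_g = int(rng.poisson(depth))
            n_enriched += n_g
            centers = gene.tss + rng.normal(0.0, reads.peak_sd, size=n_g)
            s = np.rint(centers - rl / 2).astype(np.int64)
            s = np.clip(s, 0, sizes[gene.chrom] - rl)
            chroms.append(np.full(n_g, gene.chrom, dtype=object))
            starts.append(s)
    n_bg = reads.reads_per_library - n_enriched
    if n_bg < 0:
        raise ValidationError(
            "enrichment exceeds reads_per_library; increase the library size"
        )
    names = sorted(sizes)
    lengths = np.array([sizes[c] for c in names], dtype=float)
    alloc = rng.multinomial(n_bg, lengths / lengths.sum())
    for name, n_c in zip(names, alloc):
        s = rng.integers(0, sizes[name] - rl, size=n_c)
        chroms.append(np.full(n_c, name, dtype=object))
        starts.append(s.astype(np.int64))
    chrom_col = np.concatenate(chroms) if chroms else np.array([], dtype=object)
    start_col = (
        np.concatenate(starts) if starts else np.array([], dtype=np.int64)
    )
    n = len(start_col)
    strand_col = np.where(rng.random(n) < 0.5, "+", "-")
    return pd.DataFrame(
        {
            "chrom": chrom_col,
            "start": start_col,
            "end": start_col + rl,
            "name": [f"{condition}_read{i}" for i in range(n)],
            "score": 0,
            "strand": strand_col,
        }
    )


def simulate_chip_dataset(
    occupancy: ChipOccupancySpec,
    genome: ChipGenomeSpec,
    reads: ChipReadSpec,
    seed: int,
    out_dir,
) -> ChipDataset:
    """Write BED read sets (chip WT / chip MUT / input), the annotation TSV
    and the chromosome-sizes TSV for one simulated experiment.

    Each library holds exactly ``reads_per_library`` reads: enriched reads
    (Poisson per gene around the class depth, centres normal around the TSS)
    plus uniform background filling the remainder; the input library is
    background only.  Deterministic given ``seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    genes = _place_genes(genome, reads, rng)

    paths = {}
    for condition in ("wt", "mut", "input"):
        df = _library_reads(genes, occupancy, genome, reads, condition, rng)
        name = "input.bed" if condition == "input" else f"chip_{condition}.bed"
        path = out_dir / name
        df.to_csv(path, sep="\t", header=False, index=False)
        paths[condition] = path

    ann_path = out_dir / "annotations.tsv"
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss, g.strand, g.gene_class) for g in genes],
        columns=["gene_id", "chrom", "tss", "strand", "gene_class"],
    ).to_csv(ann_path, sep="\t", index=False)
    sizes_path = out_dir / "chrom_sizes.tsv"
    with open(sizes_path, "w") as fh:
        for chrom, size in genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    return ChipDataset(
        chip_wt=paths["wt"],
        chip_mut=paths["mut"],
        input=paths["input"],
        annotations_path=ann_path,
        chrom_sizes_path=sizes_path,
        annotations=genes,
        chrom_sizes=genome.chrom_sizes,
    )
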