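"""TSS-anchored occupancy comparison between wild-type and mutant ChIP.

Simulates ChIP read sets in which the mutant polymerase subunit binds
polymerase-III target genes at 40% of the wild-type level while the
polymerase-I rDNA control is untouched, then recovers exactly that pattern:
log2 MUT/WT occupancy near log2(0.4) = -1.32 for the three promoter classes
and near 0 at rDNA.
"""

import tempfile
from pathlib import Path

from poldiff.chip import (
    aggregate_profile,
    compare_occupancy,
    load_signal,
    normalize_subtract_input,
    read_chrom_sizes,
)
from poldiff.simulate import (
    ChipGenomeSpec,
    ChipOccupancySpec,
    ChipReadSpec,
    simulate_chip_dataset,
)

with tempfile.TemporaryDirectory() as tmp:
    ds = simulate_chip_dataset(
        ChipOccupancySpec(), ChipGenomeSpec(), ChipReadSpec(),
        seed=7, out_dir=Path(tmp),
    )
    sizes = read_chrom_sizes(ds.chrom_sizes_path)
    inp = load_signal(ds.input, bin_width=10, chrom_sizes=sizes)
    wt = normalize_subtract_input(load_signal(ds.chip_wt, 10, sizes), inp)
    mut = normalize_subtract_input(load_signal(ds.chip_mut, 10, sizes), inp)

    print(f"{'class':6s} {'genes':>5s} {'mean WT':>8s} {'mean MUT':>9s} {'log2 MUT/WT':>12s}")
    for cls in ("type1", "type2", "type3", "rDNA"):
        prof_wt = aggregate_profile(wt, ds.annotations, cls)
        prof_mut = aggregate_profile(mut, ds.annotations, cls)
        comp = compare_occupancy(prof_wt, prof_mut)
        print(
            f"{cls:6s} {prof_wt.n_genes:5d} {comp.mean_a:8.1f} "
            f"{comp.mean_b:9.1f} {comp.log2_ratio:12.3f}"
        )
print(
    "\nmeans are input-subtracted reads-per-million over 100 windows of 10 bp"
    "\non each side of the TSS; rDNA near 0 shows the dissociation: only the"
    "\npolymerase-III classes lose occupancy."
)
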