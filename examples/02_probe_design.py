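"""Select array SNPs from a read pileup and design Tm-optimized probes.

One best SNP per 2-Kb window (unique-mapping, quality >= 25, highest
minor-allele depth); four probes per SNP (2 alleles x 2 strands) with length
20-35 nt chosen to bring the SantaLucia nearest-neighbor melting temperature
closest to the 80 degC target.
"""
from arraymap import (SimConfig, ThermoParams, annotate_snp_context,
                      design_probes, select_window_snps, simulate_design_world)

world = simulate_design_world(SimConfig(seed=4))
selected = select_window_snps(world.pileup, window_bp=2000, min_qual=25)
print(f"pileup: {len(world.pileup)} candidate SNPs -> "
      f"{len(selected)} selected (one per 2-Kb window)")

contexts = annotate_snp_context(selected, world.annotation_gff3)
for label in ("CDS", "mRNA", "intergenic"):
    print(f"  {label}: {contexts.count(label)} SNPs")

row = selected.iloc[0]
seq = world.reference[row["chrom"]]
center = int(row["pos"]) - 1
flank = seq[center - 18:center + 19]
design = design_probes(row, flank, ThermoParams(), target_tm=80.0)
print(f"probes for {design.snp_id} (alleles {design.alleles[0]}/"
      f"{design.alleles[1]}):")
for p in design.probes:
    print(f"  allele {p.allele} {p.strand}: {p.length} nt, "
          f"Tm {p.tm:.2f} degC")
# the four Tm values cluster near the target; fwd/rev pairs are reverse
# complements and melt identically
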