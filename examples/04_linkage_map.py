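"""Filter called genotypes and build a binned linkage map.

Dedup redundant markers (Bhattacharyya-best representative), drop low-
confidence and segregation-distorted markers and bad samples, then group
(independence test, p < 1e-10), order (adjacent-recombination minimization)
and bin cosegregating markers with Haldane cM positions.
"""
from arraymap import (FilterReport, SimConfig, build_map, filter_segregation,
                      sample_qc, segregation_model, simulate_ril_population)
from arraymap.filtering import dedup_redundant
import pandas as pd

cfg = SimConfig(n_chromosomes=3, chrom_length_cm=(90.0, 80.0, 70.0),
                chrom_length_mb=(25.0, 22.0, 18.0), n_markers=(150, 120, 100),
                n_rils=120, seed=3)
calls, truth = simulate_ril_population(cfg)

report = FilterReport()
sep = pd.Series(1.0, index=calls.index)  # cluster separations (flat here)
filtered = dedup_redundant(calls, sep, report)
filtered = filter_segregation(filtered, segregation_model(7), report=report)
filtered = sample_qc(filtered, report=report)
print(f"{len(calls)} markers -> {len(filtered)} after filtering "
      f"({report.markers_redundant} redundant, "
      f"{report.markers_distorted} distorted)")

lmap = build_map(filtered, dedup_groups=report.dedup_groups)
print(f"linkage groups: {len(lmap.linkage_groups)} "
      f"(true chromosomes: {cfg.n_chromosomes})")
for lg in lmap.linkage_groups:
    sub = lmap.table[lmap.table["linkage_group"] == lg]
    chrom = truth.markers.loc[sub.index, "chrom"].mode().iloc[0]
    print(f"  LG{lg}: {len(sub)} markers in {sub['bin_index'].nunique()} bins, "
          f"{lmap.group_length(lg):.1f} cM  (true: {chrom})")
print(f"total map length: {lmap.total_length():.1f} cM "
      f"(simulated: {sum(cfg.chrom_length_cm):.1f} cM)")
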