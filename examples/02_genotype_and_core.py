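"""Genotype marker haplotypes and select the core marker set.

Slices each strain's consensus genome at the panel coordinates, knocks out
random cells to emulate amplification dropout, and keeps as "core" the
markers detected in 100% of strains — the loci genetic similarity is
computed over.
"""

import tempfile

from mnpkit import (SimConfig, simulate_cohort, read_vcf_genotypes,
                    extract_haplotypes, select_core)
from mnpkit.marker_screen import scan_windows, select_panel
from mnpkit.simulate import designate_exempt_markers, simulate_dropout

cfg = SimConfig(seed=42, genome_length=60_000, n_pedigrees=3,
                strains_per_pedigree=3, n_wild=3)
cohort = simulate_cohort(cfg)
with tempfile.TemporaryDirectory() as tmp:
    matrix, _ = read_vcf_genotypes(cohort.write(tmp)["vcf"])
panel = select_panel(scan_windows(matrix, cfg.genome_length))

table = extract_haplotypes(cohort.consensus, panel)
exempt = designate_exempt_markers(panel, fraction=0.4)
table = simulate_dropout(table, cfg.marker_dropout_prob, exempt, seed=cfg.seed)

counts = table.detected_per_sample()
print(f"genotyped {len(table.samples)} strains x {len(table.markers)} markers")
print(f"markers detected per strain: {counts.min()}-{counts.max()} "
      f"(mean {counts.mean():.1f})")

core = select_core(table)
print(f"core markers (detected in all strains): {core.m} of {len(panel)}")
print("a haplotype:", table.data.iloc[0, 0][:40] + "...")
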