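# mnpkit

A toolkit for DNA-fingerprint identification of mushroom cultivars with
**MNP (multiple nucleotide polymorphism) markers** — short genomic windows
containing several SNPs whose joint haplotype acts as a multi-allelic
fingerprint locus. It was built around the identification problem for the
enoki mushroom (*Flammulina filiformis*), where commercially propagated
cultivars are nearly clonal, names are inconsistent, and traditional
morphological or single-marker methods cannot reliably tell cultivars
apart.

The toolkit covers the full dry-lab side of the workflow:

1. **Marker screening** — slide a 130-bp window in 10-bp steps across a
   multi-sample SNP matrix and score each window's *discriminative power*

   `DP = t / C(N, 2)`

   where `N` is the number of strains and `t` the number of unordered
   strain pairs the window distinguishes (a pair counts only when it
   differs at ≥ 2 dispersed SNPs inside the window, both strains called at
   both sites). Windows with `DP > 0.4` become panel candidates; a greedy
   highest-DP pass keeps a non-overlapping marker panel.
2. **Haplotype genotyping** — slice each strain's consensus genome at panel
   coordinates; a marker is *detected* when the slice is unambiguous and
   covered deeply enough. **Core markers** are those detected in 100% of
   strains.
3. **Genetic similarity** — `GS = (#core markers with identical haplotypes) / M`
   for each strain pair; classify with the thresholds
   `GS ≤ 0.60` → different pedigrees, `0.60 < GS ≤ 0.986` → different
   cultivars in the same pedigree, `GS > 0.986` → same cultivar. Pedigrees
   are the single-linkage closure of `GS > 0.60`.
4. **Phylogeny** — Saitou–Nei neighbor joining on core-haplotype distances,
   Newick output plus per-leaf annotations (pedigree, cap color, source).
5. **Simulation** — a seeded cohort generator (pedigreed near-clonal
   cultivars, divergent wild strains, planted same-genome duplicates,
   marker dropout, duplicate two-platform genotyping) so every stage runs
   and is tested at desk scale without any external data.

It also ships transcriptions of the published cohort-metadata tables
(163 whole-genome-sequenced strains; 69 strains assayed with the targeted
marker panel) and reproduces their printed summary statistics.

## Worked example

`examples/` holds one short script per capability. The whole pipeline in
one call (`examples/06_full_pipeline.py`):

```python
from mnpkit import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(out_dir="mnp_run", seed=1))
```

prints, for the default simulated cohort (3 pedigrees × 4 cultivars,
5 wild strains, 1 planted duplicate, 200-kb genome):

```
stage counts: {
  "snp_sites": 16631,
  "vcf_records_skipped": 439,
  "windows_scanned": 19988,
  "markers_selected": 1077,
  "core_markers": 684,
  "samples": 18,
  "pedigrees": 8
}
planted pedigree partition recovered: True
GS of planted identical-genotype pairs: {'P1C1|P1C1dup1': 1.0}
```

Reading the numbers: 16,631 biallelic SNP sites were ingested from the
cohort VCF (439 multiallelic records skipped), 19,988 sliding windows were
scored, 1,077 passed `DP > 0.4` without overlap, and 684 of them were
detected in every strain after simulated dropout. Thresholding the GS
matrix at 60% recovers exactly the 8 planted groups (3 cultivar pedigrees
plus 5 mutually distant wild strains), and the planted same-genome pair
`P1C1`/`P1C1dup1` comes out at GS = 1.0 — the fingerprint signature of one
cultivar circulating under two names. The run directory contains
`panel.bed`, `genotypes.tsv`, `core.txt`, `gs.csv`, `verdicts.tsv`,
`pedigrees.tsv`, `tree.nwk`, `ann.tsv` and `report.json`; re-running with
the same config and seed is bit-identical.

The same stages are available as a CLI:

```bash
mnpkit simulate --seed 1 --out-dir cohort/
mnpkit screen --vcf cohort/cohort.vcf --ref cohort/reference.fasta --out panel.bed
mnpkit genotype --panel panel.bed --consensus-dir cohort/consensus --out genotypes.tsv
mnpkit core --genotypes genotypes.tsv --out core.txt
mnpkit identify --genotypes genotypes.tsv --core core.txt
mnpkit tree --genotypes genotypes.tsv --core core.txt --out tree.nwk
mnpkit paper-tables
```

`mnpkit paper-tables` summarizes the bundled metadata tables: mean depth
133.0×, mean genome coverage 90.5%, mean read-mapping rate 85.8% over the
163 unique whole-genome strains; mean marker coverage 21,951× over the 69
targeted-assay strains; 232 strains in total (157 cultivars, 75 wild).

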