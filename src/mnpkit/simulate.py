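"""Synthetic cultivar-cohort generator with truth labels.

Emulates the cohort structure the MNP pipeline assumes: tight pedigrees of
cultivars descended from a common founder, genetically diverse wild strains,
optional same-genome/different-name cultivar duplicates, marker dropout,
and duplicate genotyping of one cohort on two platforms. Evolution is
substitution-only (no indels), so coordinates are shared across samples and
consensus genomes stay length-aligned with the reference — matching the
SNP-centric marker model. Mutations are i.i.d. uniform over positions
(sampled without replacement) and over the three alternate bases.

All randomness flows from ``SimConfig.seed``; identical configs produce
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotyping import MISSING, GenotypeTable, extract_haplotypes
from .marker_screen import MarkerPanel

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort; defaults give the pipeline's reference
    separation regime (within-pedigree GS well above 0.60, between well
    below) with wide margins.

    Rates are substitutions per bp: within-pedigree divergence is tight
    (cultivars are near-clonal selections from a founder), between-pedigree
    divergence an order of magnitude larger, and wild strains larger still
    (wild populations carry the species' diversity).
    """

    seed: int = 0
    genome_length: int = 200_000
    contig: str = "chr1"
    n_pedigrees: int = 3
    strains_per_pedigree: int = 4
    n_wild: int = 5
    snp_rate_between_pedigrees: float = 8e-3
    snp_rate_within_pedigree: float = 5e-4
    wild_rate: float = 1.2e-2
    n_clone_pairs: int = 1  # planted identical-genotype pairs (same genome, new name)
    marker_dropout_prob: float = 0.05
    core_dropout_exempt: bool = True
    depth_mean: float = 100.0

    def __post_init__(self) -> None:
        for name in ("snp_rate_between_pedigrees", "snp_rate_within_pedigree", "wild_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"{name}={rate} outside [0, 1)")
            if rate * self.genome_length > self.genome_length:
                raise ValueError(f"{name} implies more substitutions than genome positions")
        if not (0.0 <= self.marker_dropout_prob < 1.0):
            raise ValueError("marker_dropout_prob must be in [0, 1)")
        if min(self.n_pedigrees, self.strains_per_pedigree, self.n_wild,
               self.n_clone_pairs, self.genome_length) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class TruthSet:
    """Planted labels: pedigree and source per sample, plus identical pairs."""

    pedigree: dict[str, str]
    source: dict[str, str]  # "cultivar" | "wild"
    identical_pairs: list[tuple[str, str]]

    def partition(self) -> set[frozenset[str]]:
        groups: dict[str, set[str]] = {}
        for sample, label in self.pedigree.items():
            groups.setdefault(label, set()).add(sample)
        return {frozenset(g) for g in groups.values()}


@dataclass
class Cohort:
    """A simulated cohort: reference, per-sample consensus genomes, truth."""

    config: SimConfig
    reference: dict[str, str]
    consensus: dict[str, dict[str, str]]  # sample -> contig -> sequence
    truth: TruthSet

    @property
    def samples(self) -> list[str]:
        return list(self.consensus)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write reference.fasta, consensus/*.fasta, cohort.vcf and truth.tsv."""
        from .io_formats import write_fasta

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"reference": out / "reference.fasta", "vcf": out / "cohort.vcf",
                 "truth": out / "truth.tsv", "consensus_dir": out / "consensus"}
        write_fasta(self.reference, paths["reference"])
        paths["consensus_dir"].mkdir(exist_ok=True)
        for sample, genome in self.consensus.items():
            write_fasta(genome, paths["consensus_dir"] / f"{sample}.fasta")
        write_cohort_vcf(self, paths["vcf"])
        with open(paths["truth"], "w") as fh:
            fh.write("sample\tpedigree\tsource\n")
            for sample in self.samples:
                fh.write(f"{sample}\t{self.truth.pedigree[sample]}\t{self.truth.source[sample]}\n")
        return paths


def _random_genome(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, genome: np.ndarray, rate: float) -> np.ndarray:
    """Substitute a Binomial(L, rate) set of positions, sampled without
    replacement, each to a uniform choice of the three other bases."""
    length = len(genome)
    n_subs = rng.binomial(length, rate)
    out = genome.copy()
    if n_subs == 0:
        return out
    positions = rng.choice(length, size=n_subs, replace=False)
    # shift by 1..3 in base index: always lands on a different base
    base_idx = np.searchsorted(_BASES, out[positions])
    out[positions] = _BASES[(base_idx + rng.integers(1, 4, size=n_subs)) % 4]
    return out


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate the cohort: founder per pedigree, cultivars around founders,
    independent wild strains, and planted identical-genotype clones."""
    rng = np.random.default_rng(cfg.seed)
    ancestor = _random_genome(rng, cfg.genome_length)

    consensus: dict[str, dict[str, str]] = {}
    pedigree: dict[str, str] = {}
    source: dict[str, str] = {}

    clone_sources: list[str] = []
    for p in range(1, cfg.n_pedigrees + 1):
        founder = _mutate(rng, ancestor, cfg.snp_rate_between_pedigrees)
        for c in range(1, cfg.strains_per_pedigree + 1):
            name = f"P{p}C{c}"
            genome = _mutate(rng, founder, cfg.snp_rate_within_pedigree)
            consensus[name] = {cfg.contig: genome.tobytes().decode()}
            pedigree[name] = f"P{p}"
            source[name] = "cultivar"
            clone_sources.append(name)
    for w in range(1, cfg.n_wild + 1):
        name = f"W{w}"
        genome = _mutate(rng, ancestor, cfg.wild_rate)
        consensus[name] = {cfg.contig: genome.tobytes().decode()}
        pedigree[name] = f"WILD{w}"
        source[name] = "wild"

    identical_pairs: list[tuple[str, str]] = []
    for k in range(cfg.n_clone_pairs):
        if not clone_sources:
            break
        orig = clone_sources[k % len(clone_sources)]
        name = f"{orig}dup{k + 1}"
        consensus[name] = dict(consensus[orig])  # same genome, distinct name
        pedigree[name] = pedigree[orig]
        source[name] = "cultivar"
        identical_pairs.append((orig, name))

    reference = {cfg.contig: ancestor.tobytes().decode()}
    return Cohort(
        config=cfg,
        reference=reference,
        consensus=consensus,
        truth=TruthSet(pedigree=pedigree, source=source, identical_pairs=identical_pairs),
    )


def cohort_variant_sites(cohort: Cohort) -> list[tuple[int, str, list[str], list[int]]]:
    """Sites polymorphic across the cohort.

    Returns (0-based position, ref base, alt bases, per-sample allele index
    with 0 = ref) for every position where at least one sample differs from
    the reference, in coordinate order.
    """
    contig = cohort.config.contig
    ref = np.frombuffer(cohort.reference[contig].encode(), dtype="S1")
    samples = cohort.samples
    mat = np.vstack([
        np.frombuffer(cohort.consensus[s][contig].encode(), dtype="S1") for s in samples
    ])
    poly = np.nonzero((mat != ref[None, :]).any(axis=0))[0]
    sites = []
    for pos in poly:
        ref_base = ref[pos].decode()
        col = mat[:, pos]
        alts = sorted({b.decode() for b in col} - {ref_base})
        allele_of = {ref_base: 0, **{a: i + 1 for i, a in enumerate(alts)}}
        sites.append((int(pos), ref_base, alts, [allele_of[b.decode()] for b in col]))
    return sites


def write_cohort_vcf(cohort: Cohort, path: str | Path) -> None:
    """Write every cohort-polymorphic site as a (possibly multiallelic)
    haploid-genotype VCF record."""
    import pysam

    cfg = cohort.config
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={cfg.contig},length={cfg.genome_length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    samples = cohort.samples
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for pos, ref_base, alts, alleles in cohort_variant_sites(cohort):
            rec = vcf.new_record(
                contig=cfg.contig, start=pos, stop=pos + 1,
                alleles=[ref_base, *alts],
            )
            for s, a in zip(samples, alleles):
                rec.samples[s]["GT"] = (a,)
            vcf.write(rec)


def designate_exempt_markers(panel: MarkerPanel, fraction: float = 0.4) -> list[str]:
    """Deterministic dropout-exempt subset: every marker whose rank in the
    panel order falls in the first ``fraction`` (these model loci whose
    primers amplify robustly in every strain)."""
    n_exempt = int(round(fraction * len(panel.markers)))
    return [m.marker_id for m in panel.markers[:n_exempt]]


def simulate_dropout(
    table: GenotypeTable,
    dropout_prob: float,
    exempt_markers: Sequence[str] = (),
    seed: int | np.random.Generator = 0,
) -> GenotypeTable:
    """Independently knock out non-exempt cells with the given probability,
    modelling per-strain amplification failure of individual markers."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = table.data.copy()
    exempt = set(exempt_markers)
    targets = [m for m in df.columns if m not in exempt]
    if targets and dropout_prob > 0:
        mask = rng.random((len(df), len(targets))) < dropout_prob
        sub = df[targets].to_numpy(dtype=object)
        sub[mask] = MISSING
        df[targets] = sub
    return GenotypeTable(df)


def simulate_two_platforms(
    cohort: Cohort,
    panel: MarkerPanel,
    subset: Sequence[str] | None = None,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypeTable, GenotypeTable]:
    """Genotype the same consensus genomes twice, as two platforms would.

    In the noiseless default both tables are derived from the identical
    consensus sequences, so concordance is exactly 1. With ``error_rate``
    > 0 the second table receives an independent per-cell substitution
    error with that probability (one random in-haplotype base flipped),
    for robustness testing; expected concordance is then ≈ 1 − error_rate.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genomes = cohort.consensus
    if subset is not None:
        missing = sorted(set(subset) - set(genomes))
        if missing:
            raise KeyError(f"subset samples not in cohort: {missing}")
        genomes = {s: genomes[s] for s in subset}
    table_a = extract_haplotypes(genomes, panel)
    table_b = extract_haplotypes(genomes, panel)
    if error_rate > 0:
        df = table_b.data.copy()
        for i in range(df.shape[0]):
            for j in range(df.shape[1]):
                hap = df.iat[i, j]
                if hap != MISSING and rng.random() < error_rate:
                    pos = int(rng.integers(len(hap)))
                    old = hap[pos]
                    choices = [b for b in "ACGT" if b != old]
                    df.iat[i, j] = hap[:pos] + choices[int(rng.integers(3))] + hap[pos + 1 :]
        table_b = GenotypeTable(df)
    return table_a, table_b
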