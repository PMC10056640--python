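"""End-to-end pipeline runner and the printed-table summary report.

Chains simulate → screen → genotype → core → identify → tree into one run
directory with a JSON report. Re-running with the same config and seed is
bit-identical on every data output (the log carries no timestamps for the
same reason).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from . import genotyping, io_formats, marker_screen, phylogeny, similarity
from .simulate import (
    Cohort,
    SimConfig,
    designate_exempt_markers,
    simulate_cohort,
    simulate_dropout,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the method's published settings
    (window 130 bp, step 10 bp, DP > 0.4, GS thresholds 0.60 / 0.986)."""

    out_dir: str = "mnp_run"
    seed: int = 0
    # inputs: either simulate=True or provide vcf/reference/consensus_dir
    simulate: bool = True
    sim: SimConfig | None = None
    vcf: str | None = None
    reference: str | None = None
    consensus_dir: str | None = None
    metadata: str | None = None
    # screen
    window: int = 130
    step: int = 10
    dp_min: float = 0.4
    min_separation: int = 1
    max_markers: int = 0  # 0 = unbounded
    # genotype
    min_depth: float = 10.0
    apply_dropout: bool = True  # simulated runs only: emulate marker dropout
    exempt_fraction: float = 0.4
    # identify
    theta_ped: float = similarity.THETA_PEDIGREE
    theta_cv: float = similarity.THETA_CULTIVAR
    linkage_mode: str = "single"
    # tree
    distance: str = "pdist"  # or "gs"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, populate the run directory, return the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mnpkit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        report = _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()
    outputs = {p.name: _sha256(p) for p in sorted(out.iterdir())
               if p.is_file() and p.name not in ("pipeline.log", "report.json")}
    report["checksums"] = outputs
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _run(config: PipelineConfig, out: Path) -> dict:
    report: dict = {"parameters": {k: v for k, v in asdict(config).items() if k != "sim"}}

    # ---- stage: inputs ----------------------------------------------------
    truth = None
    if config.simulate:
        sim_cfg = config.sim or SimConfig(seed=config.seed)
        report["parameters"]["sim"] = asdict(sim_cfg)
        logger.info("simulating cohort (seed=%d)", sim_cfg.seed)
        cohort = simulate_cohort(sim_cfg)
        paths = cohort.write(out / "cohort")
        vcf_path, consensus = paths["vcf"], cohort.consensus
        contig_length = sim_cfg.genome_length
        truth = cohort.truth
        source_of = cohort.truth.source
    else:
        if not (config.vcf and config.reference and config.consensus_dir):
            raise ValueError("non-simulated run requires vcf, reference and consensus_dir")
        vcf_path = Path(config.vcf)
        reference = io_formats.read_fasta(config.reference)
        contig_length = max(len(s) for s in reference.values())
        consensus = {
            p.stem: io_formats.read_fasta(p)
            for p in sorted(Path(config.consensus_dir).glob("*.fasta"))
        }
        source_of = {}

    # ---- stage: screen ----------------------------------------------------
    matrix, skipped = io_formats.read_vcf_genotypes(vcf_path)
    logger.info("SNP matrix: %d sites (%d records skipped), %d samples",
                len(matrix.positions), skipped, matrix.n_samples)
    windows = marker_screen.scan_windows(
        matrix, contig_length, window=config.window, step=config.step,
        min_separation=config.min_separation,
    )
    panel = marker_screen.select_panel(windows, dp_min=config.dp_min,
                                       max_markers=config.max_markers or None)
    panel.params.update({"window": config.window, "step": config.step,
                         "min_separation": config.min_separation})
    io_formats.write_bed(panel, out / "panel.bed")
    (out / "panel.params.json").write_text(json.dumps(panel.params, sort_keys=True) + "\n")
    logger.info("panel: %d markers from %d windows", len(panel), len(windows))
    if not panel.markers:
        raise RuntimeError("screen stage selected an empty panel")

    # ---- stage: genotype --------------------------------------------------
    table = genotyping.extract_haplotypes(consensus, panel, min_depth=config.min_depth)
    if config.simulate and config.apply_dropout:
        sim_cfg = config.sim or SimConfig(seed=config.seed)
        exempt = (designate_exempt_markers(panel, config.exempt_fraction)
                  if sim_cfg.core_dropout_exempt else [])
        table = simulate_dropout(table, sim_cfg.marker_dropout_prob, exempt,
                                 seed=sim_cfg.seed + 1)
    table.to_tsv(out / "genotypes.tsv")

    # ---- stage: core ------------------------------------------------------
    core = genotyping.select_core(table)
    (out / "core.txt").write_text("".join(f"{m}\n" for m in core.marker_ids))
    logger.info("core markers: %d of %d", core.m, len(panel))

    # ---- stage: identify --------------------------------------------------
    gsm = similarity.gs_matrix(table, core)
    io_formats.write_matrix_csv(gsm.samples, gsm.gs, out / "gs.csv")
    with open(out / "verdicts.tsv", "w") as fh:
        fh.write("sample_a\tsample_b\tgs\tverdict\n")
        for a, b in itertools.combinations(gsm.samples, 2):
            cls = similarity.classify_pair(gsm.value(a, b), config.theta_ped,
                                           config.theta_cv, pair=(a, b))
            fh.write(f"{a}\t{b}\t{cls.gs:.6f}\t{cls.verdict}\n")
    partition = similarity.pedigree_partition(gsm, config.theta_ped, config.linkage_mode)
    with open(out / "pedigrees.tsv", "w") as fh:
        fh.write("sample\tpedigree\n")
        for sample in gsm.samples:
            fh.write(f"{sample}\t{partition[sample]}\n")
    n_pedigrees = len(set(partition.values()))
    logger.info("pedigrees: %d", n_pedigrees)

    # ---- stage: tree ------------------------------------------------------
    dm = (phylogeny.distance_from_gs(gsm) if config.distance == "gs"
          else phylogeny.distance_pdist(table, core))
    tree = phylogeny.nj_tree(dm)
    io_formats.write_newick(tree, out / "tree.nwk")
    metadata = {
        s: io_formats.SampleRecord(sample_id=s, source=source_of.get(s, "cultivar"))
        for s in gsm.samples
    }
    phylogeny.annotate_leaves(tree, metadata, partition, out / "ann.tsv")

    report["counts"] = {
        "snp_sites": int(len(matrix.positions)),
        "vcf_records_skipped": int(skipped),
        "windows_scanned": len(windows),
        "markers_selected": len(panel),
        "core_markers": core.m,
        "samples": len(gsm.samples),
        "pedigrees": n_pedigrees,
    }
    if truth is not None:
        recovered = {frozenset(s for s in gsm.samples if partition[s] == g)
                     for g in set(partition.values())}
        report["truth"] = {
            "pedigrees": len(truth.partition()),
            "partition_recovered": recovered == truth.partition(),
            "identical_pairs_gs": {
                f"{a}|{b}": gsm.value(a, b) for a, b in truth.identical_pairs
            },
        }
    return report


def paper_tables(fixtures_dir: str | Path | None = None) -> dict:
    """Summaries of the shipped strain-metadata tables.

    Reports the whole-genome cohort means (depth, genome coverage, mapping
    rate; table1, deduplicated), the marker-library mean coverage and both
    the recomputed and per-strain detected-marker figures (table2), and
    the strain counts by source across both tables.
    """
    if fixtures_dir is None:
        t1_path = io_formats.bundled_table("table1.tsv")
        t2_path = io_formats.bundled_table("table2.tsv")
    else:
        t1_path = Path(fixtures_dir) / "table1.tsv"
        t2_path = Path(fixtures_dir) / "table2.tsv"
        for p in (t1_path, t2_path):
            if not p.exists():
                raise FileNotFoundError(f"fixture missing: {p}")
    t1 = io_formats.load_sample_table(t1_path, dedupe=True)
    t2 = io_formats.load_sample_table(t2_path, dedupe=True)
    s1 = io_formats.summarize_cohort(t1)
    s2 = io_formats.summarize_cohort(t2)
    both = io_formats.summarize_cohort(t1 + t2)
    return {
        "table1": {
            "n_samples": s1.n_samples,
            "mean_depth": round(s1.mean_depth, 1),
            "mean_genome_coverage_pct": round(100 * s1.mean_coverage, 1),
            "mean_mapping_rate_pct": round(100 * s1.mean_mapping_rate, 1),
        },
        "table2": {
            "n_samples": s2.n_samples,
            "mean_marker_coverage": round(s2.mean_marker_coverage),
            "mean_markers_detected": round(s2.mean_markers_detected, 1),
            "total_markers_detected": s2.total_markers_detected,
        },
        "combined": {
            "n_samples": both.n_samples,
            "n_cultivar": both.n_cultivar,
            "n_wild": both.n_wild,
        },
    }
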