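"""Readers/writers for the standard formats the MNP pipeline touches.

Covers paired-end FASTQ quality filtering, FASTA round-trips, ingestion of
multi-sample VCF genotypes into a :class:`~mnpkit.marker_screen.SnpMatrix`,
the shipped strain-metadata tables with their cohort summaries, and the
BED5 / Newick / CSV writers for pipeline outputs.

Coordinate convention: 0-based half-open everywhere inside the package;
conversions happen only at the VCF (1-based) and BED (0-based) boundaries.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .marker_screen import MISSING, MarkerPanel, SnpMatrix

logger = logging.getLogger(__name__)

# IUPAC ambiguity code for each unordered base pair (dikaryon heterozygotes).
_IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


# ---------------------------------------------------------------------------
# FASTQ read-pair QC
# ---------------------------------------------------------------------------

@dataclass
class ReadPair:
    """A paired-end read with Phred+33-decoded quality scores."""

    id: str
    seq1: str
    seq2: str
    qual1: list[int]
    qual2: list[int]

    def __post_init__(self) -> None:
        for seq, qual, mate in ((self.seq1, self.qual1, 1), (self.seq2, self.qual2, 2)):
            if len(seq) != len(qual):
                raise ValueError(
                    f"read pair {self.id!r} mate {mate}: sequence length "
                    f"{len(seq)} != quality length {len(qual)}"
                )
            if qual and (min(qual) < 0 or max(qual) > 93):
                raise ValueError(f"read pair {self.id!r} mate {mate}: Phred score outside [0, 93]")


@dataclass
class FilterCounts:
    """Per-reason tally of discarded pairs; kept + discarded == total."""

    kept: int = 0
    adapter: int = 0
    n_content: int = 0
    low_quality: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.adapter + self.n_content + self.low_quality


def filter_read_pairs(
    pairs: Iterable[ReadPair],
    adapter: str,
    n_frac_max: float = 0.10,
    lowq_phred: int = 5,
    lowq_frac_max: float = 0.50,
    counts: FilterCounts | None = None,
) -> Iterator[ReadPair]:
    """Apply the read-pair QC rules, yielding survivors in input order.

    A pair is discarded iff any of the following holds in *either* mate:

    1. the adapter string occurs as an exact substring;
    2. the fraction of uncertain (``N``) bases exceeds ``n_frac_max``
       (strictly more than 10% by default);
    3. the fraction of bases with Phred quality below ``lowq_phred`` is
       over ``lowq_frac_max`` (strictly more than 50% by default).

    The first matching rule is the recorded discard reason. Pass a
    :class:`FilterCounts` to collect the per-reason tally.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if counts is None:
        counts = FilterCounts()
    for pair in pairs:
        reason = _discard_reason(pair, adapter, n_frac_max, lowq_phred, lowq_frac_max)
        if reason is None:
            counts.kept += 1
            yield pair
        else:
            setattr(counts, reason, getattr(counts, reason) + 1)


def _discard_reason(
    pair: ReadPair, adapter: str, n_frac_max: float, lowq_phred: int, lowq_frac_max: float
) -> str | None:
    for seq, qual in ((pair.seq1, pair.qual1), (pair.seq2, pair.qual2)):
        if adapter in seq:
            return "adapter"
    for seq, qual in ((pair.seq1, pair.qual1), (pair.seq2, pair.qual2)):
        if seq and seq.count("N") / len(seq) > n_frac_max:
            return "n_content"
    for seq, qual in ((pair.seq1, pair.qual1), (pair.seq2, pair.qual2)):
        if qual and sum(q < lowq_phred for q in qual) / len(qual) > lowq_frac_max:
            return "low_quality"
    return None


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream mate pairs from two synchronized FASTQ files (Phred+33)."""
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    index = 0
    while True:
        try:
            rec1 = next(it1, None)
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {index} in {path1}: {exc}") from exc
        try:
            rec2 = next(it2, None)
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {index} in {path2}: {exc}") from exc
        if rec1 is None and rec2 is None:
            return
        if rec1 is None or rec2 is None:
            raise ValueError(f"mate-count mismatch between {path1} and {path2} at record {index}")
        yield ReadPair(
            id=rec1.id,
            seq1=str(rec1.seq).upper(),
            seq2=str(rec2.seq).upper(),
            qual1=list(rec1.letter_annotations["phred_quality"]),
            qual2=list(rec2.letter_annotations["phred_quality"]),
        )
        index += 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a multi-FASTA into an ordered ``{contig_id: sequence}`` map (upper-cased)."""
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise ValueError(f"duplicate contig id {record.id!r} in {path}")
        genome[record.id] = str(record.seq).upper()
    if not genome:
        logger.warning("FASTA file %s contains no sequences", path)
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for contig, seq in genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------

def read_vcf_genotypes(
    path: str | Path,
    samples: list[str] | None = None,
    het_policy: str = "iupac",
) -> tuple[SnpMatrix, int]:
    """Read biallelic SNP records from a VCF into a :class:`SnpMatrix`.

    Multiallelic and indel records are skipped; the skip count is returned
    alongside the matrix. 1-based VCF positions become internal 0-based
    coordinates. Missing genotypes map to the missing state. Heterozygous
    diploid calls map per ``het_policy``: ``"iupac"`` (default) encodes the
    allele pair as its IUPAC ambiguity base — the faithful representation
    for dikaryotic strains genotyped as consensus sequences — while
    ``"major"`` takes the first allele of the call.
    """
    from cyvcf2 import VCF  # deferred: cyvcf2 import is slow

    if het_policy not in ("iupac", "major"):
        raise ValueError(f"unknown het_policy {het_policy!r}")
    vcf = VCF(str(path))
    header_samples = list(vcf.samples)
    if samples is None:
        samples = header_samples
    else:
        missing = [s for s in samples if s not in header_samples]
        if missing:
            raise ValueError(f"samples absent from VCF header: {missing}")
    col = [header_samples.index(s) for s in samples]

    contig = None
    positions: list[int] = []
    rows: list[list[str]] = []
    skipped = 0
    for variant in vcf:
        alts = variant.ALT
        if len(alts) != 1 or len(variant.REF) != 1 or len(alts[0]) != 1:
            skipped += 1
            continue
        if contig is None:
            contig = variant.CHROM
        elif variant.CHROM != contig:
            raise ValueError(
                f"multi-contig VCF not supported in one matrix: {contig!r} vs {variant.CHROM!r}"
            )
        alleles = (variant.REF.upper(), alts[0].upper())
        row = []
        genotypes = variant.genotypes  # [allele1, allele2, ..., phased]
        for c in col:
            gt = [a for a in genotypes[c][:-1] if a is not None]
            calls = sorted({a for a in gt if a >= 0})
            if not calls:
                row.append(MISSING)
            elif len(calls) == 1:
                row.append(alleles[calls[0]])
            else:  # heterozygous
                if het_policy == "major":
                    row.append(alleles[gt[0]])
                else:
                    pair = frozenset(alleles)
                    row.append(_IUPAC.get(pair, MISSING))
        positions.append(variant.POS - 1)
        rows.append(row)
    matrix = SnpMatrix(
        contig=contig or "",
        positions=np.asarray(positions, dtype=np.int64),
        alleles=np.asarray(rows, dtype="<U1") if rows else np.empty((0, len(samples)), dtype="<U1"),
        samples=list(samples),
    )
    return matrix, skipped


# ---------------------------------------------------------------------------
# Strain metadata tables
# ---------------------------------------------------------------------------

@dataclass
class SampleRecord:
    """One strain's row from the cohort metadata tables."""

    sample_id: str
    source: str  # "wild" | "cultivar"
    cap_color: str = "unknown"  # "white" | "yellow" | "unknown"
    location: str = ""
    clean_bases: int | None = None
    mapping_rate: float | None = None  # fraction in [0, 1]
    genome_coverage: float | None = None  # fraction in [0, 1]
    mean_depth: float | None = None  # fold
    marker_coverage: float | None = None  # fold
    markers_detected: int | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        for name in ("mapping_rate", "genome_coverage"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.sample_id}: {name}={v} outside [0, 1]")
        for name in ("mean_depth", "marker_coverage"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{self.sample_id}: {name}={v} negative")


@dataclass
class CohortSummary:
    n_samples: int
    n_cultivar: int
    n_wild: int
    mean_depth: float | None = None
    mean_coverage: float | None = None
    mean_mapping_rate: float | None = None
    mean_marker_coverage: float | None = None
    mean_markers_detected: float | None = None
    total_markers_detected: int | None = None


_COLUMN_MAP = {
    "sample": "sample_id",
    "clean base (bp)": "clean_bases",
    "clean reads": "clean_bases",
    "average mapping rate of reads": "mapping_rate",
    "mean genome coverage": "genome_coverage",
    "mean depth": "mean_depth",
    "average coverage of mnp markers": "marker_coverage",
    "number of mnp marker detected": "markers_detected",
    "cap color": "cap_color",
    "source": "source",
    "location": "location",
}

_INT_FIELDS = {"clean_bases", "markers_detected"}
_PCT_FIELDS = {"mapping_rate", "genome_coverage"}
_FLOAT_FIELDS = {"mean_depth", "marker_coverage"}


def _parse_numeric(raw: str, fieldname: str, row: int, col: str) -> float:
    text = raw.replace(",", "").rstrip("%")
    try:
        return float(text)
    except ValueError as exc:
        raise ValueError(f"unparseable numeric cell at row {row}, column {col!r}: {raw!r}") from exc


def load_sample_table(path: str | Path, dedupe: bool = True) -> list[SampleRecord]:
    """Load a TSV of strain metadata (either table schema) into SampleRecords.

    Percent columns are stored as fractions. With ``dedupe=True`` an exact
    repeated sample_id keeps only its first occurrence (the shipped table
    prints strain GR91-1 twice).
    """
    records: list[SampleRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: missing header row")
        fields = {name: _COLUMN_MAP.get(name.strip().lower()) for name in reader.fieldnames}
        for i, row in enumerate(reader, start=1):
            kwargs: dict = {}
            for raw_name, fieldname in fields.items():
                if fieldname is None:
                    continue
                raw = (row.get(raw_name) or "").strip()
                if fieldname == "sample_id":
                    kwargs["sample_id"] = raw
                elif fieldname == "source":
                    kwargs["source"] = "wild" if "wild" in raw.lower() else "cultivar"
                elif fieldname == "cap_color":
                    kwargs["cap_color"] = raw.lower() if raw.lower() in ("white", "yellow") else "unknown"
                elif fieldname == "location":
                    kwargs["location"] = "" if raw == "-" else raw
                elif not raw or raw == "-":
                    kwargs[fieldname] = None
                else:
                    value = _parse_numeric(raw, fieldname, i, raw_name)
                    if fieldname in _PCT_FIELDS:
                        value /= 100.0
                    elif fieldname in _INT_FIELDS:
                        value = int(value)
                    kwargs[fieldname] = value
            rec = SampleRecord(**kwargs)
            if dedupe:
                if rec.sample_id in seen:
                    continue
                seen.add(rec.sample_id)
            records.append(rec)
    return records


def summarize_cohort(records: list[SampleRecord]) -> CohortSummary:
    """Unweighted arithmetic means and source counts over metadata records.

    Each mean is computed over the records that carry the field, so tables
    with different schemata can be summarized jointly.
    """
    if not records:
        raise ValueError("no records to summarize")

    def _mean(fieldname: str) -> float | None:
        vals = [getattr(r, fieldname) for r in records if getattr(r, fieldname) is not None]
        # math.fsum: exact, hence invariant to record order
        return math.fsum(vals) / len(vals) if vals else None

    detected = [r.markers_detected for r in records if r.markers_detected is not None]
    return CohortSummary(
        n_samples=len(records),
        n_cultivar=sum(r.source == "cultivar" for r in records),
        n_wild=sum(r.source == "wild" for r in records),
        mean_depth=_mean("mean_depth"),
        mean_coverage=_mean("genome_coverage"),
        mean_mapping_rate=_mean("mapping_rate"),
        mean_marker_coverage=_mean("marker_coverage"),
        mean_markers_detected=(math.fsum(detected) / len(detected)) if detected else None,
        total_markers_detected=int(np.sum(detected)) if detected else None,
    )


def bundled_table(name: str) -> Path:
    """Path to a shipped metadata fixture (``table1.tsv`` or ``table2.tsv``)."""
    path = Path(__file__).parent / "data" / name
    if not path.exists():
        raise FileNotFoundError(f"no bundled table {name!r}")
    return path


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def write_bed(panel: MarkerPanel, path: str | Path) -> None:
    """Write a marker panel as BED5: contig, start, end, marker_id, DP."""
    with open(path, "w") as fh:
        for marker in panel.markers:
            fh.write(
                f"{marker.contig}\t{marker.start}\t{marker.end}\t{marker.marker_id}\t{marker.dp:g}\n"
            )


def read_bed(path: str | Path) -> MarkerPanel:
    from .marker_screen import Window

    markers = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, start, end, marker_id, dp = line.rstrip("\n").split("\t")[:5]
            markers.append(
                Window(contig=contig, start=int(start), end=int(end), t=-1,
                       dp=float(dp), marker_id=marker_id)
            )
    return MarkerPanel(markers=markers, params={})


def write_matrix_csv(samples: list[str], matrix: np.ndarray, path: str | Path) -> None:
    """Write a symmetric sample-by-sample matrix as CSV with header row/column."""
    df = pd.DataFrame(np.asarray(matrix), index=samples, columns=samples)
    df.to_csv(path)


def read_matrix_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    return list(df.index), df.to_numpy(dtype=float)


def write_newick(tree, path: str | Path) -> None:
    """Serialize a tree to Newick with 6-decimal fixed-format branch lengths."""
    from .phylogeny import to_newick

    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")
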