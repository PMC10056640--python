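"""Per-sample MNP haplotype genotyping, core-marker selection and concordance.

Haplotypes are slices of each strain's consensus genome at panel
coordinates; a marker counts as detected in a strain when its slice is
unambiguous (no ``N``) and, when depth information is supplied, covered at
or above a minimum fold depth. Core markers are the panel subset detected
in 100% of strains — the loci over which genetic similarity is defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .marker_screen import MarkerPanel

#: Serialized representation of an undetected marker haplotype.
MISSING = "."


@dataclass
class GenotypeTable:
    """Samples × markers grid of haplotype strings (``.`` = missing).

    Backed by a pandas DataFrame with sample ids as the index and marker
    ids as columns; every cell is either a haplotype string or MISSING.
    """

    data: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def markers(self) -> list[str]:
        return list(self.data.columns)

    def detected_per_sample(self) -> pd.Series:
        """Number of non-missing markers in each strain's row."""
        return (self.data != MISSING).sum(axis=1)

    def detected_per_marker(self) -> pd.Series:
        return (self.data != MISSING).sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeTable":
        return cls(pd.read_csv(path, sep="\t", index_col="sample", dtype=str))


@dataclass
class CoreSet:
    """Markers detected in every sample, in panel order."""

    marker_ids: list[str]

    @property
    def m(self) -> int:
        return len(self.marker_ids)


def extract_haplotypes(
    consensus: Mapping[str, Mapping[str, str]],
    panel: MarkerPanel,
    min_depth: float = 10.0,
    depths: Mapping[str, Mapping[str, float]] | None = None,
    n_max: int = 1,
) -> GenotypeTable:
    """Slice each sample's consensus genome at the panel coordinates.

    A cell is the upper-cased substring ``[start, end)`` of the sample's
    consensus contig, set to MISSING when the substring contains ``n_max``
    or more ambiguous ``N`` bases (default: any N) or when the supplied
    per-sample per-marker depth is below ``min_depth``.
    """
    rows = {}
    for sample, genome in consensus.items():
        row = {}
        for marker in panel.markers:
            if marker.contig not in genome:
                raise ValueError(
                    f"sample {sample!r}: contig {marker.contig!r} absent "
                    f"(needed by marker {marker.marker_id})"
                )
            contig_seq = genome[marker.contig]
            if len(contig_seq) < marker.end:
                raise ValueError(
                    f"sample {sample!r}: contig {marker.contig!r} length {len(contig_seq)} "
                    f"shorter than marker {marker.marker_id} end {marker.end}"
                )
            hap = contig_seq[marker.start : marker.end].upper()
            if hap.count("N") >= n_max:
                hap = MISSING
            elif depths is not None:
                depth = depths.get(sample, {}).get(marker.marker_id)
                if depth is not None and depth < min_depth:
                    hap = MISSING
            row[marker.marker_id] = hap
        rows[sample] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex(columns=[m.marker_id for m in panel.markers])
    df.index.name = "sample"
    return GenotypeTable(df)


def select_core(table: GenotypeTable) -> CoreSet:
    """Markers with zero missing cells — detected in 100% of samples."""
    detected = table.data != MISSING
    core = [m for m in table.markers if bool(detected[m].all())]
    if not core:
        raise ValueError(
            "no marker is detected in all samples; genetic similarity is undefined "
            "with an empty core set — revise the panel or detection thresholds"
        )
    return CoreSet(core)


@dataclass
class ConcordanceResult:
    fraction: float
    compared: int
    identical: int
    discordant_markers: list[str] = field(default_factory=list)


def concordance(table_a: GenotypeTable, table_b: GenotypeTable) -> ConcordanceResult:
    """Cross-platform genotype agreement.

    Compares every cell that is non-missing in ``table_a`` (the assay whose
    detections are being verified, e.g. targeted MNP sequencing) against the
    corresponding cell in ``table_b`` (e.g. whole-genome-derived genotypes),
    over the common samples and markers. Returns the identical fraction and
    the markers with at least one discordant cell.
    """
    samples = [s for s in table_a.samples if s in set(table_b.samples)]
    if not samples:
        raise ValueError("tables share no samples")
    markers = [m for m in table_a.markers if m in set(table_b.markers)]
    a = table_a.data.loc[samples, markers]
    b = table_b.data.loc[samples, markers]
    mask = a != MISSING
    compared = int(mask.to_numpy().sum())
    same = (a == b) & mask
    identical = int(same.to_numpy().sum())
    per_marker_bad = (mask & ~same).sum(axis=0)
    discordant = [m for m in markers if per_marker_bad[m] > 0]
    fraction = identical / compared if compared else float("nan")
    return ConcordanceResult(fraction, compared, identical, discordant)
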