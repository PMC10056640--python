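"""Genetic similarity (GS) fingerprinting and pedigree classification.

GS between two strains is the number of core MNP markers at which their
haplotype sequences are identical, divided by the number of core markers M;
it therefore takes only the values k/M. Strain pairs are classified with
two thresholds: GS ≤ 0.60 separates pedigrees, 0.60 < GS ≤ 0.986 marks
different cultivars within one pedigree, and GS > 0.986 marks the same
cultivar (GS = 1 indicating a shared genetic origin under distinct names).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import networkx as nx
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .genotyping import MISSING, CoreSet, GenotypeTable

#: Pedigree-separation threshold: pairs at or below are different pedigrees.
THETA_PEDIGREE = 0.60
#: Cultivar-identity threshold: pairs strictly above are the same cultivar.
THETA_CULTIVAR = 0.986

SAME_CULTIVAR = "same_cultivar"
SAME_PEDIGREE = "same_pedigree_different_cultivar"
DIFFERENT_PEDIGREE = "different_pedigree"


@dataclass
class GsMatrix:
    """Symmetric pairwise genetic-similarity matrix with unit diagonal."""

    samples: list[str]
    gs: np.ndarray  # (n, n) float in [0, 1]
    m: int  # number of core markers used

    def value(self, a: str, b: str) -> float:
        i, j = self.samples.index(a), self.samples.index(b)
        return float(self.gs[i, j])


@dataclass
class PairClassification:
    pair: tuple[str, str] | None
    gs: float
    verdict: str
    near_identity: bool = False
    thresholds: dict = field(default_factory=dict)


def gs_pair(row_a: Sequence[str], row_b: Sequence[str], m: int | None = None) -> float:
    """GS = (#markers with identical haplotype strings) / M."""
    if len(row_a) != len(row_b):
        raise ValueError(f"haplotype vectors differ in length: {len(row_a)} vs {len(row_b)}")
    if m is None:
        m = len(row_a)
    elif m != len(row_a):
        raise ValueError(f"vectors have length {len(row_a)}, expected M={m}")
    if m == 0:
        raise ValueError("GS undefined over zero core markers")
    if MISSING in row_a or MISSING in row_b:
        raise ValueError("core-marker haplotype vectors must not contain missing cells")
    identical = sum(a == b for a, b in zip(row_a, row_b))
    return identical / m


def gs_matrix(table: GenotypeTable, core: CoreSet | None = None) -> GsMatrix:
    """All-pairs GS over the core markers (symmetric, unit diagonal)."""
    markers = core.marker_ids if core is not None else table.markers
    data = table.data[markers]
    samples = list(data.index)
    n = len(samples)
    if n < 2:
        raise ValueError("gs_matrix requires at least 2 samples")
    arr = data.to_numpy(dtype=object)
    if (arr == MISSING).any():
        raise ValueError("core-marker table contains missing cells")
    m = len(markers)
    gs = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            gs[i, j] = gs[j, i] = np.count_nonzero(arr[i] == arr[j]) / m
    return GsMatrix(samples=samples, gs=gs, m=m)


def classify_pair(
    gs: float,
    theta_ped: float = THETA_PEDIGREE,
    theta_cv: float = THETA_CULTIVAR,
    pair: tuple[str, str] | None = None,
) -> PairClassification:
    """Classify one strain pair from its GS value.

    gs ≤ theta_ped → different pedigrees; theta_ped < gs ≤ theta_cv →
    different cultivars in the same pedigree; gs > theta_cv → same cultivar.
    Verdicts in the open interval (theta_cv, 1) carry a near-identity flag:
    the pair is called one cultivar but is not byte-identical at every core
    marker.
    """
    if not (0.0 <= gs <= 1.0):
        raise ValueError(f"GS {gs} outside [0, 1]")
    if gs <= theta_ped:
        verdict = DIFFERENT_PEDIGREE
    elif gs <= theta_cv:
        verdict = SAME_PEDIGREE
    else:
        verdict = SAME_CULTIVAR
    return PairClassification(
        pair=pair,
        gs=gs,
        verdict=verdict,
        near_identity=(verdict == SAME_CULTIVAR and gs < 1.0),
        thresholds={"theta_ped": theta_ped, "theta_cv": theta_cv},
    )


def pedigree_partition(
    gsm: GsMatrix,
    theta_ped: float = THETA_PEDIGREE,
    linkage_mode: str = "single",
) -> dict[str, str]:
    """Group strains into pedigrees by thresholding the GS matrix.

    Default single linkage: pedigrees are the connected components of the
    graph with an edge wherever GS > theta_ped — the minimal grouping
    consistent with the pairwise threshold rule. ``linkage_mode="complete"``
    instead cuts a complete-linkage dendrogram on distance 1 − GS, so every
    within-pedigree pair exceeds the threshold. Labels G1, G2, ... are
    assigned by descending pedigree size, then by lexicographically
    smallest member.
    """
    n = len(gsm.samples)
    if linkage_mode == "single":
        graph = nx.Graph()
        graph.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if gsm.gs[i, j] > theta_ped:
                    graph.add_edge(i, j)
        components = [sorted(c) for c in nx.connected_components(graph)]
    elif linkage_mode == "complete":
        if n == 1:
            components = [[0]]
        else:
            dist = 1.0 - gsm.gs
            np.fill_diagonal(dist, 0.0)
            z = linkage(squareform(dist, checks=False), method="complete")
            # components share all pairwise distances < 1 - theta (strict GS > theta)
            eps = 1e-12
            labels = fcluster(z, t=1.0 - theta_ped - eps, criterion="distance")
            components = [
                sorted(np.nonzero(labels == lab)[0].tolist()) for lab in np.unique(labels)
            ]
    else:
        raise ValueError(f"unknown linkage_mode {linkage_mode!r}")

    components.sort(key=lambda c: (-len(c), gsm.samples[c[0]]))
    # order members inside a component by sample id for stable output
    out: dict[str, str] = {}
    for k, comp in enumerate(components, start=1):
        for idx in sorted(comp, key=lambda i: gsm.samples[i]):
            out[gsm.samples[idx]] = f"G{k}"
    return out


@dataclass
class PedigreeStats:
    label: str
    size: int
    mean_within_gs: float | None  # None for singletons
    min_within_gs: float | None


def pedigree_stats(
    gsm: GsMatrix, partition: dict[str, str]
) -> tuple[list[PedigreeStats], float | None]:
    """Within-pedigree GS summaries and the minimum between-pedigree GS.

    Means are arithmetic over unordered within-pedigree pairs; singleton
    pedigrees are reported with undefined (None) within-GS. The second
    return value is the global minimum GS over all cross-pedigree pairs
    (None when there is a single pedigree).
    """
    labels = sorted(set(partition.values()), key=lambda g: int(g.lstrip("G")))
    idx = {s: i for i, s in enumerate(gsm.samples)}
    stats = []
    for label in labels:
        members = [s for s in gsm.samples if partition[s] == label]
        if len(members) < 2:
            stats.append(PedigreeStats(label, len(members), None, None))
            continue
        vals = [
            gsm.gs[idx[a], idx[b]]
            for k, a in enumerate(members)
            for b in members[k + 1 :]
        ]
        stats.append(
            PedigreeStats(label, len(members), float(np.mean(vals)), float(np.min(vals)))
        )
    between = [
        gsm.gs[i, j]
        for i in range(len(gsm.samples))
        for j in range(i + 1, len(gsm.samples))
        if partition[gsm.samples[i]] != partition[gsm.samples[j]]
    ]
    return stats, (float(np.min(between)) if between else None)
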