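"""Cluster aligned chimeras into interactions and attach annotation/support.

An interaction is a transitive-closure cluster of same-miRNA, same-strand
chimera alignments with overlapping genomic coordinates.  Its ligation site
is the modal 5' end of member fragments (ties resolved to the most upstream
position on the strand) and its 75-nt target region runs downstream of that
site; clusters longer than 100 nt are dropped and clusters of 76-100 nt are
trimmed symmetrically to 75.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .detect import TargetAlignment
from .io import GenomeRef, RegionAnnotation

REGION_PRIORITY = [
    "three_prime_utr",
    "cds",
    "five_prime_utr",
    "noncoding",
    "intron",
    "intergenic",
]


@dataclass
class Interaction:
    interaction_id: str
    mirna_id: str
    chrom: str
    strand: str
    start: int
    end: int
    n: int
    samples: set = field(default_factory=set)
    ligation_site: int = 0
    target_region: str = ""
    region_label: str = ""
    dropped: bool = False
    clipped: bool = False
    members: list = field(default_factory=list)


def cluster_chimeras(alignments: list[TargetAlignment]) -> list[Interaction]:
    """Merge same-miRNA, same-strand, coordinate-overlapping alignments."""
    groups: dict[tuple, list[TargetAlignment]] = {}
    for a in alignments:
        groups.setdefault((a.chimera.mirna_id, a.chrom, a.strand), []).append(a)
    out: list[Interaction] = []
    for (mirna, chrom, strand), members in sorted(groups.items()):
        members.sort(key=lambda a: (a.start, a.end))
        cur: list[TargetAlignment] = []
        cur_end = -1
        def flush():
            if not cur:
                return
            start = min(a.start for a in cur)
            end = max(a.end for a in cur)
            sites = Counter(a.ligation_site for a in cur)
            top = max(sites.values())
            modal = [s for s, c in sites.items() if c == top]
            site = min(modal) if strand == "+" else max(modal)
            out.append(
                Interaction(
                    interaction_id=f"I{len(out):06d}",
                    mirna_id=mirna, chrom=chrom, strand=strand,
                    start=start, end=end, n=len(cur),
                    samples={a.chimera.sample_id for a in cur if a.chimera.sample_id},
                    ligation_site=site,
                    members=list(cur),
                )
            )
        for a in members:
            if cur and a.start < cur_end:
                cur.append(a)
                cur_end = max(cur_end, a.end)
            else:
                flush()
                cur = [a]
                cur_end = a.end
        flush()
    return out


def define_target_region(
    interaction: Interaction, genome: GenomeRef, window: int = 75,
    max_span: int = 100,
) -> str | None:
    """75-nt target region downstream of the ligation site, strand-aware.

    Returns None (and flags the interaction dropped) for clusters > max_span.
    """
    span = interaction.end - interaction.start
    chrom_len = len(genome.chroms[interaction.chrom])
    if span > max_span:
        interaction.dropped = True
        return None
    if span > window:
        excess = span - window
        left = (excess + 1) // 2 if interaction.strand == "+" else excess // 2
        start = interaction.start + left
        end = start + window
    elif interaction.strand == "+":
        start = interaction.ligation_site
        end = start + window
    else:
        end = interaction.ligation_site + 1
        start = end - window
    if start < 0 or end > chrom_len:
        interaction.clipped = True
        start, end = max(start, 0), min(end, chrom_len)
    region = genome.fetch(interaction.chrom, start, end, interaction.strand)
    interaction.target_region = region
    return region


class _AnnotIndex:
    def __init__(self, annotation: RegionAnnotation):
        self.trees: dict[str, IntervalTree] = {}
        for r in annotation.records:
            self.trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)

    def labels_at(self, chrom: str, pos: int, strand: str) -> list[str]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return [
            iv.data.region_label
            for iv in tree.at(pos)
            if iv.data.strand == strand or iv.data.region_label == "mirna_locus"
        ]


def annotate_region(
    interaction: Interaction, annotation: RegionAnnotation | _AnnotIndex
) -> str:
    """Transcript-region label by midpoint overlap with a fixed priority ladder."""
    idx = annotation if isinstance(annotation, _AnnotIndex) else _AnnotIndex(annotation)
    mid = (interaction.start + interaction.end) // 2
    labels = set(idx.labels_at(interaction.chrom, mid, interaction.strand))
    for label in REGION_PRIORITY[:-1]:
        if label in labels:
            interaction.region_label = label
            return label
    interaction.region_label = "intergenic"
    return "intergenic"


def annotate_all(interactions, annotation: RegionAnnotation):
    idx = _AnnotIndex(annotation)
    for it in interactions:
        annotate_region(it, idx)
    return interactions


@dataclass
class PeakSupport:
    interaction_id: str
    overlapping_reads: int
    bc: int
    density: float


def peak_support(
    interactions: list[Interaction],
    nonchimeric: list[TargetAlignment],
    depths: dict[str, int],
    scale: float = 1e6,
) -> dict[str, PeakSupport]:
    """Non-chimeric read support per interaction.

    BC = number of distinct biological samples with >= 1 overlapping read;
    density = mean across libraries of the pseudocounted depth-normalized
    overlapping-read count (see :func:`normalize_counts`).
    """
    trees: dict[tuple, IntervalTree] = {}
    for i, it in enumerate(interactions):
        trees.setdefault((it.chrom, it.strand), IntervalTree()).addi(it.start, it.end, i)
    reads_per = [Counter() for _ in interactions]
    for a in nonchimeric:
        tree = trees.get((a.chrom, a.strand))
        if tree is None:
            continue
        for iv in tree.overlap(a.start, a.end):
            reads_per[iv.data][a.chimera.sample_id] += a.chimera.count
    out = {}
    for it, per_sample in zip(interactions, reads_per):
        total = sum(per_sample.values())
        norm = [
            (per_sample.get(s, 0) + 1) / depth * scale
            for s, depth in depths.items()
            if depth > 0
        ]
        out[it.interaction_id] = PeakSupport(
            it.interaction_id,
            overlapping_reads=total,
            bc=len(per_sample),
            density=float(np.mean(norm)) if norm else 0.0,
        )
    return out


def normalize_counts(
    counts: pd.DataFrame, depths: dict[str, int], scale: float = 1e6
) -> pd.DataFrame:
    """(count + 1) / library depth x scale, per cluster x library."""
    for lib in counts.columns:
        if depths.get(lib, 0) <= 0:
            raise ValueError(f"library {lib!r} has zero depth")
    return (counts + 1).div(pd.Series(depths)[counts.columns], axis=1) * scale


def interactions_table(interactions, support=None) -> pd.DataFrame:
    rows = []
    for it in interactions:
        sup = support.get(it.interaction_id) if support else None
        rows.append(
            {
                "interaction_id": it.interaction_id,
                "mirna_id": it.mirna_id,
                "chrom": it.chrom,
                "strand": it.strand,
                "start": it.start,
                "end": it.end,
                "N": it.n,
                "samples": ",".join(sorted(it.samples)),
                "BC": sup.bc if sup else 0,
                "density": sup.density if sup else 0.0,
                "region_label": it.region_label,
                "target_region": it.target_region,
                "dropped": it.dropped,
            }
        )
    return pd.DataFrame(rows)
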