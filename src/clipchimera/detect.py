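"""Chimera detection: locate mature miRNAs inside reads and place target flanks.

The "reverse mapping" contract: a miRNA hit requires its 5' 8-mer to occur in
the read with at most ``seed_mismatches`` (default 1) mismatches, extended
toward the miRNA 3' end with at most ``ext_mismatches`` (default 2) further
mismatches.  In full-length mode the entire miRNA must be spanned; in
truncation mode at least ``min_prefix`` (default 12) nt from the miRNA 5' end
must match and the number of absent 3' bases is recorded.  Flanking read
sequence >= 18 nt on either side of the hit becomes a target fragment:
downstream (3') flanks give miR-first chimeras, upstream flanks miR-last.

Target fragments are placed on the genome with edlib candidate search plus
Hamming verification (substitutions only); only fragments with exactly one
best-scoring placement are retained.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import edlib
import pandas as pd
from intervaltree import IntervalTree

from .io import GenomeRef, RegionAnnotation, SequenceRecord, revcomp


@dataclass(frozen=True)
class MiRNAEntry:
    mirna_id: str
    sequence: str  # mature 5'->3', DNA letters
    family_id: str = ""

    @property
    def seed(self) -> str:
        """Positions 2-8 heptamer."""
        return self.sequence[1:8]


class MiRNACatalog:
    """Mature-miRNA catalogue; seed families group identical positions 2-8."""

    def __init__(self, entries: list[MiRNAEntry]):
        by_seed: dict[str, list[MiRNAEntry]] = {}
        for e in entries:
            if len(e.sequence) < 16:
                raise ValueError(f"{e.mirna_id}: mature sequence shorter than 16 nt")
            by_seed.setdefault(e.seed, []).append(e)
        self.entries: list[MiRNAEntry] = []
        for seed, members in by_seed.items():
            fam = members[0].family_id or f"fam-{min(m.mirna_id for m in members)}"
            for m in members:
                self.entries.append(MiRNAEntry(m.mirna_id, m.sequence, fam))
        self.by_id = {e.mirna_id: e for e in self.entries}
        if len(self.by_id) != len(self.entries):
            raise ValueError("duplicate miRNA ids in catalogue")

    @classmethod
    def from_fasta(cls, path) -> "MiRNACatalog":
        from .io import read_sequences

        return cls(
            [MiRNAEntry(r.id, r.sequence) for r in read_sequences(path, "fasta")]
        )

    def family_members(self, mirna_id: str) -> list[MiRNAEntry]:
        fam = self.by_id[mirna_id].family_id
        return [e for e in self.entries if e.family_id == fam]


@dataclass
class MappingParams:
    seed_mismatches: int = 1
    ext_mismatches: int = 2
    truncation_mode: bool = False
    min_prefix: int = 12


@dataclass
class MiRNAHit:
    read_id: str
    mirna_id: str
    candidate_ids: frozenset
    read_span: tuple[int, int]
    mismatch_positions: tuple[int, ...]
    truncation_3p: int


@dataclass
class Chimera:
    read_id: str
    sample_id: str | None
    mirna_id: str
    orientation: str  # "miR_first" | "miR_last"
    target_fragment: str
    ligase_treated: bool = True
    count: int = 1
    truncation_3p: int = 0


@dataclass
class TargetAlignment:
    chimera: Chimera
    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int
    unique: bool = True

    @property
    def ligation_site(self) -> int:
        """Genomic coordinate of the target fragment's 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


def _match_one(read_seq: str, mseq: str, start: int, params: MappingParams):
    """Score the placement of ``mseq`` at ``start`` in the read; None if invalid."""
    L = len(mseq)
    avail = len(read_seq) - start
    seed_mm = [
        k for k in range(8) if read_seq[start + k] != mseq[k]
    ]
    if len(seed_mm) > params.seed_mismatches:
        return None
    span = min(L, avail)
    mm = list(seed_mm)
    if not params.truncation_mode:
        if avail < L:
            return None
        for k in range(8, L):
            if read_seq[start + k] != mseq[k]:
                mm.append(k)
                if len(mm) - len(seed_mm) > params.ext_mismatches:
                    return None
        return (len(mm), L, tuple(mm), 0)
    # truncation mode: greedy extension, span ends on a matching base
    matched_end = 8
    k = 8
    while k < span:
        if read_seq[start + k] == mseq[k]:
            matched_end = k + 1
        else:
            mm.append(k)
            if len(mm) - len(seed_mm) > params.ext_mismatches:
                break
        k += 1
    mm = [p for p in mm if p < matched_end]
    if matched_end < params.min_prefix:
        return None
    return (len(mm), matched_end, tuple(mm), L - matched_end)


def build_seed_index(catalog: MiRNACatalog, seed_mismatches: int = 1):
    """Map every <=``seed_mismatches``-variant of each miRNA 5' 8-mer to its ids."""
    index: dict[str, list[str]] = {}
    for e in catalog.entries:
        seed8 = e.sequence[:8]
        variants = {seed8}
        if seed_mismatches >= 1:
            for i in range(8):
                for b in "ACGT":
                    if b != seed8[i]:
                        variants.add(seed8[:i] + b + seed8[i + 1 :])
        for v in variants:
            index.setdefault(v, []).append(e.mirna_id)
    return index


def find_mirna_in_read(
    read: SequenceRecord,
    catalog: MiRNACatalog,
    params: MappingParams | None = None,
    seed_index=None,
) -> MiRNAHit | None:
    """Best placement of any catalogue miRNA inside the read, or None.

    Best = fewest total mismatches, then longest matched span, then leftmost
    read position.  Equal-scoring miRNAs at the winning position are returned
    as ``candidate_ids`` for downstream random resolution.
    """
    params = params or MappingParams()
    if seed_index is None:
        seed_index = build_seed_index(catalog, params.seed_mismatches)
    seq = read.sequence
    best = None  # (mm, -span, start) -> (candidates, span, mm_pos, trunc)
    for start in range(len(seq) - 7):
        ids = seed_index.get(seq[start : start + 8])
        if not ids:
            continue
        for mid in ids:
            res = _match_one(seq, catalog.by_id[mid].sequence, start, params)
            if res is None:
                continue
            n_mm, span, mm_pos, trunc = res
            key = (n_mm, -span, start)
            if best is None or key < best[0]:
                best = (key, {mid: (span, mm_pos, trunc)})
            elif key == best[0]:
                best[1][mid] = (span, mm_pos, trunc)
    if best is None:
        return None
    (n_mm, neg_span, start), cands = best
    mid = sorted(cands)[0]
    span, mm_pos, trunc = cands[mid]
    return MiRNAHit(
        read_id=read.id,
        mirna_id=mid,
        candidate_ids=frozenset(cands),
        read_span=(start, start + span),
        mismatch_positions=mm_pos,
        truncation_3p=trunc,
    )


def resolve_ambiguous(hit: MiRNAHit, rng_seed: int) -> MiRNAHit:
    """Collapse a multi-candidate hit to one randomly chosen miRNA.

    Deterministic given (rng_seed, read_id); the candidate set is retained
    for the strict family-analysis mode.
    """
    if not hit.candidate_ids:
        raise RuntimeError("hit has an empty candidate set")
    if len(hit.candidate_ids) == 1:
        return hit
    rng = random.Random(f"{rng_seed}:{hit.read_id}")
    chosen = rng.choice(sorted(hit.candidate_ids))
    return MiRNAHit(
        hit.read_id, chosen, hit.candidate_ids, hit.read_span,
        hit.mismatch_positions, hit.truncation_3p,
    )


def extract_flanks(
    read: SequenceRecord, hit: MiRNAHit, min_len: int = 18,
    ligase_treated: bool = True,
) -> list[Chimera]:
    """Emit miR-first (3' flank) and/or miR-last (5' flank) chimeras >= min_len."""
    out = []
    start, end = hit.read_span
    five = read.sequence[:start]
    three = read.sequence[end:]
    if len(five) >= min_len:
        out.append(Chimera(read.id, read.sample_id, hit.mirna_id, "miR_last",
                           five, ligase_treated, read.count, hit.truncation_3p))
    if len(three) >= min_len:
        out.append(Chimera(read.id, read.sample_id, hit.mirna_id, "miR_first",
                           three, ligase_treated, read.count, hit.truncation_3p))
    return out


class GenomeIndex:
    """Genome wrapper for fragment placement (edlib search + Hamming check)."""

    def __init__(self, genome: GenomeRef):
        self.genome = genome

    def _hits(self, frag: str, max_mm: int):
        hits = []
        for chrom, seq in self.genome.chroms.items():
            for strand in "+-":
                query = frag if strand == "+" else revcomp(frag)
                res = edlib.align(query, seq, mode="HW", task="locations", k=max_mm)
                if res["editDistance"] < 0:
                    continue
                starts = set()
                for (s, e) in res["locations"]:
                    # edlib end positions are inclusive; recover fixed-length
                    # windows near each location and verify by Hamming.
                    for cand in range(e - len(query), e - len(query) + 3):
                        if 0 <= cand <= len(seq) - len(query):
                            starts.add(cand)
                for s in starts:
                    window = seq[s : s + len(query)]
                    mm = sum(a != b for a, b in zip(window, query))
                    if mm <= max_mm:
                        hits.append((mm, chrom, s, s + len(query), strand))
        return hits


def map_target(
    chimera: Chimera, index: GenomeIndex, max_mismatches: int = 2
) -> TargetAlignment | str:
    """Place a target fragment; returns a rejection reason string on failure."""
    hits = index._hits(chimera.target_fragment, max_mismatches)
    if not hits:
        return "unmapped"
    best_mm = min(h[0] for h in hits)
    best = sorted(set(h for h in hits if h[0] == best_mm))
    if len(best) > 1:
        return "multi_mapped"
    mm, chrom, start, end, strand = best[0]
    return TargetAlignment(chimera, chrom, start, end, strand, mm)


def filter_mirna_loci(
    alignments: list[TargetAlignment], annotation: RegionAnnotation
) -> list[TargetAlignment]:
    """Drop alignments overlapping any annotated miRNA locus (either strand)."""
    trees: dict[str, IntervalTree] = {}
    for r in annotation.records:
        if r.region_label == "mirna_locus":
            trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    return [
        a
        for a in alignments
        if not (a.chrom in trees and trees[a.chrom].overlap(a.start, a.end))
    ]


def estimate_false_ligation_rate(
    chimeras: list[Chimera],
    primary: GenomeRef,
    foreign: GenomeRef,
    max_mismatches: int = 2,
):
    """Fraction of target fragments attributable to a foreign (mixed-in) genome.

    Each fragment is assigned to primary, foreign, both (ambiguous, excluded)
    or neither; rate = foreign / (primary + foreign).
    """
    if primary.chroms == foreign.chroms:
        raise ValueError("primary and foreign genomes are identical")
    pidx, fidx = GenomeIndex(primary), GenomeIndex(foreign)
    counts = {"primary": 0, "foreign": 0, "ambiguous": 0, "neither": 0}
    rows = []
    for c in chimeras:
        in_p = bool(pidx._hits(c.target_fragment, max_mismatches))
        in_f = bool(fidx._hits(c.target_fragment, max_mismatches))
        cat = (
            "ambiguous" if in_p and in_f
            else "primary" if in_p
            else "foreign" if in_f
            else "neither"
        )
        counts[cat] += 1
        rows.append((c.sample_id, c.read_id, cat))
    denom = counts["primary"] + counts["foreign"]
    rate = counts["foreign"] / denom if denom else 0.0
    table = pd.DataFrame(rows, columns=["sample_id", "read_id", "assignment"])
    return rate, counts, table


def chimera_rate_summary(
    chimeras_by_sample: dict[str, list[Chimera]],
    unique_totals: dict[str, int],
    ligase_status: dict[str, bool],
) -> pd.DataFrame:
    """Per-sample miR-first/miR-last fractions of unique reads, by ligase status.

    Chimeras are deduplicated by (read_id, orientation) within a sample; an
    overall plus/no-ligase enrichment ratio per orientation is attached as
    DataFrame attrs.
    """
    rows = []
    for sample, chims in chimeras_by_sample.items():
        total = unique_totals.get(sample, 0)
        if total == 0:
            continue
        for orient in ("miR_first", "miR_last"):
            n = len({(c.read_id, c.orientation) for c in chims if c.orientation == orient})
            rows.append((sample, ligase_status[sample], orient, n, total, n / total))
    df = pd.DataFrame(
        rows, columns=["sample_id", "ligase_treated", "orientation", "n", "total", "fraction"]
    )
    ratios = {}
    for orient in ("miR_first", "miR_last"):
        plus = df[(df.orientation == orient) & df.ligase_treated].fraction.mean()
        minus = df[(df.orientation == orient) & ~df.ligase_treated].fraction.mean()
        ratios[orient] = plus / minus if minus and minus > 0 else float("nan")
    df.attrs["plus_over_no_ligase"] = ratios
    return df


def detect_chimeras(
    reads_by_sample: dict[str, list[SequenceRecord]],
    catalog: MiRNACatalog,
    params: MappingParams | None = None,
    min_flank: int = 18,
    rng_seed: int = 0,
    ligase_status: dict[str, bool] | None = None,
) -> tuple[list[Chimera], list[MiRNAHit]]:
    """Run miRNA search + flank extraction over demultiplexed, collapsed reads."""
    params = params or MappingParams()
    seed_index = build_seed_index(catalog, params.seed_mismatches)
    chimeras: list[Chimera] = []
    hits: list[MiRNAHit] = []
    for sample, reads in reads_by_sample.items():
        ligase = True if ligase_status is None else ligase_status[sample]
        for read in reads:
            if read.sample_id is None:
                read.sample_id = sample
            hit = find_mirna_in_read(read, catalog, params, seed_index)
            if hit is None:
                continue
            hit = resolve_ambiguous(hit, rng_seed)
            hits.append(hit)
            chimeras.extend(extract_flanks(read, hit, min_flank, ligase))
    return chimeras, hits
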