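"""miRNA reverse-mapping, flank extraction and target placement."""

import numpy as np
import pytest

from clipchimera.detect import (GenomeIndex, MappingParams, MiRNACatalog,
                                MiRNAEntry, extract_flanks,
                                filter_mirna_loci, find_mirna_in_read,
                                map_target, resolve_ambiguous)
from clipchimera.detect import Chimera, TargetAlignment
from clipchimera.io import (AnnotationRecord, GenomeRef, RegionAnnotation,
                            SequenceRecord, revcomp)

BASES = list("ACGT")


def _rand(rng, n):
    return "".join(rng.choice(BASES, n))


def test_exact_mirna_with_flank(catalog):
    m = catalog.by_id["miR-c"].sequence
    rng = np.random.default_rng(0)
    read = SequenceRecord("r", m + _rand(rng, 30))
    hit = find_mirna_in_read(read, catalog)
    assert hit.mirna_id == "miR-c"
    assert hit.read_span == (0, 22) and hit.truncation_3p == 0


def test_truncation_mode_records_missing_3p(catalog):
    m = catalog.by_id["miR-c"].sequence
    read = SequenceRecord("r", m[:12] + "CCCCCCCCCCCCCCCCCCCCCC")
    assert find_mirna_in_read(read, catalog) is None  # full-length mode
    hit = find_mirna_in_read(
        read, catalog, MappingParams(truncation_mode=True, min_prefix=12))
    assert hit is not None and hit.truncation_3p == len(m) - hit.read_span[1]
    assert hit.read_span[1] - hit.read_span[0] >= 12


def _oracle_scan(read_seq, catalog, params):
    """Exhaustive sliding-window Hamming oracle for the hit contract."""
    best = None
    for e in catalog.entries:
        L = len(e.sequence)
        for start in range(len(read_seq) - 7):
            if start + 8 > len(read_seq):
                break
            seed_mm = sum(read_seq[start + k] != e.sequence[k] for k in range(8))
            if seed_mm > params.seed_mismatches:
                continue
            if not params.truncation_mode:
                if start + L > len(read_seq):
                    continue
                ext_mm = sum(read_seq[start + k] != e.sequence[k]
                             for k in range(8, L))
                if ext_mm > params.ext_mismatches:
                    continue
                key = (seed_mm + ext_mm, -L, start)
            else:
                span = 8
                mm = 0
                k = 8
                while start + k < len(read_seq) and k < L:
                    if read_seq[start + k] == e.sequence[k]:
                        span = k + 1
                    else:
                        mm += 1
                        if mm > params.ext_mismatches:
                            break
                    k += 1
                if span < params.min_prefix:
                    continue
                trailing = sum(read_seq[start + k] != e.sequence[k]
                               for k in range(8, span))
                key = (seed_mm + trailing, -span, start)
            if best is None or key < best[0]:
                best = (key, {e.mirna_id})
            elif key == best[0]:
                best[1].add(e.mirna_id)
    return best


@pytest.mark.parametrize("truncation", [False, True])
def test_detection_matches_bruteforce_oracle(catalog, truncation):
    rng = np.random.default_rng(42)
    params = MappingParams(truncation_mode=truncation)
    n_hits = 0
    for trial in range(400):
        seq = _rand(rng, rng.integers(30, 60))
        if trial % 2 == 0:  # plant a (possibly mutated) miRNA
            e = catalog.entries[rng.integers(0, len(catalog.entries))]
            m = list(e.sequence)
            for _ in range(rng.integers(0, 3)):
                m[rng.integers(0, len(m))] = BASES[rng.integers(0, 4)]
            pos = rng.integers(0, max(len(seq) - len(m), 1))
            seq = seq[:pos] + "".join(m) + seq[pos + len(m):]
        hit = find_mirna_in_read(SequenceRecord("r", seq), catalog, params)
        oracle = _oracle_scan(seq, catalog, params)
        if oracle is None:
            assert hit is None
        else:
            assert hit is not None
            n_hits += 1
            assert hit.candidate_ids == frozenset(oracle[1])
            (mm, neg_span, start) = oracle[0]
            assert hit.read_span[0] == start
            assert len(hit.mismatch_positions) == mm
    assert n_hits > 50  # the comparison actually exercised planted hits


def test_strict_hits_subset_of_default(catalog):
    rng = np.random.default_rng(7)
    strict = MappingParams(seed_mismatches=0, ext_mismatches=0)
    for _ in range(200):
        e = catalog.entries[rng.integers(0, len(catalog.entries))]
        m = list(e.sequence)
        if rng.random() < 0.5:
            m[rng.integers(0, len(m))] = BASES[rng.integers(0, 4)]
        seq = _rand(rng, 10) + "".join(m) + _rand(rng, 10)
        read = SequenceRecord("r", seq)
        if find_mirna_in_read(read, catalog, strict) is not None:
            assert find_mirna_in_read(read, catalog) is not None


def test_resolve_ambiguous_deterministic_and_balanced(catalog):
    # family members share their first 12 nt: a read carrying only that
    # shared prefix cannot distinguish them in truncation mode
    a = catalog.by_id["miR-a"].sequence
    b = catalog.by_id["miR-b"].sequence
    tail = "".join(next(x for x in BASES if x not in (a[k], b[k]))
                   for k in range(12, len(a)))
    body = a[:12] + tail
    params = MappingParams(truncation_mode=True, min_prefix=12)
    counts = {"miR-a": 0, "miR-b": 0}
    n = 10_000
    hit0 = find_mirna_in_read(SequenceRecord("probe", body), catalog, params)
    assert hit0 is not None and hit0.candidate_ids == frozenset({"miR-a", "miR-b"})
    for i in range(n):
        hit = find_mirna_in_read(SequenceRecord(f"r{i}", body), catalog, params)
        chosen = resolve_ambiguous(hit, rng_seed=5)
        assert chosen.mirna_id == resolve_ambiguous(hit, rng_seed=5).mirna_id
        counts[chosen.mirna_id] += 1
    for mid, c in counts.items():
        assert abs(c / n - 0.5) < 0.02, (mid, c)


def test_extract_flanks_thresholds(catalog):
    m = catalog.by_id["miR-c"].sequence
    rng = np.random.default_rng(3)
    f5, f3 = _rand(rng, 20), _rand(rng, 19)
    read = SequenceRecord("r", f5 + m + f3, sample_id="s")
    hit = find_mirna_in_read(read, catalog)
    chims = extract_flanks(read, hit)
    assert {c.orientation for c in chims} == {"miR_first", "miR_last"}
    by = {c.orientation: c for c in chims}
    assert by["miR_last"].target_fragment == f5
    assert by["miR_first"].target_fragment == f3
    # 17-nt flank is below the 18-nt minimum
    read2 = SequenceRecord("r2", m + f3[:17])
    hit2 = find_mirna_in_read(read2, catalog)
    assert extract_flanks(read2, hit2) == []
    # chimera fragments re-inserted at the read span reconstruct the read
    s, e = hit.read_span
    assert by["miR_last"].target_fragment + read.sequence[s:e] + \
        by["miR_first"].target_fragment == read.sequence


def _chim(frag):
    return Chimera("r", "s", "miR-x", "miR_first", frag)


def test_map_target_unique_multi_and_reverse():
    rng = np.random.default_rng(9)
    seq = _rand(rng, 4000)
    dup = seq[100:130]
    genome = GenomeRef({"chr1": seq + dup})  # duplicate 30-mer at two loci
    idx = GenomeIndex(genome)
    aln = map_target(_chim(seq[500:530]), idx)
    assert isinstance(aln, TargetAlignment)
    assert (aln.chrom, aln.start, aln.end, aln.strand) == ("chr1", 500, 530, "+")
    assert map_target(_chim(dup), idx) == "multi_mapped"
    rc = map_target(_chim(revcomp(seq[900:930])), idx)
    assert rc.strand == "-" and rc.start == 900
    assert map_target(_chim("A" * 30), idx) == "unmapped"


def test_map_target_recovers_planted_mutated_fragments():
    rng = np.random.default_rng(10)
    genome = GenomeRef({"chr1": _rand(rng, 20000), "chr2": _rand(rng, 15000)})
    idx = GenomeIndex(genome)
    recovered = 0
    n = 100
    for _ in range(n):
        chrom = "chr1" if rng.random() < 0.5 else "chr2"
        L = int(rng.integers(25, 45))
        start = int(rng.integers(0, len(genome.chroms[chrom]) - L))
        frag = list(genome.chroms[chrom][start:start + L])
        for _ in range(rng.integers(0, 3)):
            frag[rng.integers(0, L)] = BASES[rng.integers(0, 4)]
        aln = map_target(_chim("".join(frag)), idx)
        if isinstance(aln, TargetAlignment) and aln.chrom == chrom \
                and aln.start == start:
            recovered += 1
    assert recovered >= 0.95 * n


def test_filter_mirna_loci_halfopen_boundary():
    ann = RegionAnnotation([
        AnnotationRecord("chr1", 100, 160, "+", "mirna_locus", "mirg0"),
    ])
    inside = TargetAlignment(_chim("A" * 20), "chr1", 150, 170, "+", 0)
    past = TargetAlignment(_chim("A" * 20), "chr1", 160, 180, "+", 0)
    minus = TargetAlignment(_chim("A" * 20), "chr1", 120, 140, "-", 0)
    kept = filter_mirna_loci([inside, past, minus], ann)
    assert kept == [past]
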