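"""Sequence, genome, annotation and sample-sheet I/O plus raw-read preprocessing.

Reads are carried as :class:`SequenceRecord` objects with DNA-normalized
sequences (U -> T, upper-cased) and a flag remembering whether the source
used the RNA alphabet.  Preprocessing covers index-based demultiplexing,
3'-adapter trimming and PCR-duplicate collapsing; each stage reports exact
read accounting so that reads-in always equals reads-out plus drops.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

REGION_LABELS = (
    "five_prime_utr",
    "cds",
    "three_prime_utr",
    "intron",
    "noncoding",
    "mirna_locus",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when an input file does not parse in the declared format."""


@dataclass
class SequenceRecord:
    id: str
    sequence: str
    quality: list[int] | None = None
    sample_id: str | None = None
    is_rna: bool = False
    count: int = 1

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )


def _normalize(seq: str) -> tuple[str, bool]:
    s = seq.upper()
    is_rna = "U" in s
    if is_rna:
        s = s.replace("U", "T")
    return s, is_rna


def read_sequences(path, fmt: str):
    """Yield :class:`SequenceRecord` from a FASTA or FASTQ file, in file order."""
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    i = 0
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
            seq, is_rna = _normalize(str(rec.seq))
            qual = None
            if fmt == "fastq":
                qual = list(rec.letter_annotations["phred_quality"])
            yield SequenceRecord(id=rec.id, sequence=seq, quality=qual, is_rna=is_rna)
    except ValueError as exc:
        # Biopython reports the offending record; add the file for context.
        raise ParseError(f"{path}: malformed {fmt} record ~#{i + 1}: {exc}") from exc


def write_sequences(records, path, fmt: str) -> int:
    """Write records as FASTA/FASTQ.  RNA-flagged records are written back as RNA."""
    out = []
    for r in records:
        seq = r.sequence.replace("T", "U") if r.is_rna else r.sequence
        rec = SeqRecord(Seq(seq), id=r.id, description="")
        if fmt == "fastq":
            if r.quality is None:
                raise ValueError(f"record {r.id!r} has no quality scores")
            rec.letter_annotations["phred_quality"] = list(r.quality)
        out.append(rec)
    return SeqIO.write(out, str(path), fmt)


@dataclass(frozen=True)
class Sample:
    sample_id: str
    index: str
    ligase_treated: bool
    species_tag: str = ""


@dataclass
class SampleSheet:
    samples: list[Sample]

    def __post_init__(self) -> None:
        indices = [s.index for s in self.samples]
        if len(set(indices)) != len(indices):
            raise ValueError("sample indices are not unique across samples")
        for s in self.samples:
            if not s.index:
                raise ValueError(f"sample {s.sample_id!r} has an empty index")

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample_id", "index", "ligase_treated"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"{path}: sample sheet missing columns {sorted(missing)}")
        samples = [
            Sample(
                sample_id=row.sample_id,
                index=row.index.upper(),
                ligase_treated=str(row.ligase_treated).lower() in ("1", "true", "yes"),
                species_tag=getattr(row, "species_tag", "") or "",
            )
            for row in df.itertuples(index=False)
        ]
        return cls(samples)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [
                (s.sample_id, s.index, s.ligase_treated, s.species_tag)
                for s in self.samples
            ],
            columns=["sample_id", "index", "ligase_treated", "species_tag"],
        ).to_csv(path, sep="\t", index=False)


@dataclass
class GenomeRef:
    """Named chromosome sequences, uppercase DNA."""

    chroms: dict[str, str]

    def __post_init__(self) -> None:
        self.chroms = {name: seq.upper() for name, seq in self.chroms.items()}

    @classmethod
    def from_fasta(cls, path) -> "GenomeRef":
        chroms: dict[str, str] = {}
        for rec in read_sequences(path, "fasta"):
            if rec.id in chroms:
                raise ParseError(f"{path}: duplicate chromosome name {rec.id!r}")
            chroms[rec.id] = rec.sequence
        return cls(chroms)

    def to_fasta(self, path) -> None:
        write_sequences(
            (SequenceRecord(id=n, sequence=s) for n, s in self.chroms.items()),
            path,
            "fasta",
        )

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.chroms[chrom][max(start, 0) : end]
        return revcomp(seq) if strand == "-" else seq

    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.chroms.items()}


@dataclass(frozen=True)
class AnnotationRecord:
    chrom: str
    start: int
    end: int
    strand: str
    region_label: str
    gene_id: str
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.region_label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.region_label!r}")


@dataclass
class RegionAnnotation:
    records: list[AnnotationRecord]

    @classmethod
    def from_bed(cls, path) -> "RegionAnnotation":
        """BED-like table: chrom start end name(label|gene|transcript) score strand."""
        recs = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ParseError(f"{path}:{ln}: expected >=6 BED columns")
                name = parts[3].split("|")
                recs.append(
                    AnnotationRecord(
                        chrom=parts[0],
                        start=int(parts[1]),
                        end=int(parts[2]),
                        strand=parts[5],
                        region_label=name[0],
                        gene_id=name[1] if len(name) > 1 else "",
                        transcript_id=name[2] if len(name) > 2 else "",
                    )
                )
        return cls(recs)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                name = f"{r.region_label}|{r.gene_id}|{r.transcript_id}"
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")


@dataclass
class DemuxResult:
    by_sample: dict[str, list[SequenceRecord]]
    unassigned: int
    dropped_short: int
    total: int = 0

    def assigned(self) -> int:
        return sum(len(v) for v in self.by_sample.values())


def _trim_adapter(seq: str, adapter: str, min_overlap: int) -> str:
    """Remove the 3' adapter at the leftmost qualifying match.

    Full-length adapter occurrences may carry one mismatch; shorter
    suffix-prefix overlaps (>= min_overlap) must be exact.
    """
    alen = len(adapter)
    for p in range(len(seq)):
        overlap = min(alen, len(seq) - p)
        window = seq[p : p + overlap]
        if overlap == alen:
            mm = sum(a != b for a, b in zip(window, adapter))
            if mm <= 1:
                return seq[:p]
        elif overlap >= min_overlap and window == adapter[:overlap]:
            return seq[:p]
    return seq


def demultiplex_and_trim(
    reads,
    sheet: SampleSheet,
    adapter: str,
    min_adapter_overlap: int = 6,
    index_offset: int = 0,
    min_length: int = 18,
) -> DemuxResult:
    """Assign reads to samples by exact index match and trim the 3' adapter.

    The sample index (at ``index_offset`` from the read 5' end) is removed
    from the assigned read; reads shorter than ``min_length`` after adapter
    trimming are dropped and counted.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_adapter_overlap < 1:
        raise ValueError("min_adapter_overlap must be >= 1")
    adapter = _normalize(adapter)[0]
    by_sample: dict[str, list[SequenceRecord]] = {s.sample_id: [] for s in sheet.samples}
    unassigned = 0
    dropped = 0
    total = 0
    for read in reads:
        total += 1
        hit = None
        for s in sheet.samples:
            if read.sequence[index_offset : index_offset + len(s.index)] == s.index:
                hit = s
                break  # indices are unique; at most one exact match
        if hit is None:
            unassigned += 1
            continue
        insert = (
            read.sequence[:index_offset]
            + read.sequence[index_offset + len(hit.index) :]
        )
        qual = None
        if read.quality is not None:
            qual = (
                read.quality[:index_offset]
                + read.quality[index_offset + len(hit.index) :]
            )
        trimmed = _trim_adapter(insert, adapter, min_adapter_overlap)
        if len(trimmed) < min_length:
            dropped += 1
            continue
        by_sample[hit.sample_id].append(
            SequenceRecord(
                id=read.id,
                sequence=trimmed,
                quality=qual[: len(trimmed)] if qual is not None else None,
                sample_id=hit.sample_id,
                is_rna=read.is_rna,
            )
        )
    return DemuxResult(by_sample, unassigned, dropped, total)


def collapse_duplicates(reads) -> list[SequenceRecord]:
    """Collapse identical sequences within a sample into one record with a count."""
    seen: dict[str, SequenceRecord] = {}
    for r in reads:
        prev = seen.get(r.sequence)
        if prev is None:
            seen[r.sequence] = replace(r, count=r.count)
        else:
            prev.count += r.count
    return list(seen.values())


def log_stage(stage: str, **counts) -> None:
    parts = " ".join(f"{k}={v}" for k, v in counts.items())
    print(f"[clipchimera] {stage}: {parts}", file=sys.stderr)
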