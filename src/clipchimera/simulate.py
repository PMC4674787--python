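"""Synthetic CLIP experiments with full ground truth.

The generator emulates the study conditions of a ligation-based AGO CLIP
experiment: a random genome with transcript annotation, a mature-miRNA
catalogue with seed families and divergent 3' ends, planted target sites of
known seed class written into transcript regions, and multiplexed read
libraries containing miR-first/miR-last chimeras (~14:1), a ~10x drop in
chimera rate in no-ligase control samples, 3'-truncated miRNAs (mass at 0
and 1 nt), PCR duplicates, sample indices, a 3' sequencing adapter, cross
species contaminant fragments, non-chimeric background reads (including
pile-ups over planted sites for biological-complexity truth) and a probe
level expression table with per-site-class repression effects.

All outputs are deterministic functions of ``SimConfig.rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import MiRNACatalog, MiRNAEntry
from .io import (AnnotationRecord, GenomeRef, RegionAnnotation, Sample,
                 SampleSheet, SequenceRecord, revcomp)
from .seeds import _CLASS_SPAN, _site_template

ADAPTER = "GTGTCAGTCACTTCCAGCGG"  # 3' sequencing adapter (DNA form)

_BASES = np.array(list("ACGT"))


def _rand_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


@dataclass
class SimConfig:
    rng_seed: int = 0
    # genome / annotation
    n_chromosomes: int = 2
    n_genes: int = 120
    utr5_len: int = 120
    cds_len: int = 400
    intron_len: int = 150
    utr3_len: int = 400
    intergenic_len: int = 200
    n_mirna_loci: int = 4
    # miRNA catalogue
    n_mirnas: int = 18
    n_families: int = 2
    family_size: int = 3
    mirna_len: int = 22
    # planted sites
    n_sites: int = 300
    site_region_mix: dict = field(default_factory=lambda: {
        "three_prime_utr": 0.70, "cds": 0.15, "five_prime_utr": 0.05,
        "intron": 0.10,
    })
    seed_class_mixture: dict = field(default_factory=lambda: {
        "8mer": 0.25, "7mer-m8": 0.20, "7mer-A1": 0.15, "6mer": 0.15,
        "mismatch": 0.10, "bulge": 0.05, "seedless": 0.10,
    })
    max_site_offset: int = 20   # site start downstream of the ligation junction
    # libraries
    n_reads: int = 50_000
    n_ligase_samples: int = 4
    n_noligase_samples: int = 2
    index_len: int = 4
    chimera_fraction: float = 0.03        # miR-first molecules, ligase samples
    mir_first_last_ratio: float = 14.0
    ligase_ratio: float = 10.0            # miR-first drop in no-ligase samples
    truncation_probs: dict = field(default_factory=lambda: {0: 0.85, 1: 0.15})
    flank_len_range: tuple = (30, 45)
    background_len_range: tuple = (20, 40)
    background_site_fraction: float = 0.30  # background reads piling on sites
    background_mirna_fraction: float = 0.20  # pure mature-miRNA reads
    contamination_fraction: float = 0.01
    pcr_duplication_rate: float = 0.2
    # expression model
    probes_per_gene: int = 2
    canonical_effect: float = -0.5
    noncanonical_effect: float = -0.2
    expression_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if abs(sum(self.seed_class_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("seed class mixture must sum to 1")
        site_len = 9 + self.max_site_offset
        if site_len > self.flank_len_range[0]:
            raise ValueError("planted sites cannot exceed the minimum flank")


@dataclass
class SimResult:
    config: SimConfig
    genome: GenomeRef
    foreign_genome: GenomeRef
    annotation: RegionAnnotation
    catalog: MiRNACatalog
    sheet: SampleSheet
    reads_by_sample: dict
    truth_reads: pd.DataFrame
    truth_sites: pd.DataFrame
    expression: pd.DataFrame
    truth_genes: pd.DataFrame

    def write(self, outdir) -> None:
        from pathlib import Path

        from .io import write_sequences

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.genome.to_fasta(out / "genome.fa")
        self.foreign_genome.to_fasta(out / "foreign_genome.fa")
        self.annotation.to_bed(out / "annotation.bed")
        write_sequences(
            (SequenceRecord(e.mirna_id, e.sequence, is_rna=True)
             for e in self.catalog.entries),
            out / "mirnas.fa", "fasta",
        )
        self.sheet.to_tsv(out / "samples.tsv")
        for sample, reads in self.reads_by_sample.items():
            write_sequences(reads, out / f"{sample}.fastq", "fastq")
        self.truth_reads.to_csv(out / "truth_reads.tsv", sep="\t", index=False)
        self.truth_sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
        self.expression.to_csv(out / "expression.tsv", sep="\t", index=False)


def _make_catalog(cfg: SimConfig, rng) -> MiRNACatalog:
    entries = []
    seeds_used = set()
    n_family_mirnas = cfg.n_families * cfg.family_size
    for f in range(cfg.n_families):
        while True:
            base = _rand_seq(rng, cfg.mirna_len)
            if base[1:8] not in seeds_used:
                break
        seeds_used.add(base[1:8])
        for m in range(cfg.family_size):
            # identical first 10 nt (seed + start of central region),
            # divergent 3' ends
            seq = base[:10] + _rand_seq(rng, cfg.mirna_len - 10)
            entries.append(MiRNAEntry(f"miR-F{f + 1}{chr(97 + m)}", seq))
    for i in range(cfg.n_mirnas - n_family_mirnas):
        while True:
            seq = _rand_seq(rng, cfg.mirna_len)
            if seq[1:8] not in seeds_used:
                break
        seeds_used.add(seq[1:8])
        entries.append(MiRNAEntry(f"miR-{i + 1:02d}", seq))
    return MiRNACatalog(entries)


def _make_genome(cfg: SimConfig, rng):
    """Random chromosomes of concatenated genes; all genes on the + strand."""
    chroms: dict[str, list] = {}
    records: list[AnnotationRecord] = []
    gene_regions: dict[str, dict[str, tuple]] = {}
    genes_per_chrom = -(-cfg.n_genes // cfg.n_chromosomes)
    g = 0
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        parts: list[str] = []
        pos = 0
        for _ in range(min(genes_per_chrom, cfg.n_genes - g)):
            gid, tid = f"g{g:03d}", f"t{g:03d}"
            pos += cfg.intergenic_len
            parts.append(_rand_seq(rng, cfg.intergenic_len))
            layout = [
                ("five_prime_utr", cfg.utr5_len),
                ("cds", cfg.cds_len // 2),
                ("intron", cfg.intron_len),
                ("cds", cfg.cds_len - cfg.cds_len // 2),
                ("three_prime_utr", cfg.utr3_len),
            ]
            regions = {}
            for label, length in layout:
                records.append(
                    AnnotationRecord(chrom, pos, pos + length, "+", label, gid, tid)
                )
                regions.setdefault(label, []).append((pos, pos + length))
                parts.append(_rand_seq(rng, length))
                pos += length
            gene_regions[gid] = {"chrom": chrom, "regions": regions}
            g += 1
        pos += cfg.intergenic_len
        parts.append(_rand_seq(rng, cfg.intergenic_len))
        chroms[chrom] = parts
    genome = {c: "".join(p) for c, p in chroms.items()}
    return genome, records, gene_regions


def _build_site(cfg, rng, mirna: MiRNAEntry, klass: str):
    """Site sequence for a planted seed class, plus normalized truth label."""
    if klass in ("8mer", "7mer-m8", "7mer-A1", "6mer"):
        site, _ = _site_template(mirna.sequence, klass)
        return site, klass, None
    if klass == "mismatch":
        cls = ["8mer", "7mer-m8", "6mer"][rng.integers(0, 3)]
        site, pos_map = _site_template(mirna.sequence, cls)
        lo, hi = _CLASS_SPAN[cls]
        mpos = int(rng.integers(3, min(hi, 7) + 1))  # interior, breaks all 6mers
        i = pos_map.index(mpos)
        wc = site[i]
        mi = mirna.sequence[mpos - 1]
        choices = [b for b in "ACGT" if b != wc and (mi, b) not in (("G", "T"), ("T", "G"))]
        b = choices[rng.integers(0, len(choices))]
        label = {"8mer": "mm8", "7mer-m8": "mm7", "6mer": "mm6"}[cls]
        return site[:i] + b + site[i + 1 :], label, mpos
    if klass == "bulge":
        site, pos_map = _site_template(mirna.sequence, "8mer")
        left = int(rng.integers(3, 7))  # insertion between positions left/left+1
        i = pos_map.index(left)
        b = "ACGT"[rng.integers(0, 4)]
        return site[:i] + b + site[i:], "bulge_target_8mer", left
    if klass == "seedless":
        # 3'-end complementarity only (positions 13-20)
        return revcomp(mirna.sequence[12:20]), "none", None
    raise ValueError(f"unknown planted class {klass!r}")


def _foreign_genome(cfg: SimConfig, rng, primary: dict) -> GenomeRef:
    """A contaminant genome sharing no exact 20-mer with the primary one."""
    k = 20
    primary_kmers = set()
    for seq in primary.values():
        for i in range(len(seq) - k + 1):
            primary_kmers.add(seq[i : i + k])
    size = sum(len(s) for s in primary.values()) // 3
    while True:
        seq = _rand_seq(rng, size)
        if all(seq[i : i + k] not in primary_kmers for i in range(len(seq) - k + 1)):
            return GenomeRef({"fchr1": seq})


def simulate_experiment(cfg: SimConfig | None = None) -> SimResult:
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    catalog = _make_catalog(cfg, rng)
    genome_dict, ann_records, gene_regions = _make_genome(cfg, rng)

    # plant target sites (mutating chromosome strings in place)
    chrom_arrays = {c: list(s) for c, s in genome_dict.items()}
    region_labels = list(cfg.site_region_mix)
    region_probs = np.array([cfg.site_region_mix[r] for r in region_labels])
    region_probs = region_probs / region_probs.sum()
    class_labels = list(cfg.seed_class_mixture)
    class_probs = np.array([cfg.seed_class_mixture[c] for c in class_labels])
    mirna_weights = rng.dirichlet(np.ones(len(catalog.entries)) * 2.0)
    gene_ids = sorted(gene_regions)
    site_rows = []
    used: dict[tuple, list] = {}
    site_id = 0
    attempts = 0
    while site_id < cfg.n_sites and attempts < cfg.n_sites * 20:
        attempts += 1
        gid = gene_ids[rng.integers(0, len(gene_ids))]
        label = region_labels[int(rng.choice(len(region_labels), p=region_probs))]
        info = gene_regions[gid]
        if label not in info["regions"]:
            continue
        rstart, rend = info["regions"][label][0]
        mirna = catalog.entries[int(rng.choice(len(catalog.entries), p=mirna_weights))]
        klass = class_labels[int(rng.choice(len(class_labels), p=class_probs))]
        offset = int(rng.integers(2, cfg.max_site_offset + 1))
        max_flank = cfg.flank_len_range[1]
        lo = rstart + offset
        hi = rend - max_flank
        if hi <= lo:
            continue
        junction = int(rng.integers(lo - offset, hi - offset))
        # keep planted sites well separated
        taken = used.setdefault(info["chrom"], [])
        if any(abs(junction - j) < 120 for j in taken):
            continue
        site_seq, truth_label, edit_pos = _build_site(cfg, rng, mirna, klass)
        pos = junction + offset
        arr = chrom_arrays[info["chrom"]]
        arr[pos : pos + len(site_seq)] = list(site_seq)
        # guard bases so the flanking genome cannot upgrade the planted
        # class (e.g. a chance A after a 7mer-m8 would make it an 8mer)
        m8 = mirna.sequence[7]
        arr[pos - 1] = next(b for b in "CAGT"
                            if b != revcomp(m8)
                            and (m8, b) not in (("G", "T"), ("T", "G")))
        arr[pos + len(site_seq)] = "C"
        taken.append(junction)
        site_rows.append({
            "site_id": f"s{site_id:04d}", "gene_id": gid,
            "chrom": info["chrom"], "pos": pos, "junction": junction,
            "offset": offset, "mirna_id": mirna.mirna_id,
            "planted_class": klass, "truth_class": truth_label,
            "edit_position": edit_pos, "region_label": label,
        })
        site_id += 1
    truth_sites = pd.DataFrame(site_rows)
    genome = GenomeRef({c: "".join(a) for c, a in chrom_arrays.items()})

    # miRNA loci in terminal intergenic space, for locus filtering
    loci = []
    for i in range(min(cfg.n_mirna_loci, len(catalog.entries))):
        chrom = sorted(genome.chroms)[i % cfg.n_chromosomes]
        end = len(genome.chroms[chrom]) - 10 - (i // cfg.n_chromosomes) * 70
        loci.append(AnnotationRecord(chrom, end - 60, end, "+", "mirna_locus",
                                     f"mirg{i}", ""))
    annotation = RegionAnnotation(ann_records + loci)
    foreign = _foreign_genome(cfg, rng, genome.chroms)

    samples = [
        Sample(f"lig{i + 1}", _unique_index(rng, cfg.index_len, i), True)
        for i in range(cfg.n_ligase_samples)
    ] + [
        Sample(f"nolig{i + 1}",
               _unique_index(rng, cfg.index_len, cfg.n_ligase_samples + i), False)
        for i in range(cfg.n_noligase_samples)
    ]
    sheet = SampleSheet(samples)

    n_samples = len(samples)
    per_sample = cfg.n_reads // n_samples
    reads_by_sample: dict[str, list[SequenceRecord]] = {}
    truth_rows = []
    sites_by_mirna: dict[str, list[int]] = {}
    for i, row in truth_sites.iterrows():
        sites_by_mirna.setdefault(row.mirna_id, []).append(i)

    def draw_site(rng):
        mirna = catalog.entries[int(rng.choice(len(catalog.entries), p=mirna_weights))]
        rows = sites_by_mirna.get(mirna.mirna_id)
        if not rows:
            return None
        return truth_sites.iloc[rows[rng.integers(0, len(rows))]]

    trunc_vals = np.array(sorted(cfg.truncation_probs))
    trunc_probs = np.array([cfg.truncation_probs[v] for v in trunc_vals], dtype=float)
    trunc_probs /= trunc_probs.sum()

    for sample in samples:
        reads: list[SequenceRecord] = []
        mol = 0
        first_rate = cfg.chimera_fraction
        if not sample.ligase_treated:
            first_rate /= cfg.ligase_ratio
        last_rate = cfg.chimera_fraction / cfg.mir_first_last_ratio
        while len(reads) < per_sample:
            mol_id = f"{sample.sample_id}:m{mol:06d}"
            mol += 1
            u = rng.random()
            category, mirna_id, orientation = "background_genomic", "", ""
            insert = ""
            truncation = 0
            site_ref = ""
            flank_len = 0
            if u < first_rate or (first_rate <= u < first_rate + last_rate):
                orientation = "miR_first" if u < first_rate else "miR_last"
                site = draw_site(rng)
                if site is None:
                    continue
                mirna = catalog.by_id[site.mirna_id]
                truncation = int(trunc_vals[int(rng.choice(len(trunc_vals),
                                                           p=trunc_probs))])
                mseq = mirna.sequence[: len(mirna.sequence) - truncation]
                flank_len = int(rng.integers(*cfg.flank_len_range))
                if rng.random() < cfg.contamination_fraction:
                    category = "contaminant_chimera"
                    fstart = int(rng.integers(0, len(foreign.chroms["fchr1"]) - flank_len))
                    frag = foreign.chroms["fchr1"][fstart : fstart + flank_len]
                else:
                    category = "chimera"
                    frag = genome.chroms[site.chrom][site.junction : site.junction + flank_len]
                    site_ref = site.site_id
                mirna_id = mirna.mirna_id
                insert = mseq + frag if orientation == "miR_first" else frag + mseq
            else:
                v = rng.random()
                if v < cfg.background_mirna_fraction:
                    category = "background_mirna"
                    e = catalog.entries[int(rng.choice(len(catalog.entries),
                                                       p=mirna_weights))]
                    mirna_id = e.mirna_id
                    insert = e.sequence
                elif v < cfg.background_mirna_fraction + cfg.background_site_fraction:
                    category = "background_target"
                    site = draw_site(rng)
                    if site is None:
                        continue
                    length = int(rng.integers(*cfg.background_len_range))
                    start = site.junction - int(rng.integers(0, 10))
                    frag = genome.chroms[site.chrom][max(start, 0): max(start, 0) + length]
                    insert = frag
                    site_ref = site.site_id
                else:
                    category = "background_genomic"
                    chrom = sorted(genome.chroms)[rng.integers(0, cfg.n_chromosomes)]
                    length = int(rng.integers(*cfg.background_len_range))
                    start = int(rng.integers(0, len(genome.chroms[chrom]) - length))
                    insert = genome.chroms[chrom][start : start + length]
            copies = 1
            while rng.random() < cfg.pcr_duplication_rate:
                copies += 1
            for _ in range(copies):
                if len(reads) >= per_sample:
                    break
                rid = f"{sample.sample_id}:r{len(reads):06d}"
                seq = sample.index + insert + ADAPTER
                reads.append(SequenceRecord(rid, seq, quality=[30] * len(seq)))
                truth_rows.append({
                    "read_id": rid, "sample_id": sample.sample_id,
                    "molecule_id": mol_id, "category": category,
                    "mirna_id": mirna_id, "orientation": orientation,
                    "truncation": truncation, "flank_len": flank_len,
                    "site_id": site_ref,
                    "ligase_treated": sample.ligase_treated,
                })
        reads_by_sample[sample.sample_id] = reads

    truth_reads = pd.DataFrame(truth_rows)
    expression, truth_genes = _simulate_expression(cfg, rng, truth_sites, gene_ids)
    return SimResult(cfg, genome, foreign, annotation, catalog, sheet,
                     reads_by_sample, truth_reads, truth_sites, expression,
                     truth_genes)


def _unique_index(rng, length: int, ordinal: int) -> str:
    """Deterministic distinct sample indices (Hamming-separated by design)."""
    alphabet = "ACGT"
    digits = []
    x = ordinal
    for _ in range(length):
        digits.append(alphabet[x % 4])
        x //= 4
    # prefix with a rotating base to avoid all-A collisions with inserts
    return "".join(digits[::-1])


def _simulate_expression(cfg, rng, truth_sites, gene_ids):
    canonical = {"8mer", "7mer-m8", "7mer-A1", "6mer"}
    effects = {}
    for _, row in truth_sites.iterrows():
        if row.planted_class in canonical:
            effects[row.gene_id] = min(effects.get(row.gene_id, 0.0),
                                       cfg.canonical_effect)
        elif row.planted_class in ("mismatch", "bulge", "seedless"):
            effects.setdefault(row.gene_id, 0.0)
            if effects[row.gene_id] == 0.0:
                effects[row.gene_id] = cfg.noncanonical_effect
    rows = []
    gene_rows = []
    for gid in gene_ids:
        mu = effects.get(gid, 0.0)
        gene_rows.append({"gene_id": gid, "planted_log2fc": mu})
        for p in range(cfg.probes_per_gene):
            rows.append({
                "gene_id": gid, "probe_id": f"{gid}_p{p}",
                "log2fc": mu + rng.normal(0, cfg.expression_noise_sd),
            })
    return pd.DataFrame(rows), pd.DataFrame(gene_rows)


def simulate_expression_groups(
    n_canonical: int = 60,
    n_noncanonical: int = 60,
    n_control: int = 150,
    canonical_effect: float = -0.5,
    noncanonical_effect: float = -0.2,
    noise_sd: float = 0.25,
    probes_per_gene: int = 2,
    rng_seed: int = 0,
):
    """Probe-level expression table with planted per-site-class repression.

    Returns (probe table, gene sets by class) for perturbation-response
    statistics; effects are the per-class log2FC shifts of the expression
    model, zero for control genes.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    sets: dict[str, set] = {"canonical": set(), "noncanonical": set(),
                            "control": set()}
    spec_list = [("canonical", n_canonical, canonical_effect),
                 ("noncanonical", n_noncanonical, noncanonical_effect),
                 ("control", n_control, 0.0)]
    g = 0
    for name, count, mu in spec_list:
        for _ in range(count):
            gid = f"g{g:04d}"
            g += 1
            sets[name].add(gid)
            for p in range(probes_per_gene):
                rows.append({"gene_id": gid, "probe_id": f"{gid}_p{p}",
                             "log2fc": mu + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows), sets


# ---------------------------------------------------------------------------
# planted binding-mode archetypes (pairing-profile space)

def default_archetypes(n_positions: int = 21) -> np.ndarray:
    """Six binding-mode archetypes over miRNA positions 2..(n_positions+1).

    Mirrors the qualitative modes seen in chimera structure maps: seed-only,
    seed + 3' supplementary, seed + long 3' pairing, seedless 3'-only,
    seed + bipartite and seed + tripartite auxiliary patterns.
    """
    def prof(*spans):
        v = np.zeros(n_positions)
        for lo, hi in spans:  # miRNA positions, inclusive
            v[lo - 2 : hi - 1] = 1
        return v

    return np.vstack([
        prof((2, 8)),
        prof((2, 8), (13, 17)),
        prof((2, 8), (11, 21)),
        prof((13, 20)),
        prof((2, 8), (10, 13), (17, 21)),
        prof((2, 8), (9, 11), (13, 15), (18, 20)),
    ])


def simulate_pairing_matrix(
    n_rows: int = 3000,
    archetypes: np.ndarray | None = None,
    noise: float = 0.10,
    rng_seed: int = 0,
):
    """Binary pairing vectors drawn from planted archetypes with bit-flip noise.

    Returns (matrix, labels, archetypes); rows are archetype profiles with
    each bit flipped independently with probability ``noise``.
    """
    archetypes = default_archetypes() if archetypes is None else archetypes
    rng = np.random.default_rng(rng_seed)
    labels = rng.integers(0, len(archetypes), n_rows)
    mat = archetypes[labels].astype(float)
    flips = rng.random(mat.shape) < noise
    mat[flips] = 1.0 - mat[flips]
    return mat, labels, archetypes


# ---------------------------------------------------------------------------
# truth evaluation

def evaluate_detection(chimeras, truth_reads: pd.DataFrame) -> dict:
    """Precision/recall of chimera detection against generator truth.

    Evaluation is at the unique-molecule level (PCR duplicates collapse to
    one representative read, so read-level recall is ill-posed by design).
    Recall is reported for the well-posed subset (full-length miRNA, flank
    >= 18 nt); ``false_calls_nonmirna`` counts chimera calls on molecules
    generated without any miRNA content.
    """
    rid2mol = dict(zip(truth_reads.read_id, truth_reads.molecule_id))
    mols = truth_reads.drop_duplicates("molecule_id").set_index("molecule_id")
    detected = {(rid2mol[c.read_id], c.orientation)
                for c in chimeras if c.read_id in rid2mol}
    det_mols = {m for m, _ in detected}
    nonmir = set(mols[mols.category.isin(
        ["background_target", "background_genomic"])].index)
    out = {"false_calls_nonmirna": len(det_mols & nonmir)}
    tp = sum(mols.loc[m, "orientation"] == o for m, o in detected)
    out["precision"] = tp / len(detected) if detected else float("nan")
    chim = mols[mols.category.isin(["chimera", "contaminant_chimera"])]
    for orient in ("miR_first", "miR_last"):
        well = chim[(chim.orientation == orient)
                    & (chim.truncation == 0) & (chim.flank_len >= 18)]
        got = sum((m, orient) in detected for m in well.index)
        out[f"recall_{orient}"] = got / len(well) if len(well) else float("nan")
    ligset = set(mols[mols.ligase_treated].index)
    nf = sum(1 for m, o in detected if o == "miR_first" and m in ligset)
    nl = sum(1 for m, o in detected if o == "miR_last" and m in ligset)
    out["detected_first_last_ratio"] = nf / nl if nl else float("inf")
    return out


def seed_class_confusion(predicted: dict, truth_sites: pd.DataFrame):
    """Confusion over planted canonical classes.

    ``predicted`` maps site_id -> classifier class.  Returns the confusion
    table and the diagonal fraction over canonical planted sites.
    """
    canonical = ["8mer", "7mer-m8", "7mer-A1", "6mer"]
    sub = truth_sites[truth_sites.planted_class.isin(canonical)]
    rows = []
    diag = total = 0
    for _, r in sub.iterrows():
        pred = predicted.get(r.site_id)
        if pred is None:
            continue
        rows.append({"truth": r.planted_class, "predicted": pred})
        total += 1
        diag += pred == r.planted_class
    table = pd.DataFrame(rows)
    return table, (diag / total if total else float("nan"))
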