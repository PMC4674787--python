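"""De-novo k-mer motif enrichment with miRNA-complementarity confidence.

For every eligible miRNA, 7-mers (configurable k) are tested for presence
enrichment in that miRNA's chimera target regions against a 5x background
drawn from other miRNAs' regions (same-seed-family miRNAs excluded) with a
one-sided hypergeometric test.  Top candidates are refined into position
frequency matrices from their foreground occurrences (best window within
Hamming distance 1 per region, exact occurrences preferred), scored for
complementarity to the cognate miRNA (s in [0, 1]: the PFM's mean
per-column probability of the miRNA's reverse-complement base at the best
ungapped offset), and combined into the confidence statistic

    c = (-log10(p) - 10) / 10 + (s - 0.35) * 6.7

Motifs are retained when s >= 0.35, information content per bp >= 1.75 bits
and c >= 1; with three independent background draws a motif is reported
robust when retained in at least two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import revcomp

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def _kmer_presence(regions: list[str], k: int) -> np.ndarray:
    """Presence (0/1) of each of the 4^k k-mers per region, summed over regions."""
    counts = np.zeros(4 << (2 * (k - 1)), dtype=np.int64)
    for seq in regions:
        codes = np.array([_CODE.get(c, -1) for c in seq], dtype=np.int64)
        seen = set()
        for i in range(len(codes) - k + 1):
            window = codes[i : i + k]
            if (window < 0).any():
                continue
            key = 0
            for c in window:
                key = (key << 2) | int(c)
            seen.add(key)
        for key in seen:
            counts[key] += 1
    return counts


def _kmer_string(key: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[key & 3])
        key >>= 2
    return "".join(reversed(out))


@dataclass
class MotifResult:
    mirna_id: str
    consensus: str
    pfm: np.ndarray              # (k, 4) column probabilities
    p: float
    s: float = 0.0
    matched_offset: int = 0      # 1-based miRNA position of the 5'-most complemented base
    ic_per_bp: float = 0.0
    c: float = float("-inf")
    fg_fraction: float = 0.0
    retained: bool = False
    draws_retained: int = 0


def build_fg_bg(
    regions_by_mirna: dict[str, list[str]],
    families: dict[str, str],
    chimera_counts: dict[str, int] | None = None,
    min_chimeras: int = 50,
    min_sites: int = 40,
    bg_factor: int = 5,
    n_draws: int = 3,
    rng_seed: int = 0,
):
    """Foreground/background region sets per eligible miRNA.

    Eligibility: >= min_chimeras individual chimeras and >= min_sites
    distinct sites.  Background: ``bg_factor`` x |foreground| regions sampled
    without replacement from other miRNAs' regions, excluding miRNAs in the
    same seed family; ``n_draws`` independent draws are produced.
    """
    rng = np.random.default_rng(rng_seed)
    out = {}
    for mid, regions in sorted(regions_by_mirna.items()):
        n_chim = chimera_counts.get(mid, len(regions)) if chimera_counts else len(regions)
        if n_chim < min_chimeras or len(regions) < min_sites:
            continue
        fam = families.get(mid)
        pool = [
            r
            for other, regs in sorted(regions_by_mirna.items())
            if other != mid and families.get(other) != fam
            for r in regs
        ]
        need = bg_factor * len(regions)
        if len(pool) < need:
            raise ValueError(
                f"{mid}: background pool has {len(pool)} regions, need {need}"
            )
        draws = [
            [pool[i] for i in rng.choice(len(pool), size=need, replace=False)]
            for _ in range(n_draws)
        ]
        out[mid] = (list(regions), draws)
    return out


def enriched_kmers(
    foreground: list[str],
    background: list[str],
    k: int = 7,
    top_n: int = 25,
    min_fg_fraction: float = 0.10,
) -> list[tuple[str, float, int]]:
    """Candidate enriched k-mers as (kmer, p, fg_presence_count).

    One-sided hypergeometric enrichment of per-region presence, ranked by p;
    candidates within Hamming distance 1 or a single-offset shift of a
    higher-ranked candidate are suppressed; at most ``top_n`` returned.
    """
    if not foreground or not background:
        raise ValueError("foreground and background must be non-empty")
    fg = _kmer_presence(foreground, k)
    bg = _kmer_presence(background, k)
    n_fg, n_bg = len(foreground), len(background)
    K = fg + bg
    with np.errstate(divide="ignore"):
        p = stats.hypergeom.sf(fg - 1, n_fg + n_bg, K, n_fg)
    min_hits = max(2, math.ceil(min_fg_fraction * n_fg))
    cand = np.where(fg >= min_hits)[0]
    cand = cand[np.lexsort((-fg[cand], p[cand]))]
    chosen: list[tuple[str, float, int]] = []

    def redundant(kmer: str) -> bool:
        for prev, _, _ in chosen:
            if sum(a != b for a, b in zip(kmer, prev)) <= 1:
                return True
            if kmer[1:] == prev[:-1] or prev[1:] == kmer[:-1]:
                return True
        return False

    for key in cand:
        kmer = _kmer_string(int(key), k)
        if redundant(kmer):
            continue
        chosen.append((kmer, float(p[key]), int(fg[key])))
        if len(chosen) >= top_n:
            break
    return chosen


def refine_pfm(consensus: str, foreground: list[str]) -> tuple[np.ndarray, float]:
    """PFM from the best occurrence (exact else Hamming-1, leftmost) per region.

    Returns (column-probability matrix, fraction of foreground regions with
    an occurrence).
    """
    k = len(consensus)
    counts = np.zeros((k, 4))
    n_occ = 0
    for seq in foreground:
        best = None
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if any(c not in _CODE for c in window):
                continue
            d = sum(a != b for a, b in zip(window, consensus))
            if d <= 1 and (best is None or d < best[0]):
                best = (d, window)
                if d == 0:
                    break
        if best is None:
            continue
        n_occ += 1
        for col, base in enumerate(best[1]):
            counts[col, _CODE[base]] += 1
    if n_occ == 0:
        return np.full((k, 4), 0.25), 0.0
    return counts / n_occ, n_occ / len(foreground)


def information_content(pfm: np.ndarray) -> float:
    """Mean per-column information content in bits (uniform background)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(pfm > 0, np.log2(np.where(pfm > 0, pfm, 1.0)), 0.0)
    entropy = -(pfm * logs).sum(axis=1)
    return float((2.0 - entropy).mean())


def match_score(pfm: np.ndarray, mirna_seq: str) -> tuple[float, int]:
    """Best ungapped complementarity of the motif PFM to the miRNA.

    A target motif read 5'->3' pairs antiparallel to the miRNA, so PFM
    column 0 faces the highest complemented miRNA position.  Returns
    (s, matched_offset) with the offset as the 1-based miRNA position of
    the 5'-most complemented base.
    """
    k = pfm.shape[0]
    L = len(mirna_seq)
    best, best_off = 0.0, 1
    for q in range(L - k + 1):  # q = 0-based 5'-most complemented position
        score = 0.0
        for col in range(k):
            mi = mirna_seq[q + (k - 1 - col)]
            score += pfm[col, _CODE[revcomp(mi)]]
        score /= k
        if score > best:
            best, best_off = score, q + 1
    return best, best_off


def combined_confidence(p: float, s: float) -> float:
    """c = (-log10(p) - 10)/10 + (s - 0.35) * 6.7; decreasing in p, increasing in s."""
    if p <= 0:
        raise ValueError("p must be in (0, 1]")
    return (-math.log10(p) - 10.0) / 10.0 + (s - 0.35) * 6.7


def discover_motifs(
    mirna_id: str,
    mirna_seq: str,
    foreground: list[str],
    background_draws: list[list[str]],
    k: int = 7,
    s_min: float = 0.35,
    ic_min: float = 1.75,
    c_min: float = 1.0,
    top_n: int = 25,
) -> list[MotifResult]:
    """Full per-miRNA motif discovery across background draws.

    A motif's statistics come from the first draw in which it appears; its
    ``draws_retained`` counts the draws where it passed all thresholds, and
    robust motifs (retained in >= 2 draws when >= 2 draws are supplied) keep
    ``retained=True``.
    """
    per_draw: list[dict[str, MotifResult]] = []
    for bg in background_draws:
        results = {}
        for consensus, p, fg_hits in enriched_kmers(foreground, bg, k, top_n):
            pfm, fg_frac = refine_pfm(consensus, foreground)
            s, off = match_score(pfm, mirna_seq)
            ic = information_content(pfm)
            c = combined_confidence(p, s)
            res = MotifResult(
                mirna_id, consensus, pfm, p, s, off, ic, c, fg_frac,
                retained=(s >= s_min and ic >= ic_min and c >= c_min),
            )
            results[consensus] = res
        per_draw.append(results)
    merged: dict[str, MotifResult] = {}
    for results in per_draw:
        for consensus, res in results.items():
            if consensus not in merged:
                merged[consensus] = res
            if res.retained:
                merged[consensus].draws_retained += 1
    need = 2 if len(background_draws) >= 2 else 1
    for res in merged.values():
        res.retained = res.draws_retained >= need
    return sorted(merged.values(), key=lambda r: r.p)


def motif_position_heatmap(
    retained: dict[str, list[MotifResult]],
    mirna_lengths: dict[str, int],
    k: int = 7,
):
    """Per-miRNA motif intensity painted over complemented miRNA positions.

    Intensity = foreground occurrence fraction over positions
    [matched_offset, matched_offset + k - 1]; rows ordered by average-linkage
    hierarchical clustering of intensity profiles.
    """
    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import pdist

    mirnas = sorted(retained)
    lmax = max(mirna_lengths.values()) if mirna_lengths else 0
    mat = np.zeros((len(mirnas), lmax))
    for r, mid in enumerate(mirnas):
        for res in retained[mid]:
            lo = res.matched_offset - 1
            hi = min(lo + k, lmax)
            mat[r, lo:hi] = np.maximum(mat[r, lo:hi], res.fg_fraction)
    if len(mirnas) > 2 and mat.any():
        order = leaves_list(average(pdist(mat)))
    else:
        order = np.arange(len(mirnas))
    return [mirnas[i] for i in order], mat[order]
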