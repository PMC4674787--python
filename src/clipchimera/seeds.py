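"""Seed-match taxonomy for target regions against their cognate miRNA.

Canonical classes follow the standard nomenclature: in target 5'->3'
orientation the site reads revcomp(miRNA positions hi..2) optionally followed
by an A opposite miRNA position 1 (the A is required to be A, not to
complement position 1).  Variant classes allow exactly one edit relative to a
canonical site: a substitution (mm8/mm7/mm6, mismatch position in miRNA
coordinates), one extra target base between two seed pairs (bulge_target) or
one skipped target base (bulge_mirna).  A substitution that converts a
Watson-Crick pair into G:U is reported as the canonical class with the wobble
position recorded (switchable to mismatch with ``wobble_as_mismatch``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import MiRNAEntry
from .io import revcomp

CANONICAL_ORDER = ["8mer", "7mer-m8", "7mer-A1", "6mer"]
_CLASS_SPAN = {"8mer": (2, 8), "7mer-m8": (2, 8), "7mer-A1": (2, 7), "6mer": (2, 7)}
_CLASS_A1 = {"8mer": True, "7mer-m8": False, "7mer-A1": True, "6mer": False}
_WOBBLE = {("G", "T"), ("T", "G")}  # (miRNA base, target base), DNA letters


@dataclass
class SeedMatch:
    interaction_id: str | None
    seed_class: str
    offset: int
    mismatch_position: int | None = None
    bulge_position: tuple[int, int] | None = None  # miRNA positions flanking insertion
    bulge_base: str | None = None
    bulged_mirna_position: int | None = None
    wobble_positions: frozenset = frozenset()
    edits: int = 0


def _site_template(mirna: str, seed_class: str) -> tuple[str, list[int]]:
    """Target-strand site string and, per site index, the paired miRNA position
    (0 marks the A opposite position 1)."""
    lo, hi = _CLASS_SPAN[seed_class]
    core = revcomp(mirna[lo - 1 : hi])
    positions = list(range(hi, lo - 1, -1))
    if _CLASS_A1[seed_class]:
        return core + "A", positions + [0]
    return core, positions


def canonical_match(
    region: str, mirna: MiRNAEntry, interaction_id: str | None = None
) -> SeedMatch | None:
    """Highest canonical class present in the region; leftmost site on ties."""
    for cls in CANONICAL_ORDER:
        site, _ = _site_template(mirna.sequence, cls)
        idx = region.find(site)
        if idx >= 0:
            return SeedMatch(interaction_id, cls, idx)
    return None


def _pairs(mi: str, tb: str) -> str | None:
    """'wc', 'wobble' or None for a (miRNA base, target base) combination."""
    if tb == revcomp(mi):
        return "wc"
    if (mi, tb) in _WOBBLE:
        return "wobble"
    return None


def variant_match(
    region: str,
    mirna: MiRNAEntry,
    interaction_id: str | None = None,
    wobble_as_mismatch: bool = False,
) -> SeedMatch | None:
    """Best single-edit seed variant in the region.

    Enumerates all single substitutions, single target-base insertions
    (bulge_target) and single target-base deletions (bulge_mirna) of every
    canonical site, scores candidates by (seed pairs, fewest edits) and
    breaks ties by smallest offset (closest to the ligation junction).
    """
    candidates: list[tuple[tuple, SeedMatch]] = []

    def add(match: SeedMatch, n_pairs: int):
        idx = region.find(match_site)
        if idx >= 0:
            m = SeedMatch(
                interaction_id, match.seed_class, idx,
                match.mismatch_position, match.bulge_position, match.bulge_base,
                match.bulged_mirna_position, match.wobble_positions, match.edits,
            )
            candidates.append(((-n_pairs, m.edits, idx), m))

    for cls in CANONICAL_ORDER:
        site, pos_map = _site_template(mirna.sequence, cls)
        lo, hi = _CLASS_SPAN[cls]
        n_pairs = hi - lo + 1
        # substitution variants
        for i, mpos in enumerate(pos_map):
            if mpos == 0:
                continue  # the A anchor is definitional, not a pairing position
            mi_base = mirna.sequence[mpos - 1]
            for b in "ACGT":
                if b == site[i]:
                    continue
                match_site = site[:i] + b + site[i + 1 :]
                kind = _pairs(mi_base, b)
                if kind == "wobble" and not wobble_as_mismatch:
                    add(
                        SeedMatch(None, cls, 0, wobble_positions=frozenset({mpos}),
                                  edits=1),
                        n_pairs,
                    )
                else:
                    mm_cls = {"8mer": "mm8", "7mer-m8": "mm7", "7mer-A1": "mm7",
                              "6mer": "mm6"}[cls]
                    add(
                        SeedMatch(None, mm_cls, 0, mismatch_position=mpos, edits=1),
                        n_pairs - 1,
                    )
        if cls in ("8mer", "7mer-m8"):
            # single target-base insertion between two seed-pairing bases
            for i in range(1, len(site) - (1 if _CLASS_A1[cls] else 0)):
                left_pos, right_pos = pos_map[i], pos_map[i - 1]
                if right_pos == 0:
                    continue
                for b in "ACGT":
                    match_site = site[:i] + b + site[i:]
                    add(
                        SeedMatch(None, f"bulge_target_{cls}", 0,
                                  bulge_position=(left_pos, right_pos),
                                  bulge_base=b, edits=1),
                        n_pairs,
                    )
            # single target-base deletion -> bulged (unpaired) miRNA position
            for i, mpos in enumerate(pos_map):
                if mpos in (0, lo, hi):
                    continue  # interior bulges only
                match_site = site[:i] + site[i + 1 :]
                add(
                    SeedMatch(None, f"bulge_mirna_{cls}", 0,
                              bulged_mirna_position=mpos, edits=1),
                    n_pairs - 1,
                )
    if not candidates:
        return None
    candidates.sort(key=lambda t: t[0])
    return candidates[0][1]


def classify_region(
    region: str, mirna: MiRNAEntry, interaction_id: str | None = None,
    wobble_as_mismatch: bool = False,
) -> SeedMatch:
    """Canonical first, then single-edit variants, else class 'none'."""
    m = canonical_match(region, mirna, interaction_id)
    if m is not None:
        return m
    m = variant_match(region, mirna, interaction_id, wobble_as_mismatch)
    if m is not None:
        return m
    return SeedMatch(interaction_id, "none", -1)


def seed_position_cdf(
    pairs: list[tuple[str, int, MiRNAEntry]],
    rng_seed: int = 0,
    window: tuple[int, int] = (-100, 100),
    downstream: tuple[int, int] = (0, 75),
):
    """Canonical seed-match positions relative to the ligation junction.

    ``pairs`` are (sequence, junction_index, miRNA): the sequence may extend
    upstream of the junction, whose position inside it is ``junction_index``.
    Per chimera the reported offset is the canonical match closest to the
    junction (ties broken downstream); the downstream/upstream fractions
    count chimeras with a canonical match starting inside ``downstream``
    (respectively its upstream mirror image), for the true assignment and
    for a seeded cyclic shuffle of the miRNA assignment (no region keeps its
    own miRNA).  ``enrichment`` is true minus shuffled downstream fraction.
    """
    if not pairs:
        raise ValueError("no (region, junction, miRNA) pairs supplied")

    def all_offsets(seq, junction, mirna):
        offs = set()
        for cls in CANONICAL_ORDER:
            site, _ = _site_template(mirna.sequence, cls)
            start = 0
            while True:
                idx = seq.find(site, start)
                if idx < 0:
                    break
                offs.add(idx - junction)
                start = idx + 1
        return offs

    def stats_of(assignment):
        offsets, down, up = [], 0, 0
        lo, hi = downstream
        for (seq, junction, _), mirna in zip(pairs, assignment):
            offs = all_offsets(seq, junction, mirna)
            if offs:
                offsets.append(min(offs, key=lambda o: (abs(o), o < 0)))
            if any(lo <= o < hi for o in offs):
                down += 1
            if any(-hi <= o < -lo for o in offs):
                up += 1
        return offsets, down / len(pairs), up / len(pairs)

    mirnas = [m for (_, _, m) in pairs]
    true_offsets, fd, fu = stats_of(mirnas)
    rng = np.random.default_rng(rng_seed)
    perm = np.roll(rng.permutation(len(pairs)), 1)  # cyclic: no fixed points
    _, fds, fus = stats_of([mirnas[i] for i in perm])
    lo, hi = window
    grid = np.arange(lo, hi + 1)
    offs = np.array(sorted(true_offsets)) if true_offsets else np.array([])
    cdf = (
        np.searchsorted(offs, grid, side="right") / len(pairs)
        if len(offs)
        else np.zeros_like(grid, dtype=float)
    )
    return {
        "offsets": true_offsets,
        "grid": grid,
        "cdf": cdf,
        "frac_downstream": fd,
        "frac_upstream": fu,
        "frac_downstream_shuffled": fds,
        "frac_upstream_shuffled": fus,
        "enrichment": fd - fds,
    }


def positional_preference_profile(
    matches_by_mirna: dict[str, list[SeedMatch]],
    min_sites: int = 50,
    disallowed_floor: float = 0.01,
):
    """Per-miRNA positional frequency vectors for each variant type.

    Rows (positions 1-8) sum to 1 per variant type; positions with frequency
    below ``disallowed_floor`` (given >= min_sites sites) are flagged.
    """
    out = {}
    for mirna_id, matches in matches_by_mirna.items():
        if len(matches) < min_sites:
            continue
        profiles = {}
        for kind, positions in (
            ("mismatch", [m.mismatch_position for m in matches
                          if m.mismatch_position is not None]),
            ("bulge_target", [m.bulge_position[0] for m in matches
                              if m.bulge_position is not None]),
            ("bulge_mirna", [m.bulged_mirna_position for m in matches
                             if m.bulged_mirna_position is not None]),
            ("wobble", [p for m in matches for p in m.wobble_positions]),
        ):
            vec = np.zeros(8)
            for p in positions:
                vec[p - 1] += 1
            total = vec.sum()
            freq = vec / total if total else vec
            profiles[kind] = {
                "freq": freq,
                "n": int(total),
                "disallowed": [
                    i + 1 for i, f in enumerate(freq)
                    if total >= min_sites and f < disallowed_floor
                ],
            }
        out[mirna_id] = profiles
    return out
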