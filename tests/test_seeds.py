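"""Seed-match taxonomy: canonical classes, single-edit variants, positions."""

import numpy as np
import pytest

from clipchimera.detect import MiRNAEntry
from clipchimera.io import revcomp
from clipchimera.seeds import (_site_template, canonical_match,
                               classify_region, positional_preference_profile,
                               seed_position_cdf, variant_match, SeedMatch)

MIRNA = MiRNAEntry("miR-x", "TGAGGTAGTAGGTTGTATAGTT")
BASES = "ACGT"


def _pad(rng, site, left=10, right=10):
    s = "".join(rng.choice(list(BASES), left + right))
    return s[:left] + site + s[left:]


def test_canonical_definitions():
    rng = np.random.default_rng(0)
    for cls, lo, hi, a1 in [("8mer", 2, 8, True), ("7mer-m8", 2, 8, False),
                            ("7mer-A1", 2, 7, True), ("6mer", 2, 7, False)]:
        site = revcomp(MIRNA.sequence[lo - 1:hi]) + ("A" if a1 else "")
        tmpl, _ = _site_template(MIRNA.sequence, cls)
        assert tmpl == site
    region = _pad(rng, _site_template(MIRNA.sequence, "8mer")[0])
    assert canonical_match(region, MIRNA).seed_class == "8mer"
    region6 = _pad(rng, _site_template(MIRNA.sequence, "6mer")[0] + "G")
    m = canonical_match(region6, MIRNA)
    assert m.seed_class in ("6mer", "7mer-A1")  # depends on following base


def test_canonical_classes_are_nested():
    t8, _ = _site_template(MIRNA.sequence, "8mer")
    for cls in ("7mer-m8", "7mer-A1", "6mer"):
        assert _site_template(MIRNA.sequence, cls)[0] in t8


def _canonical_oracle(region, mirna):
    """Independent position-by-position scan of the class definitions."""
    m = mirna.sequence
    best = None
    order = {"8mer": 0, "7mer-m8": 1, "7mer-A1": 2, "6mer": 3}
    for i in range(len(region)):
        for cls, lo, hi, a1 in [("8mer", 2, 8, True), ("7mer-m8", 2, 8, False),
                                ("7mer-A1", 2, 7, True), ("6mer", 2, 7, False)]:
            core = revcomp(m[lo - 1:hi])
            want = core + ("A" if a1 else "")
            if region[i:i + len(want)] == want:
                key = (order[cls], i)
                if best is None or key < best[0]:
                    best = (key, cls, i)
    return None if best is None else (best[1], best[2])


def test_canonical_matches_bruteforce_scan():
    rng = np.random.default_rng(1)
    n_hit = 0
    for trial in range(800):
        region = "".join(rng.choice(list(BASES), 40))
        if trial % 3 == 0:
            cls = ["8mer", "7mer-m8", "7mer-A1", "6mer"][rng.integers(0, 4)]
            site, _ = _site_template(MIRNA.sequence, cls)
            pos = rng.integers(0, 40 - len(site))
            region = region[:pos] + site + region[pos + len(site):]
        got = canonical_match(region, MIRNA)
        want = _canonical_oracle(region, MIRNA)
        if want is None:
            assert got is None
        else:
            n_hit += 1
            assert (got.seed_class, got.offset) == want
    assert n_hit > 200


def test_bulge_between_positions_5_and_6():
    # an extra target G inserted between the bases pairing positions 5 and 6
    site, pos_map = _site_template(MIRNA.sequence, "8mer")
    i = pos_map.index(5)
    bulged = site[:i] + "G" + site[i:]
    rng = np.random.default_rng(2)
    region = _pad(rng, bulged)
    m = classify_region(region, MIRNA)
    assert m.seed_class == "bulge_target_8mer"
    assert m.bulge_position == (5, 6) and m.bulge_base == "G"


def test_mismatch_position_recorded():
    site, pos_map = _site_template(MIRNA.sequence, "8mer")
    i = pos_map.index(4)
    wc = site[i]
    mi = MIRNA.sequence[3]
    sub = next(b for b in BASES
               if b != wc and (mi, b) not in (("G", "T"), ("T", "G")))
    rng = np.random.default_rng(3)
    m = classify_region(_pad(rng, site[:i] + sub + site[i + 1:]), MIRNA)
    assert m.seed_class == "mm8" and m.mismatch_position == 4


def test_wobble_reported_as_canonical_with_positions():
    # find a seed position where the miRNA base admits a G:U pairing
    site, pos_map = _site_template(MIRNA.sequence, "7mer-m8")
    # interior position, so the wobble cannot leave a shorter canonical site
    pos = next(p for p in pos_map if 3 <= p <= 7 and MIRNA.sequence[p - 1] in "GT")
    i = pos_map.index(pos)
    wob = "T" if MIRNA.sequence[pos - 1] == "G" else "G"
    region = "C" * 10 + site[:i] + wob + site[i + 1:] + "C" * 10
    m = classify_region(region, MIRNA)
    assert m.seed_class == "7mer-m8" and m.wobble_positions == frozenset({pos})
    demoted = classify_region(region, MIRNA, wobble_as_mismatch=True)
    assert demoted.seed_class.startswith("mm")


def test_variant_never_overrides_canonical():
    rng = np.random.default_rng(4)
    for _ in range(200):
        region = "".join(rng.choice(list(BASES), 40))
        if canonical_match(region, MIRNA) is not None:
            m = classify_region(region, MIRNA)
            assert m.seed_class in ("8mer", "7mer-m8", "7mer-A1", "6mer")
            assert m.edits == 0


def test_exhaustive_single_edit_neighbors_of_7mer():
    """Every 1-substitution neighbour of the 7mer-m8 site classifies as a
    canonical wobble, a mismatch at the edited position, or (if the edit
    restores/creates another site) something at least as good."""
    site, pos_map = _site_template(MIRNA.sequence, "7mer-m8")
    for i, pos in enumerate(pos_map):
        for b in BASES:
            if b == site[i]:
                continue
            region = "C" * 8 + site[:i] + b + site[i + 1:] + "C" * 8
            m = classify_region(region, MIRNA)
            assert m is not None and m.seed_class != "none"
            mi = MIRNA.sequence[pos - 1]
            if canonical_match(region, MIRNA):
                continue  # edge edits can recreate a 6mer; canonical wins
            if (mi, b) in (("G", "T"), ("T", "G")):
                assert pos in m.wobble_positions
            elif m.mismatch_position is not None:
                assert m.mismatch_position == pos


def test_seed_position_cdf_localization():
    rng = np.random.default_rng(5)
    site, _ = _site_template(MIRNA.sequence, "8mer")
    pairs = []
    for _ in range(60):
        seq = "".join(rng.choice(list(BASES), 200))
        seq = seq[:110] + site + seq[110 + len(site):]  # offset +10 downstream
        pairs.append((seq, 100, MIRNA))
    res = seed_position_cdf(pairs, rng_seed=1)
    assert res["frac_downstream"] == 1.0
    assert all(o == 10 for o in res["offsets"])
    assert res["frac_upstream"] < 0.2
    # step CDF at +10
    grid = res["grid"]
    assert res["cdf"][grid == 9][0] < 0.2 and res["cdf"][grid == 10][0] == 1.0
    # shuffled assignment of a single shared miRNA would be a no-op; use
    # distinct miRNAs to check the null has no downstream excess
    mirnas = [MiRNAEntry(f"m{i}", "".join(rng.choice(list(BASES), 22)))
              for i in range(8)]
    null_pairs = [("".join(rng.choice(list(BASES), 200)), 100,
                   mirnas[i % 8]) for i in range(120)]
    null = seed_position_cdf(null_pairs, rng_seed=2)
    assert abs(null["enrichment"]) < 0.15
    with pytest.raises(ValueError):
        seed_position_cdf([])


def test_positional_preference_profiles():
    bulges = [SeedMatch(None, "bulge_target_8mer", 0, bulge_position=(5, 6),
                        bulge_base="G") for _ in range(60)]
    prof = positional_preference_profile({"m1": bulges}, min_sites=50)
    assert prof["m1"]["bulge_target"]["freq"][4] == 1.0
    rng = np.random.default_rng(6)
    mms = [SeedMatch(None, "mm8", 0, mismatch_position=int(p))
           for p in rng.integers(2, 9, 700)]
    prof2 = positional_preference_profile({"m2": mms}, min_sites=50)
    freq = prof2["m2"]["mismatch"]["freq"][1:8]
    assert np.allclose(freq, 1 / 7, atol=0.05)
    assert positional_preference_profile({"m3": mms[:10]}, min_sites=50) == {}
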