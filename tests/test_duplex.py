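"""Intermolecular duplex DP: oracle equivalence, constraints, shuffling."""

import numpy as np
import pytest

from clipchimera.detect import MiRNAEntry
from clipchimera.duplex import (Constraint, EnergyParams, brute_force_mfe,
                                choose_constraint, default_params,
                                fold_with_seed, hybrid_mfe, seed_aux_counts,
                                seed_concordance, shuffle_assignment)
from clipchimera.io import revcomp
from clipchimera.seeds import SeedMatch, _site_template, classify_region

BASES = list("ACGT")


def test_full_helix_and_no_complementarity(params):
    m = "TGAGGTAGTAGGTTGTATAGTT"
    s = hybrid_mfe(m, revcomp(m), params)
    assert s.pairing.all() and s.mfe < -20
    # strictly increasing partners (no crossings) in 3'->5' target coords
    p = s.partners[s.partners >= 0]
    assert (np.diff(p) > 0).all()
    # a miRNA without complementary bases to the region folds to nothing
    empty = hybrid_mfe("A" * 22, "C" * 40, params)
    assert empty.mfe == 0.0 and empty.n_pairs == 0


def test_dp_equals_bruteforce_enumeration(params):
    rng = np.random.default_rng(17)
    for _ in range(120):
        m = "A" + "".join(rng.choice(BASES, 8))
        t = "".join(rng.choice(BASES, 9))
        assert hybrid_mfe(m, t, params).mfe == pytest.approx(
            brute_force_mfe(m, t, params), abs=1e-9)


def test_dp_equals_bruteforce_with_constraints(params):
    rng = np.random.default_rng(18)
    n_feasible = 0
    for _ in range(60):
        m = "A" + "".join(rng.choice(BASES, 8))
        t = "".join(rng.choice(BASES, 9))
        c = Constraint("f34", required=frozenset({1, 2}))
        d = hybrid_mfe(m, t, params, c)
        b = brute_force_mfe(m, t, params, c)
        assert d.mfe == pytest.approx(b, abs=1e-9)
        if d.n_pairs:
            n_feasible += 1
            assert d.pairing[1] and d.pairing[2]
    assert n_feasible > 10


def test_constraint_monotonicity(params):
    rng = np.random.default_rng(19)
    for _ in range(150):
        m = "".join(rng.choice(BASES, 22))
        t = "".join(rng.choice(BASES, 50))
        free = hybrid_mfe(m, t, params).mfe
        forced = hybrid_mfe(m, t, params,
                            Constraint("f56", required=frozenset({3, 4}))).mfe
        assert forced >= free - 1e-9


def test_unit_cost_table_solves_longest_noncrossing_subsequence():
    """With -1 stacks and zero penalties the DP minimizes -(pairs - 1)."""
    unit = EnergyParams(
        stack=-np.ones((6, 6)),
        bulge=np.zeros(16), interior=np.zeros(31),
        terminal=np.zeros(6), max_loop=15,
    )
    # charge every chain step -1 (gapped or stacked) so the optimum counts
    # pairs: mfe = -(LNCS - 1)
    unit.bulge[:] = -1.0
    unit.interior[:] = -1.0

    def lncs(m, t):
        # longest noncrossing complementary subsequence, O(n*m) DP oracle
        comp = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
                ("G", "T"), ("T", "G")}
        n, M = len(m), len(t)
        D = np.zeros((n + 1, M + 1), dtype=int)
        for i in range(1, n + 1):
            for j in range(1, M + 1):
                D[i, j] = max(D[i - 1, j], D[i, j - 1])
                if (m[i - 1], t[j - 1]) in comp:
                    D[i, j] = max(D[i, j], D[i - 1, j - 1] + 1)
        return D[n, M]

    rng = np.random.default_rng(20)
    for _ in range(40):
        m = "A" + "".join(rng.choice(BASES, 10))
        t = "".join(rng.choice(BASES, 12))
        k = lncs(m[1:], t[::-1])
        got = hybrid_mfe(m, t, unit).mfe
        assert got == pytest.approx(-(k - 1) if k >= 1 else 0.0, abs=1e-9)


def test_forced_canonical_anchors_seed(params):
    m = MiRNAEntry("m", "TGAGGTAGTAGGTTGTATAGTT")
    rng = np.random.default_rng(21)
    site, _ = _site_template(m.sequence, "8mer")
    pad = "".join(rng.choice(BASES, 60))
    region = pad[:12] + site + pad[12:60 - len(site) + 12]
    region = region[:75]
    sm = classify_region(region, m)
    assert sm.seed_class == "8mer"
    s = fold_with_seed(m.sequence, region, sm, params)
    assert s.constraint_used == "seed_forced"
    assert all(s.pairing[q - 2] for q in range(2, 9))
    # the anchored positions pair exactly opposite the matched site
    free = hybrid_mfe(m.sequence, region, params)
    assert s.mfe >= free.mfe - 1e-9


def test_choose_constraint_policy():
    assert choose_constraint(None) == [None]
    assert choose_constraint(SeedMatch(None, "none", -1)) == [None]
    runs = choose_constraint(SeedMatch(None, "mm7", 3, mismatch_position=4))
    assert [r.name for r in runs] == ["f34", "f56"]
    canon = choose_constraint(SeedMatch(None, "8mer", 5))
    assert canon[0].name == "seed_forced" and len(canon[0].anchor) == 7


def test_seed_aux_counts(params):
    m = "TGAGGTAGTAGGTTGTATAGTT"
    s = hybrid_mfe(m, revcomp(m), params)
    assert seed_aux_counts(s) == (7, 14)
    empty = hybrid_mfe("A" * 22, "C" * 40, params)
    assert seed_aux_counts(empty) == (0, 0)


def test_seed_concordance_constrained_is_total(params):
    m = MiRNAEntry("m", "TGAGGTAGTAGGTTGTATAGTT")
    rng = np.random.default_rng(22)
    structures, matches = [], []
    for _ in range(20):
        site, _ = _site_template(m.sequence, "7mer-m8")
        pad = "".join(rng.choice(BASES, 80))
        region = (pad[:10] + site + pad[10:])[:75]
        sm = classify_region(region, m)
        if sm.seed_class != "7mer-m8":
            continue
        structures.append(fold_with_seed(m.sequence, region, sm, params))
        matches.append(sm)
    conc = seed_concordance(structures, matches)
    assert conc["7mer-m8"] == 1.0
    with pytest.raises(ValueError):
        seed_concordance([], [])


def test_shuffle_assignment_derangement_and_degenerate(params):
    rng = np.random.default_rng(23)
    pairs = [(f"m{i}", "".join(rng.choice(BASES, 22)),
              "".join(rng.choice(BASES, 75))) for i in range(9)]
    for seed in range(50):
        res = shuffle_assignment(pairs, seed, params)
        assert (res["permutation"] != np.arange(len(pairs))).all()
    same = [("m", pairs[0][1], "".join(rng.choice(BASES, 75)))
            for _ in range(6)]
    res = shuffle_assignment(same, 0, params)
    assert res["p"] == 1.0
    with pytest.raises(ValueError):
        shuffle_assignment(pairs[:1], 0, params)


def test_region_length_contract(params):
    with pytest.raises(ValueError):
        hybrid_mfe("A" * 22, "C" * 101, params)
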