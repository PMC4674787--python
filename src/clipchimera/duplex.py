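"""Constrained intermolecular miRNA-target duplex prediction.

The model considers only intermolecular base pairs (Watson-Crick or G:U),
no branching and no pseudoknots: a structure is a non-crossing matching
between miRNA positions (5'->3', position 1 trimmed since it is buried in
AGO and does not pair) and target positions read 3'->5'.  Consecutive pairs
are scored with a nearest-neighbour stacking table; unpaired stretches
between pairs cost bulge (one strand) or interior-loop (both strands)
penalties by size, capped at ``max_loop`` bases per strand; each helix end
pays a terminal penalty for AU/GU closing pairs.  The optimum is found by
dynamic programming over "last pair" states; forced-pairing constraints
(anchored seed helices, or RNAhybrid-style "-f a,b" position constraints)
are enforced inside the recursion.

Target partner indices are reported in 3'->5' target coordinates (0 = the
target's 3' end), which makes them strictly increasing along the miRNA.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

from .seeds import SeedMatch, _CLASS_SPAN

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
PAIR_NAMES = ["AU", "UA", "GC", "CG", "GU", "UG"]
_PAIR_TABLE = -np.ones((4, 4), dtype=np.int64)
for _k, (_a, _b) in enumerate([(0, 3), (3, 0), (2, 1), (1, 2), (2, 3), (3, 2)]):
    _PAIR_TABLE[_a, _b] = _k

INF = 1e30


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, -1) for c in seq.upper()], dtype=np.int64)


@dataclass
class EnergyParams:
    stack: np.ndarray        # 6x6 kcal/mol, indexed by PAIR_NAMES
    bulge: np.ndarray        # cost by size 1..max_loop (index 0 unused)
    interior: np.ndarray     # cost by total size 2..2*max_loop
    terminal: np.ndarray     # per closing pair type
    max_loop: int = 15

    def __post_init__(self) -> None:
        if (self.stack >= 0).any():
            raise ValueError("all stacking energies must be negative")
        if (self.bulge[1:] < 0).any() or (self.interior[2:] < 0).any():
            raise ValueError("loop penalties must be non-negative")

    @classmethod
    def from_tsv(cls, path=None) -> "EnergyParams":
        if path is None:
            path = importlib.resources.files("clipchimera.data") / "energy_params.tsv"
        raw: dict[str, dict[str, float]] = {}
        with open(str(path)) as fh:
            header = fh.readline()
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                kind, key, value = line.split("\t")
                raw.setdefault(kind, {})[key] = float(value)
        max_loop = int(raw["limit"]["max_loop"])
        idx = {p: i for i, p in enumerate(PAIR_NAMES)}
        rev = {p: p[::-1] for p in PAIR_NAMES}
        stack = np.zeros((6, 6))
        for p in PAIR_NAMES:
            for q in PAIR_NAMES:
                v1 = raw["stack"].get(f"{p}|{q}")
                v2 = raw["stack"].get(f"{rev[q]}|{rev[p]}")
                vals = [v for v in (v1, v2) if v is not None]
                if not vals:
                    raise ValueError(f"no stack energy derivable for {p}|{q}")
                stack[idx[p], idx[q]] = float(np.mean(vals))
        bulge = np.zeros(max_loop + 1)
        for k, v in raw["bulge"].items():
            bulge[int(k)] = v
        interior = np.zeros(2 * max_loop + 1)
        for k, v in raw["interior"].items():
            interior[int(k)] = v
        terminal = np.array([raw["terminal"][p] for p in PAIR_NAMES])
        return cls(stack, bulge, interior, terminal, max_loop)


_DEFAULT_PARAMS: EnergyParams | None = None


def default_params() -> EnergyParams:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = EnergyParams.from_tsv()
    return _DEFAULT_PARAMS


@dataclass
class DuplexStructure:
    interaction_id: str | None
    pairing: np.ndarray          # 0/1 per miRNA position 2..L
    partners: np.ndarray         # target index (3'->5' coords) or -1
    mfe: float
    constraint_used: str = "none"

    @property
    def n_pairs(self) -> int:
        return int(self.pairing.sum())

    def pairing_string(self) -> str:
        return "".join(str(int(v)) for v in self.pairing)


@njit(cache=True)
def _dp_kernel(m, t, pair_tab, stack, bulge, interior, term, max_loop,
               anchor, required):
    n = m.shape[0]
    M = t.shape[0]
    H = np.full((n, M), INF)
    TB = np.full((n, M, 2), -2, dtype=np.int64)
    req_cum = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        req_cum[i + 1] = req_cum[i] + (1 if required[i] else 0)
    for i in range(n):
        for j in range(M):
            if m[i] < 0 or t[j] < 0:
                continue
            p = pair_tab[m[i], t[j]]
            if p < 0:
                continue
            if anchor[i] >= 0 and anchor[i] != j:
                continue
            best = INF
            ba = np.int64(-2)
            bb = np.int64(-2)
            if req_cum[i] == 0:
                best = term[p]
                ba = np.int64(-1)
                bb = np.int64(-1)
            for a in range(0, max_loop + 1):
                ii = i - 1 - a
                if ii < 0:
                    break
                if req_cum[i] - req_cum[ii + 1] > 0:
                    break
                for b in range(0, max_loop + 1):
                    jj = j - 1 - b
                    if jj < 0:
                        break
                    h = H[ii, jj]
                    if h >= INF:
                        continue
                    if a == 0 and b == 0:
                        pp = pair_tab[m[ii], t[jj]]
                        cost = stack[pp, p]
                    elif a > 0 and b > 0:
                        cost = interior[a + b]
                    else:
                        cost = bulge[a + b]
                    v = h + cost
                    if v < best:
                        best = v
                        ba = np.int64(a)
                        bb = np.int64(b)
            if best < INF:
                H[i, j] = best
                TB[i, j, 0] = ba
                TB[i, j, 1] = bb
    best_e = INF
    bi = np.int64(-1)
    bj = np.int64(-1)
    for i in range(n):
        if req_cum[n] - req_cum[i + 1] > 0:
            continue
        for j in range(M):
            if H[i, j] < INF:
                p = pair_tab[m[i], t[j]]
                v = H[i, j] + term[p]
                if v < best_e:
                    best_e = v
                    bi = np.int64(i)
                    bj = np.int64(j)
    return H, TB, best_e, bi, bj


@dataclass
class Constraint:
    """Forced pairing: ``anchor`` maps a trimmed miRNA index to a fixed target
    partner (3'->5' coords); ``required`` indices must pair with something."""

    name: str
    anchor: dict[int, int] = field(default_factory=dict)
    required: frozenset = frozenset()


def hybrid_mfe(
    mirna: str,
    region: str,
    params: EnergyParams | None = None,
    constraint: Constraint | None = None,
    interaction_id: str | None = None,
) -> DuplexStructure:
    """Minimum-free-energy intermolecular duplex for one miRNA/region pair.

    The miRNA's first nucleotide is trimmed before folding.  Without a
    constraint, a non-negative optimum yields the empty structure at 0
    kcal/mol; with a constraint the constrained optimum is returned even if
    unfavourable (infeasible constraints also yield the empty structure).
    """
    if len(region) > 100:
        raise ValueError("target region longer than 100 nt")
    params = params or default_params()
    m = encode(mirna)[1:]
    t = encode(region)[::-1].copy()  # 3'->5' target coordinates
    n = len(m)
    anchor = -np.ones(n, dtype=np.int64)
    required = np.zeros(n, dtype=np.bool_)
    cname = "none"
    if constraint is not None:
        cname = constraint.name
        for i, j in constraint.anchor.items():
            anchor[i] = j
            required[i] = True
        for i in constraint.required:
            required[i] = True
    H, TB, best_e, bi, bj = _dp_kernel(
        m, t, _PAIR_TABLE, params.stack, params.bulge, params.interior,
        params.terminal, params.max_loop, anchor, required,
    )
    pairing = np.zeros(n, dtype=np.int64)
    partners = -np.ones(n, dtype=np.int64)
    feasible = best_e < INF / 2
    if not feasible or (constraint is None and best_e >= 0):
        return DuplexStructure(interaction_id, pairing, partners, 0.0, cname)
    i, j = int(bi), int(bj)
    while True:
        pairing[i] = 1
        partners[i] = j
        a, b = int(TB[i, j, 0]), int(TB[i, j, 1])
        if a == -1:
            break
        i, j = i - 1 - a, j - 1 - b
    return DuplexStructure(interaction_id, pairing, partners, float(best_e), cname)


def brute_force_mfe(
    mirna: str, region: str, params: EnergyParams | None = None,
    constraint: Constraint | None = None,
) -> float:
    """Exhaustive enumeration of all non-crossing intermolecular pairings.

    Reference implementation for small inputs; scores with the same energy
    table as :func:`hybrid_mfe` but shares none of its recursion.
    """
    params = params or default_params()
    m = encode(mirna)[1:]
    t = encode(region)[::-1]
    n, M = len(m), len(t)
    anchor = {i: j for i, j in (constraint.anchor.items() if constraint else [])}
    required = set(anchor) | set(constraint.required if constraint else [])
    pairable = [
        [int(_PAIR_TABLE[m[i], t[j]]) if m[i] >= 0 and t[j] >= 0 else -1
         for j in range(M)]
        for i in range(n)
    ]
    best = [0.0 if constraint is None else None]

    def energy(pairs) -> float | None:
        e = params.terminal[pairable[pairs[0][0]][pairs[0][1]]]
        for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
            a, b = i2 - i1 - 1, j2 - j1 - 1
            if a > params.max_loop or b > params.max_loop:
                return None
            if a == 0 and b == 0:
                e += params.stack[pairable[i1][j1], pairable[i2][j2]]
            elif a > 0 and b > 0:
                e += params.interior[a + b]
            else:
                e += params.bulge[a + b]
        e += params.terminal[pairable[pairs[-1][0]][pairs[-1][1]]]
        return e

    def ok(pairs) -> bool:
        chosen = {i: j for i, j in pairs}
        for r in required:
            if r not in chosen:
                return False
            if r in anchor and chosen[r] != anchor[r]:
                return False
        return True

    def rec(i0, j0, pairs):
        if pairs and ok(pairs):
            e = energy(pairs)
            if e is not None and (best[0] is None or e < best[0]):
                best[0] = e
        for i in range(i0, n):
            for j in range(j0, M):
                if pairable[i][j] >= 0:
                    pairs.append((i, j))
                    rec(i + 1, j + 1, pairs)
                    pairs.pop()

    rec(0, 0, [])
    return best[0] if best[0] is not None else 0.0


def choose_constraint(seed_match: SeedMatch | None) -> list[Constraint | None]:
    """Constraint runs implied by a seed annotation.

    Canonical classes anchor the matched seed helix at its target offset;
    mismatch and bulge classes produce two runs forcing miRNA positions
    {3,4} and {5,6} paired (lower-energy structure kept); no seed homology
    folds unconstrained.
    """
    if seed_match is None or seed_match.seed_class == "none":
        return [None]
    cls = seed_match.seed_class
    if cls in _CLASS_SPAN:
        lo, hi = _CLASS_SPAN[cls]
        anchor = {}
        for q in range(lo, hi + 1):
            target_idx = seed_match.offset + (hi - q)  # 5'->3' region coords
            anchor[q - 2] = target_idx  # converted to 3'->5' by caller wrapper
        return [Constraint("seed_forced", anchor)]
    return [
        Constraint("f34", required=frozenset({1, 2})),
        Constraint("f56", required=frozenset({3, 4})),
    ]


def fold_with_seed(
    mirna: str,
    region: str,
    seed_match: SeedMatch | None,
    params: EnergyParams | None = None,
    interaction_id: str | None = None,
) -> DuplexStructure:
    """Fold one interaction under the constraint policy of the seed class."""
    runs = choose_constraint(seed_match)
    M = len(region)
    results = []
    for c in runs:
        if c is not None and c.anchor:
            c = Constraint(c.name,
                           {i: M - 1 - j for i, j in c.anchor.items()},
                           c.required)
        results.append(hybrid_mfe(mirna, region, params, c, interaction_id))
    return min(results, key=lambda s: s.mfe)


def seed_aux_counts(structure: DuplexStructure) -> tuple[int, int]:
    """(paired count in seed positions 2-8, paired count in positions 9..L)."""
    seed_bp = int(structure.pairing[:7].sum())
    aux_bp = int(structure.pairing[7:].sum())
    return seed_bp, aux_bp


def seed_concordance(
    structures: list[DuplexStructure], seed_matches: list[SeedMatch]
) -> dict:
    """Fraction of seed-containing regions whose structure pairs the whole
    matched seed span, overall and per canonical class."""
    if not structures:
        raise ValueError("empty structure set")
    per_class: dict[str, list[int]] = {}
    for s, m in zip(structures, seed_matches):
        if m is None or m.seed_class not in _CLASS_SPAN:
            continue
        lo, hi = _CLASS_SPAN[m.seed_class]
        paired = all(s.pairing[q - 2] for q in range(lo, hi + 1))
        per_class.setdefault(m.seed_class, []).append(int(paired))
    out = {cls: float(np.mean(v)) for cls, v in per_class.items()}
    all_v = [x for v in per_class.values() for x in v]
    out["overall"] = float(np.mean(all_v)) if all_v else float("nan")
    return out


def shuffle_assignment(
    pairs: list[tuple[str, str, str]],
    rng_seed: int,
    params: EnergyParams | None = None,
):
    """Shuffled-assignment null: re-fold each region with a different
    interaction's miRNA (derangement) and compare unconstrained MFEs.

    ``pairs`` are (mirna_id, mirna_sequence, region).  Returns true and
    shuffled MFE arrays and a two-tailed Welch t-test.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 interactions to shuffle")
    rng = np.random.default_rng(rng_seed)
    idx = np.arange(len(pairs))
    # Sattolo's algorithm: a uniform random cyclic permutation (no fixed points)
    for i in range(len(idx) - 1, 0, -1):
        j = rng.integers(0, i)
        idx[i], idx[j] = idx[j], idx[i]
    params = params or default_params()
    true_mfe = np.array([hybrid_mfe(seq, reg, params).mfe for _, seq, reg in pairs])
    shuf_mfe = np.array(
        [hybrid_mfe(pairs[idx[k]][1], pairs[k][2], params).mfe
         for k in range(len(pairs))]
    )
    if np.allclose(true_mfe, shuf_mfe):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(true_mfe, shuf_mfe, equal_var=False)
    return {
        "true_mfe": true_mfe,
        "shuffled_mfe": shuf_mfe,
        "permutation": idx,
        "t": float(t),
        "p": float(p),
    }
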