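"""Targeting specificity among seed-family paralogues.

Family members share an identical seed (positions 2-8) but diverge toward
the 3' end, so any chimera-level specificity must come from 3'-end pairing.
Three analyses: (i) strict chimera re-assignment with zero mismatches,
discarding reads still ambiguous between members; (ii) pairwise cross-MFE
folding of each member's target regions against every member (seed pairing
not forced), with one-tailed Welch t-tests that cognate duplexes are more
stable; (iii) member-specific motif discovery at several k against a pooled
AGO-bound background, mapped back to the member's divergent 3' sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .detect import MappingParams, MiRNACatalog, find_mirna_in_read
from .duplex import EnergyParams, default_params, hybrid_mfe
from .io import revcomp
from .motifs import MotifResult, discover_motifs


def strict_assignment(
    reads_by_sample: dict, catalog: MiRNACatalog, min_prefix: int = 12,
    truncation_mode: bool = False,
):
    """Re-run miRNA detection with zero mismatches; drop ambiguous hits.

    Returns (unambiguous hits, discarded count).  The strict hit set is a
    subset of the default-parameter hit set by construction.
    """
    params = MappingParams(
        seed_mismatches=0, ext_mismatches=0,
        truncation_mode=truncation_mode, min_prefix=min_prefix,
    )
    hits, discarded = [], 0
    for reads in reads_by_sample.values():
        for read in reads:
            hit = find_mirna_in_read(read, catalog, params)
            if hit is None:
                continue
            if len(hit.candidate_ids) > 1:
                discarded += 1
                continue
            hits.append(hit)
    return hits, discarded


@dataclass
class FamilyComparison:
    family_id: str
    members: list[str]
    mfe_mean: pd.DataFrame       # rows = target-set owner, cols = folded member
    mfe_values: dict             # (owner, member) -> np.ndarray
    tests: pd.DataFrame          # one-tailed p per (owner, cross member)
    strong_specificity: pd.DataFrame


def pairwise_mfe(
    family_id: str,
    member_seqs: dict[str, str],
    member_regions: dict[str, list[str]],
    params: EnergyParams | None = None,
    min_sites: int = 10,
    delta_strong: float = 6.0,
) -> FamilyComparison:
    """Cross-MFE matrix: each owner's regions folded against every member.

    Seed pairing is not forced.  For each owner and each cross member a
    one-tailed Welch t-test asks whether cognate MFEs are lower (more
    stable); mean cognate-vs-cross gaps > ``delta_strong`` kcal/mol are
    flagged as strong specificity.
    """
    params = params or default_params()
    members = sorted(m for m in member_seqs if len(member_regions.get(m, [])) >= min_sites)
    if len(members) < 2:
        raise ValueError("need at least two members with enough sites")
    values = {}
    for owner in members:
        for member in members:
            values[(owner, member)] = np.array(
                [hybrid_mfe(member_seqs[member], r, params).mfe
                 for r in member_regions[owner]]
            )
    mean = pd.DataFrame(
        [[values[(o, m)].mean() for m in members] for o in members],
        index=members, columns=members,
    )
    rows, strong = [], []
    for owner in members:
        cognate = values[(owner, owner)]
        for member in members:
            if member == owner:
                continue
            cross = values[(owner, member)]
            if np.allclose(cognate, cross):
                p = 0.5
            else:
                p = float(stats.ttest_ind(cognate, cross, equal_var=False,
                                          alternative="less").pvalue)
            gap = float(cross.mean() - cognate.mean())
            rows.append({"owner": owner, "member": member, "p": p,
                         "delta_mfe": gap})
            strong.append({"owner": owner, "member": member,
                           "strong": gap > delta_strong})
    return FamilyComparison(
        family_id, members, mean, values,
        pd.DataFrame(rows), pd.DataFrame(strong),
    )


def positional_profiles(
    structures_by_member: dict[str, list], lmax: int | None = None
) -> pd.DataFrame:
    """Fraction of each member's interactions paired at each miRNA position."""
    out = {}
    for member, structures in sorted(structures_by_member.items()):
        L = max(len(s.pairing) for s in structures)
        frac = np.zeros(lmax or L)
        for s in structures:
            frac[: len(s.pairing)] += s.pairing
        out[member] = frac / len(structures)
    df = pd.DataFrame(out).T
    df.columns = [f"pos{p}" for p in range(2, df.shape[1] + 2)]
    return df


def family_motifs(
    member_seqs: dict[str, str],
    member_regions: dict[str, list[str]],
    background: list[str],
    lengths=(6, 8, 10, 12),
    top_n: int = 10,
) -> pd.DataFrame:
    """Member-specific enriched motifs vs a pooled AGO-bound background.

    Retained motifs are mapped to the member they complement; the display
    string is the motif's reverse complement so it reads along the miRNA.
    """
    rows = []
    for member, seq in sorted(member_seqs.items()):
        fg = member_regions.get(member, [])
        if not fg:
            continue
        for k in lengths:
            for res in discover_motifs(member, seq, fg, [background], k=k,
                                       top_n=top_n):
                if not res.retained:
                    continue
                rows.append({
                    "member": member, "k": k, "motif": res.consensus,
                    "display": revcomp(res.consensus),
                    "p": res.p, "s": res.s, "c": res.c,
                    "matched_offset": res.matched_offset,
                    "in_divergent_3p": res.matched_offset > 8,
                })
    return pd.DataFrame(rows)
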