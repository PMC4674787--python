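"""k-means discovery of miRNA-target binding classes from pairing profiles.

Rows of the structure matrix are binary pairing vectors over miRNA positions
2..Lmax; positions beyond a shorter miRNA's length are masked out of both
distance computation and centroid updates rather than imputed.  Classes are
relabelled by descending mean seed-region (positions 2-8) pairing so that
reported class numbers are stable across runs and row orders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class StructureMatrix:
    values: np.ndarray           # (n rows, p positions) float 0/1
    valid: np.ndarray            # (n, p) bool column mask per row
    row_ids: list[str]
    mirna_ids: list[str]
    positions: np.ndarray        # miRNA positions (2..Lmax)

    @classmethod
    def from_structures(cls, structures, mirna_ids):
        lmax = max(len(s.pairing) for s in structures)
        n = len(structures)
        values = np.zeros((n, lmax))
        valid = np.zeros((n, lmax), dtype=bool)
        for r, s in enumerate(structures):
            L = len(s.pairing)
            values[r, :L] = s.pairing
            valid[r, :L] = True
        ids = [s.interaction_id or f"row{r}" for r, s in enumerate(structures)]
        return cls(values, valid, ids, list(mirna_ids), np.arange(2, lmax + 2))


@dataclass
class ClassModel:
    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    rng_seed: int
    restarts: int


def _masked_distances(X, V, centroids):
    """Squared Euclidean distance over each row's valid columns."""
    XV = X * V
    d = (
        (XV**2).sum(axis=1)[:, None]
        - 2.0 * XV @ centroids.T
        + V @ (centroids**2).T
    )
    return np.maximum(d, 0.0)


def _lloyd(X, V, centroids, max_iter=100):
    k = centroids.shape[0]
    assign = None
    for _ in range(max_iter):
        d = _masked_distances(X, V, centroids)
        new_assign = d.argmin(axis=1)
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in range(k):
            rows = assign == c
            if not rows.any():
                continue
            w = V[rows].sum(axis=0)
            s = (X[rows] * V[rows]).sum(axis=0)
            nz = w > 0
            centroids[c, nz] = s[nz] / w[nz]
    d = _masked_distances(X, V, centroids)
    assign = d.argmin(axis=1)
    inertia = float(d[np.arange(len(X)), assign].sum())
    return centroids, assign, inertia


def _pp_init(X, V, k, rng):
    """k-means++ style seeding on masked distances."""
    n = X.shape[0]
    idx = [int(rng.integers(n))]
    for _ in range(1, k):
        C = X[idx]
        d = _masked_distances(X, V, C).min(axis=1)
        total = d.sum()
        if total <= 0:
            idx.append(int(rng.integers(n)))
            continue
        idx.append(int(rng.choice(n, p=d / total)))
    return X[idx].copy()


def kmeans_structures(
    matrix: StructureMatrix,
    k: int,
    rng_seed: int = 0,
    restarts: int = 50,
    init_centroids: np.ndarray | None = None,
) -> ClassModel:
    """Best-of-restarts masked Euclidean k-means, deterministic per seed.

    Classes are relabelled by descending mean pairing over seed positions
    2-8 before returning.
    """
    X, V = matrix.values, matrix.valid.astype(float)
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows ({n})")
    rng = np.random.default_rng(rng_seed)
    best = None
    starts = [_pp_init(X, V, k, rng) for _ in range(restarts)]
    if init_centroids is not None:
        starts.append(init_centroids.copy())
    for init in starts:
        c, a, inertia = _lloyd(X, V, init.copy())
        if best is None or inertia < best[2] - 1e-12:
            best = (c, a, inertia)
    centroids, assign, inertia = best
    seed_cols = matrix.positions <= 8
    order = np.argsort(-centroids[:, seed_cols].mean(axis=1), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return ClassModel(k, centroids[order], relabel[assign], inertia, rng_seed, restarts)


def sweep_k(
    matrix: StructureMatrix,
    k_range=range(3, 13),
    rng_seed: int = 0,
    restarts: int = 10,
) -> pd.DataFrame:
    """Inertia and mean silhouette across k; never auto-selects a k.

    Each k additionally restarts from the previous best centroids plus the
    worst-fit row, which guarantees inertia is non-increasing in k.
    """
    from sklearn.metrics import silhouette_score

    rows = []
    prev = None
    for k in k_range:
        init = None
        if prev is not None:
            d = _masked_distances(matrix.values, matrix.valid.astype(float),
                                  prev.centroids)
            worst = int(d.min(axis=1).argmax())
            init = np.vstack([prev.centroids, matrix.values[worst]])
        model = kmeans_structures(matrix, k, rng_seed, restarts, init_centroids=init)
        if 1 < k < len(matrix.row_ids):
            sil = float(silhouette_score(matrix.values, model.assignments))
        else:
            sil = float("nan")
        rows.append((k, model.inertia, sil))
        prev = model
    return pd.DataFrame(rows, columns=["k", "inertia", "silhouette"])


def mirna_class_enrichment(
    model: ClassModel,
    mirna_ids: list[str],
    min_sites: int = 50,
    alpha: float = 1e-3,
    bh_correct: bool = False,
):
    """Two-sided Fisher exact test of each miRNA's class distribution.

    For each (miRNA with >= min_sites interactions, class) the 2x2 table is
    [[a, b], [c, d]] with a = miRNA-and-class, b = miRNA-not-class,
    c = others-and-class, d = others-not-class.  No multiple-testing
    correction by default (fixed alpha threshold); Benjamini-Hochberg is
    available as an option.
    """
    mirna_ids = np.asarray(mirna_ids)
    assign = model.assignments
    n = len(assign)
    rows = []
    tested = []
    for mid in sorted(set(mirna_ids)):
        sel = mirna_ids == mid
        if sel.sum() < min_sites:
            continue
        tested.append(mid)
        for c in range(model.k):
            a = int((sel & (assign == c)).sum())
            b = int(sel.sum() - a)
            cc = int((~sel & (assign == c)).sum())
            d = n - a - b - cc
            odds, p = stats.fisher_exact([[a, b], [cc, d]], alternative="two-sided")
            rows.append({
                "mirna_id": mid, "class": c, "a": a, "b": b, "c": cc, "d": d,
                "odds_ratio": odds, "p": p,
                "direction": "enriched" if (a * d) > (b * cc) else "depleted",
            })
    df = pd.DataFrame(rows)
    if bh_correct and len(df):
        from statsmodels.stats.multitest import multipletests

        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    if len(df):
        sig = df[df.p < alpha].mirna_id.unique()
        frac = len(sig) / len(tested) if tested else float("nan")
    else:
        frac = float("nan")
    return df, {"tested_mirnas": len(tested), "significant_fraction": frac}


def export_clustered_matrix(matrix: StructureMatrix, model: ClassModel):
    """Row order for heat-map rendering: by class, then descending row sum."""
    order = np.lexsort((-matrix.values.sum(axis=1), model.assignments))
    return order, matrix.values[order]
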