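"""Functional-response statistics for miRNA perturbation experiments.

Consumes precomputed per-probe log2 fold-changes (microarray-style) or
normalized AGO-binding count matrices, builds the site-class gene sets used
for CDF comparisons, and tests each set against its control with two-sample
Kolmogorov-Smirnov statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CANONICAL_CLASSES = {"8mer", "7mer-m8", "7mer-A1", "6mer"}
SEVEN_EIGHT_MER = {"8mer", "7mer-m8", "7mer-A1"}


def collapse_probes(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe-level log2FC to gene level.

    Genes with sign-contradictory probes (both >0 and <0) are removed;
    remaining genes get the mean of their probes.  Idempotent.
    """
    if table.empty:
        raise ValueError("empty expression table")
    def ok(vals):
        return not ((vals > 0).any() and (vals < 0).any())
    grouped = table.groupby("gene_id")["log2fc"]
    keep = grouped.apply(ok)
    means = grouped.mean()
    out = means[keep[means.index]].reset_index()
    out.columns = ["gene_id", "log2fc"]
    return out


def cdf_compare(
    group: set, control: set, collapsed: pd.DataFrame
) -> dict:
    """Two-sample KS test of log2FC between a gene set and its control."""
    table = collapsed.set_index("gene_id")["log2fc"]
    g = table.reindex([x for x in group if x in table.index]).dropna().to_numpy()
    c = table.reindex([x for x in control if x in table.index]).dropna().to_numpy()
    if len(g) == 0 or len(c) == 0:
        raise ValueError("empty gene set after joining with expression table")
    if np.array_equal(np.sort(g), np.sort(c)):
        d, p = 0.0, 1.0
    else:
        d, p = stats.ks_2samp(g, c)
    def ecdf(v):
        x = np.sort(v)
        return x, np.arange(1, len(x) + 1) / len(x)
    return {"D": float(d), "p": float(p), "n_group": len(g), "n_control": len(c),
            "ecdf_group": ecdf(g), "ecdf_control": ecdf(c)}


@dataclass(frozen=True)
class SiteRecord:
    gene_id: str
    mirna_id: str
    seed_class: str
    n: int = 1
    peak_overlap: bool = False
    region_label: str = "three_prime_utr"


def build_site_sets(
    sites: list[SiteRecord], mode: str, focal_mirna: str
) -> dict[str, set]:
    """Named gene sets for CDF analysis.

    Modes: ``by_count`` (sites seen once vs multiple times),
    ``peak_overlap`` (with vs without non-chimeric peak support), and
    ``exclusive_canonical`` (transcripts with only canonical vs only
    non-canonical focal-miRNA sites; transcripts with both are excluded from
    both).  The control set is always genes with chimeras of other miRNAs
    and no focal-miRNA chimera.
    """
    focal = [s for s in sites if s.mirna_id == focal_mirna]
    focal_genes = {s.gene_id for s in focal}
    control = {s.gene_id for s in sites if s.mirna_id != focal_mirna} - focal_genes
    out: dict[str, set] = {"control": control}
    if mode == "by_count":
        multi = {s.gene_id for s in focal if s.n > 1}
        out["multiple"] = multi
        out["once"] = {s.gene_id for s in focal if s.n == 1} - multi
    elif mode == "peak_overlap":
        out["peak_supported"] = {s.gene_id for s in focal if s.peak_overlap}
        out["chimera_only"] = focal_genes - out["peak_supported"]
    elif mode == "exclusive_canonical":
        canon = {s.gene_id for s in focal if s.seed_class in CANONICAL_CLASSES}
        noncanon = {s.gene_id for s in focal if s.seed_class not in CANONICAL_CLASSES}
        out["canonical_only"] = canon - noncanon
        out["noncanonical_only"] = noncanon - canon
        out["bulged_8mer_only"] = {
            s.gene_id for s in focal if s.seed_class == "bulge_target_8mer"
        } & out["noncanonical_only"]
    else:
        raise ValueError(f"unknown site-set mode {mode!r}")
    return out


def binding_change_cdf(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    cluster_info: pd.DataFrame,
    min_bc: int = 4,
    min_density: float = 40.0,
    region: str | None = None,
) -> dict:
    """CDFs of per-cluster binding change (log2 treated/control) by site class.

    ``treated``/``control`` are pseudocounted normalized count matrices
    (clusters x libraries) from the interaction map; ``cluster_info`` needs
    columns cluster_id, BC, density, has_seed, has_chimera, region_label.
    Clusters with BC < min_bc or density < min_density are excluded; classes
    are seed-only, chimera-only, both, and neither (the control class), each
    KS-tested against the control class.
    """
    info = cluster_info.set_index("cluster_id")
    if region is not None:
        info = info[info.region_label == region]
    info = info[(info.BC >= min_bc) & (info.density >= min_density)]
    common = info.index.intersection(treated.index).intersection(control.index)
    info = info.loc[common]
    ratio = np.log2(treated.loc[common].mean(axis=1) / control.loc[common].mean(axis=1))
    cls = pd.Series("neither", index=common)
    cls[info.has_seed & ~info.has_chimera] = "seed_only"
    cls[~info.has_seed & info.has_chimera] = "chimera_only"
    cls[info.has_seed & info.has_chimera] = "both"
    out = {"n_clusters": len(common), "classes": {}}
    base = ratio[cls == "neither"].to_numpy()
    for name in ("seed_only", "chimera_only", "both", "neither"):
        vals = ratio[cls == name].to_numpy()
        entry = {"n": len(vals), "values": vals,
                 "median": float(np.median(vals)) if len(vals) else float("nan")}
        if name != "neither" and len(vals) and len(base):
            d, p = stats.ks_2samp(vals, base)
            entry.update({"D": float(d), "p": float(p)})
        out["classes"][name] = entry
    return out
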