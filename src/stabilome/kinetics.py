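"""Induction testing, temporal-switch summaries, expression-stability
association and hierarchical clustering of induction kinetics."""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .counts_io import Arm, CountMatrix, ExpressionMatrix, SampleSheet
from . import nbstats
from .stability import N_CLASSES, stabilome_composition

__all__ = [
    "tnf_induction_test",
    "build_induction_table",
    "temporal_switch_density",
    "top_expressed_stability",
    "mean_timecourse",
    "cluster_kinetics",
    "KineticClusters",
    "cluster_stability_composition",
]


def tnf_induction_test(counts: CountMatrix, sheet: SampleSheet,
                       time_h: float, min_counts: float = 100.0,
                       padj_threshold: float = 0.1,
                       sf: pd.Series | None = None) -> pd.DataFrame:
    """Stimulated vs unstimulated-control NB test at one time point.

    Genes are filtered on expression in the stimulated arm (mean raw
    counts > ``min_counts``).  Flags ``induced_2fold`` / ``induced_5fold``
    require the fold-change threshold together with BH-adjusted
    significance.
    """
    control = sheet.samples(Arm.CONTROL)
    tnf = sheet.samples(Arm.TNF, time_h)
    if not control:
        raise ValueError("no CONTROL samples in the design")
    if not tnf:
        raise ValueError(f"no stimulated samples at t={time_h:g} h")
    if sf is None:
        sf = nbstats.size_factors(counts)
    df = counts.counts
    keep = df[tnf].mean(axis=1) > min_counts
    sub = df.loc[keep]
    if sub.empty:
        raise ValueError("no genes pass the expression filter")
    res = nbstats.two_group_test(sub, control, tnf, sf)
    res["time_h"] = float(time_h)
    sig = (res["padj"] < padj_threshold) & res["converged"]
    res["induced_2fold"] = sig & (res["log2fc"] >= 1.0)
    res["induced_5fold"] = sig & (res["log2fc"] >= math.log2(5.0))
    return res


def build_induction_table(counts: CountMatrix, sheet: SampleSheet,
                          times: list[float] | None = None,
                          min_counts: float = 100.0,
                          padj_threshold: float = 0.1) -> pd.DataFrame:
    """Long-format induction table over all stimulated time points."""
    if times is None:
        times = [t for t in sheet.times(Arm.TNF) if t > 0]
    sf = nbstats.size_factors(counts)
    parts = [tnf_induction_test(counts, sheet, t, min_counts,
                                padj_threshold, sf=sf) for t in times]
    return pd.concat(parts).reset_index().set_index(["gene_id", "time_h"])


def temporal_switch_density(induction: pd.DataFrame, stability: pd.DataFrame,
                            time_h: float, fold_threshold: float = 2.0,
                            n_bins: int = 20) -> dict:
    """Stability distribution of genes induced at one time point.

    ``induction`` is a single-time induction frame (or the long table) and
    ``stability`` the per-gene stability frame at the same time point.
    Returns bin edges, a density over S in [0, 1], and the fractions of
    induced genes falling in class 1 (S < 0.2) and class 5 (S > 0.8).
    """
    ind = induction
    if isinstance(ind.index, pd.MultiIndex):
        ind = ind.xs(float(time_h), level="time_h")
    flag = ("induced_2fold" if fold_threshold <= 2.0 else "induced_5fold")
    if fold_threshold not in (2.0, 5.0):
        sig = (ind["padj"] < 0.1) & ind["converged"]
        induced = ind.index[sig & (ind["log2fc"] >= math.log2(fold_threshold))]
    else:
        induced = ind.index[ind[flag]]
    stab = stability[~stability["excluded"]]
    genes = stab.index.intersection(induced)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    if len(genes) == 0:
        warnings.warn(f"no induced genes with stability calls at "
                      f"t={time_h:g} h")
        return {"time_h": float(time_h), "n_genes": 0, "bin_edges": edges,
                "density": np.zeros(n_bins), "class1_fraction": np.nan,
                "class5_fraction": np.nan, "genes": []}
    s = stab.loc[genes, "S"].to_numpy()
    hist, _ = np.histogram(s, bins=edges)
    cls = stab.loc[genes, "stability_class"].to_numpy()
    return {
        "time_h": float(time_h),
        "n_genes": int(len(genes)),
        "bin_edges": edges,
        "density": hist / len(genes),
        "class1_fraction": float((cls == 1).mean()),
        "class5_fraction": float((cls == N_CLASSES).mean()),
        "genes": list(genes),
    }


def top_expressed_stability(expr: ExpressionMatrix, stability: pd.DataFrame,
                            sheet: SampleSheet, time_h: float,
                            top_fraction: float = 0.10) -> dict:
    """Stability-class composition of the most highly expressed genes.

    Genes with stability calls at ``time_h`` are ranked by mean
    stimulation-arm expression (ties broken by gene id); the top
    ``ceil(top_fraction * n)`` are summarized.  Also reports the unstable
    members (classes 1-2) of the top set with their expression ranks.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    tnf = sheet.samples(Arm.TNF, time_h)
    if not tnf:
        raise ValueError(f"no stimulated samples at t={time_h:g} h")
    stab = stability[~stability["excluded"]]
    if stab.empty:
        raise ValueError("no genes with stability calls")
    mean_expr = expr.values.loc[stab.index, tnf].mean(axis=1)
    ranked = mean_expr.to_frame("expression").reset_index()
    ranked = ranked.sort_values(by=["expression", "gene_id"],
                                ascending=[False, True])
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    n_top = math.ceil(top_fraction * len(ranked))
    top = ranked.head(n_top).set_index("gene_id")
    comp = stabilome_composition(stab.loc[top.index, "stability_class"])
    unstable = top.join(stab[["S", "stability_class"]])
    unstable = unstable[unstable["stability_class"] <= 2]
    return {
        "time_h": float(time_h),
        "n_top": n_top,
        "composition": comp,
        "top_genes": top,
        "unstable_members": unstable,
    }


def mean_timecourse(counts: CountMatrix, sheet: SampleSheet,
                    genes: list[str] | None = None,
                    sf: pd.Series | None = None) -> pd.DataFrame:
    """Mean normalized counts over the stimulation time course.

    Time 0 is taken from the unstimulated control arm; later time points
    from the stimulated arm.
    """
    if sf is None:
        sf = nbstats.size_factors(counts)
    norm = counts.counts.div(sf, axis=1)
    if genes is not None:
        norm = norm.loc[genes]
    cols = {}
    ctrl = sheet.samples(Arm.CONTROL)
    if ctrl:
        cols[0.0] = norm[ctrl].mean(axis=1)
    for t in sheet.times(Arm.TNF):
        cols[float(t)] = norm[sheet.samples(Arm.TNF, t)].mean(axis=1)
    return pd.DataFrame(cols)


@dataclass
class KineticClusters:
    """Cluster labels (1..k) plus per-cluster mean z-scored profiles."""

    labels: pd.Series
    profiles: pd.DataFrame  # k x times, mean z-scored profile per cluster
    k: int


def cluster_kinetics(timecourse: pd.DataFrame, k: int = 6) -> KineticClusters:
    """Hierarchical clustering of time-course shapes.

    Profiles are z-scored per gene, compared by correlation distance
    (1 - Pearson) with average linkage, and the tree is cut into ``k``
    clusters.  Clusters are renumbered by the peak time of their mean
    profile (earliest peak = cluster 1), so numbering is stable under gene
    reordering.
    """
    if len(timecourse) < k:
        raise ValueError(f"cannot form {k} clusters from "
                         f"{len(timecourse)} genes")
    vals = timecourse.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    flat = sd == 0
    if flat.any():
        raise ValueError("flat (zero-variance) profiles cannot be "
                         f"clustered: {list(timecourse.index[flat][:10])}")
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    if k == 1:
        labels = np.ones(len(timecourse), dtype=int)
    else:
        d = np.maximum(pdist(z, metric="correlation"), 0.0)
        labels = fcluster(linkage(d, method="average"), t=k,
                          criterion="maxclust")
    times = timecourse.columns.to_numpy(dtype=float)
    order_keys = []
    for lab in np.unique(labels):
        prof = z[labels == lab].mean(axis=0)
        order_keys.append((times[int(np.argmax(prof))], tuple(-prof), lab))
    remap = {old: new + 1
             for new, (_, _, old) in enumerate(sorted(order_keys))}
    new_labels = pd.Series([remap[l] for l in labels],
                           index=timecourse.index, name="cluster")
    profiles = pd.DataFrame(
        [z[new_labels.to_numpy() == c].mean(axis=0)
         for c in range(1, len(remap) + 1)],
        index=pd.RangeIndex(1, len(remap) + 1, name="cluster"),
        columns=timecourse.columns)
    return KineticClusters(labels=new_labels, profiles=profiles, k=k)


def cluster_stability_composition(clusters: KineticClusters,
                                  stability: pd.DataFrame,
                                  merge: list[tuple[int, ...]] | None = None
                                  ) -> pd.DataFrame:
    """Stability-class fractions per (optionally merged) cluster group."""
    stab = stability[~stability["excluded"]]
    missing = clusters.labels.index.difference(stab.index)
    if len(missing):
        warnings.warn(f"{len(missing)} clustered gene(s) lack stability "
                      "calls and were excluded")
    if merge is None:
        merge = [(c,) for c in range(1, clusters.k + 1)]
    rows = []
    for group in merge:
        genes = clusters.labels.index[clusters.labels.isin(group)]
        genes = genes.intersection(stab.index)
        name = "+".join(str(c) for c in group)
        if len(genes) == 0:
            rows.append(pd.Series(np.full(N_CLASSES, np.nan), name=name))
            continue
        comp = stabilome_composition(stab.loc[genes, "stability_class"])
        rows.append(pd.Series(comp["fraction"].to_numpy(), name=name))
    out = pd.DataFrame(rows)
    out.columns = [f"class_{i}" for i in range(1, N_CLASSES + 1)]
    out.index.name = "cluster_group"
    return out
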