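"""Stability ratios, five-class stabilome composition and differential
stabilization between early and late stimulation.

The per-time stability ratio of a gene is the replicate-mean expression in
the chase arm divided by the replicate-mean expression in the
stimulation-only arm; it is clipped to [0, 1] for classification into five
equal-width stability classes (class 1 = very unstable, class 5 = very
stable).

Differential stabilization between an early and a late time point is
tested with a dependent-ratio NB GLM: both arms share a time effect, the
chase arm carries its own intercept plus an interaction term that is zero
at the early time point; the interaction is assessed with a chi^2(1)
likelihood-ratio test and BH-adjusted.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .counts_io import Arm, CountMatrix, ExpressionMatrix, SampleSheet
from . import nbstats

__all__ = [
    "N_CLASSES",
    "CLASS_WIDTH",
    "stability_ratio",
    "classify_stability",
    "stabilome_composition",
    "actd_response_test",
    "two_step_stabilization_workflow",
    "differential_stability_test",
    "rank_stabilized",
    "build_diffstab_design",
]

N_CLASSES = 5
CLASS_WIDTH = 0.2


def classify_stability(s: np.ndarray | float) -> np.ndarray:
    """Map clipped stability ratios to classes 1..5 (bins of width 0.2).

    Class 1 covers [0, 0.2) (very unstable), class 5 covers [0.8, 1]
    (very stable).
    """
    s = np.clip(np.asarray(s, dtype=float), 0.0, 1.0)
    edges = np.array([0.2, 0.4, 0.6, 0.8])  # literal to keep 0.6 exact
    return np.digitize(s, edges, right=False) + 1


def stability_ratio(expr: ExpressionMatrix, sheet: SampleSheet,
                    time_h: float,
                    min_expression: float = 0.0) -> pd.DataFrame:
    """Per-gene stability ratio at one stimulation time point.

    S = mean(chase arm) / mean(stimulation arm); the raw value is retained
    and a [0, 1]-clipped copy is classified.  Genes whose stimulation-arm
    mean is zero (or below ``min_expression``) are flagged excluded.
    """
    tnf = sheet.samples(Arm.TNF, time_h)
    actd = sheet.samples(Arm.TNF_ACTD, time_h)
    if not tnf or not actd:
        raise ValueError(
            f"both arms required at t={time_h:g} h "
            f"(TNF n={len(tnf)}, chase n={len(actd)})"
        )
    vals = expr.values
    tnf_mean = vals[tnf].mean(axis=1)
    actd_mean = vals[actd].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s_raw = actd_mean / tnf_mean
    excluded = tnf_mean <= max(min_expression, 0.0)
    reason = np.where(tnf_mean == 0, "zero expression in stimulation arm",
                      np.where(excluded, "below expression filter", ""))
    s_clip = np.clip(np.where(excluded, np.nan, s_raw), 0.0, 1.0)
    cls = np.where(excluded, 0, classify_stability(np.nan_to_num(s_clip)))
    out = pd.DataFrame({
        "time_h": float(time_h),
        "S_raw": np.where(excluded, np.nan, s_raw),
        "S": s_clip,
        "stability_class": cls.astype(int),
        "excluded": excluded,
        "reason": reason,
    }, index=vals.index)
    out.index.name = "gene_id"
    return out


def stabilome_composition(classes: pd.Series | np.ndarray) -> pd.DataFrame:
    """Counts and fractions of the five stability classes.

    Zero class labels (excluded genes) must be filtered by the caller.
    """
    cls = np.asarray(classes, dtype=int)
    cls = cls[cls > 0]
    if cls.size == 0:
        raise ValueError("no classified genes")
    counts = np.bincount(cls, minlength=N_CLASSES + 1)[1:]
    return pd.DataFrame({
        "stability_class": np.arange(1, N_CLASSES + 1),
        "n_genes": counts,
        "fraction": counts / counts.sum(),
    }).set_index("stability_class")


def actd_response_test(counts: CountMatrix, sheet: SampleSheet,
                       time_h: float, min_counts: float = 100.0,
                       padj_threshold: float = 0.1,
                       sf: pd.Series | None = None) -> pd.DataFrame:
    """Two-group NB test of the chase arm against the stimulation arm.

    Genes whose mean raw count over the stimulation-arm samples at
    ``time_h`` is <= ``min_counts`` are dropped before testing.  Returns
    log2 fold change (chase vs stimulation), LRT statistic, p, BH-adjusted
    p and a ``significant_down`` flag at the given threshold.
    """
    tnf = sheet.samples(Arm.TNF, time_h)
    actd = sheet.samples(Arm.TNF_ACTD, time_h)
    if len(tnf) < 2 or len(actd) < 2:
        raise ValueError(
            f"need >= 2 replicates per arm at t={time_h:g} h "
            f"(TNF n={len(tnf)}, chase n={len(actd)})"
        )
    if sf is None:
        sf = nbstats.size_factors(counts)
    df = counts.counts
    keep = df[tnf].mean(axis=1) > min_counts
    sub = df.loc[keep]
    if sub.empty:
        raise ValueError("no genes pass the expression filter")
    res = nbstats.two_group_test(sub, tnf, actd, sf)
    res["significant_down"] = ((res["padj"] < padj_threshold)
                               & (res["log2fc"] < 0) & res["converged"])
    return res


def two_step_stabilization_workflow(counts: CountMatrix, sheet: SampleSheet,
                                    early_h: float = 1.0,
                                    late_h: float = 72.0,
                                    min_counts: float = 100.0,
                                    padj_threshold: float = 0.1) -> dict:
    """Two-step identification of stabilized vs destabilized transcripts.

    Step 1: genes significantly down-regulated by the chase at the early
    time point (unstable candidates).  Step 2: among those still expressed
    at the late time point, compare chase log2 fold changes — a fold change
    moving toward 0 marks stabilization, away from 0 destabilization.

    Both variants of step 2 are reported: sign-only (fold-change
    comparison) and significance-filtered (late chase response must itself
    be significant for the destabilized call).
    """
    early = actd_response_test(counts, sheet, early_h, min_counts,
                               padj_threshold)
    late_all = actd_response_test(counts, sheet, late_h, min_counts,
                                  padj_threshold)
    step1 = early.index[early["significant_down"]]
    expressed_late = step1.intersection(late_all.index)
    dropped = step1.difference(late_all.index)

    tab = pd.DataFrame({
        "log2fc_early": early.loc[expressed_late, "log2fc"],
        "log2fc_late": late_all.loc[expressed_late, "log2fc"],
        "padj_late": late_all.loc[expressed_late, "padj"],
    })
    tab["stabilized"] = tab["log2fc_late"] > tab["log2fc_early"]
    tab["destabilized"] = tab["log2fc_late"] < tab["log2fc_early"]
    sig_late = late_all.loc[expressed_late, "significant_down"]
    tab["stabilized_sigfilter"] = tab["stabilized"]
    tab["destabilized_sigfilter"] = tab["destabilized"] & sig_late
    tab.index.name = "gene_id"
    return {
        "early_test": early,
        "late_test": late_all,
        "actd_down_early": list(step1),
        "dropped_not_expressed_late": list(dropped),
        "table": tab,
        "stabilized": list(tab.index[tab["stabilized"]]),
        "destabilized": list(tab.index[tab["destabilized"]]),
    }


def build_diffstab_design(sheet_rows: pd.DataFrame, early_h: float,
                          late_h: float) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Design matrices for the dependent-ratio GLM.

    Alternative model columns: stimulation-arm intercept, chase-arm
    intercept, shared late-time effect, and the chase x late interaction
    (constrained to 0 at the early time point); the null model drops the
    interaction.
    """
    arm = sheet_rows["arm"].to_numpy()
    t = sheet_rows["time_h"].to_numpy()
    tnf = (arm == Arm.TNF.value).astype(float)
    actd = (arm == Arm.TNF_ACTD.value).astype(float)
    late = (t == float(late_h)).astype(float)
    X_alt = np.column_stack([tnf, actd, late, actd * late])
    names = ("beta_tnf", "beta_tnf_actd", "beta_time", "beta_delta")
    return X_alt, X_alt[:, :3], names


def differential_stability_test(counts: CountMatrix, sheet: SampleSheet,
                                early_h: float = 1.0, late_h: float = 72.0,
                                min_norm_counts: float = 10.0,
                                padj_threshold: float = 0.1,
                                pseudocount: float = 0.5) -> pd.DataFrame:
    """Dependent-ratio NB GLM test of differential mRNA stabilization.

    Per gene, a null model (no chase x time interaction, 3 parameters) and
    an alternative model (4 parameters) are fitted to the four design
    cells (two arms x early/late) with log size-factor offsets and the
    trended gene dispersion; the LRT follows chi^2(1) and is BH-adjusted.
    Genes with mean normalized stimulation-arm counts below
    ``min_norm_counts`` at either time point are excluded.

    Returns one row per tested gene: ``beta_delta`` (natural log),
    ``stabilization_degree`` = log2(S_late / S_early) from
    pseudocount-stabilized normalized means, ``stat``, ``pvalue``,
    ``padj`` and a ``direction`` label.
    """
    if float(early_h) == float(late_h):
        raise ValueError("early and late time points must differ")
    cells = {}
    for t, name in ((early_h, "early"), (late_h, "late")):
        for arm, aname in ((Arm.TNF, "tnf"), (Arm.TNF_ACTD, "actd")):
            ids = sheet.samples(arm, t)
            if len(ids) < 2:
                raise ValueError(
                    f"need >= 2 replicates in cell ({arm.value}, {t:g} h), "
                    f"found {len(ids)}"
                )
            cells[f"{aname}_{name}"] = ids

    sf = nbstats.size_factors(counts)  # joint, across all libraries
    df = counts.counts
    used = [s for ids in cells.values() for s in ids]
    norm = df[used].div(sf.loc[used], axis=1)

    tnf_early = norm[cells["tnf_early"]].mean(axis=1)
    tnf_late = norm[cells["tnf_late"]].mean(axis=1)
    actd_early = norm[cells["actd_early"]].mean(axis=1)
    actd_late = norm[cells["actd_late"]].mean(axis=1)
    keep = (tnf_early >= min_norm_counts) & (tnf_late >= min_norm_counts)

    excluded = pd.DataFrame({
        "reason": np.where(
            tnf_early[~keep] < min_norm_counts,
            "normalized stimulation-arm counts below filter at early time",
            "normalized stimulation-arm counts below filter at late time"),
    }, index=df.index[~keep])

    sub_sheet = sheet.table[sheet.table["sample_id"].isin(used)]
    sub_sheet = sub_sheet.set_index("sample_id").loc[used].reset_index()
    disp_sheet = SampleSheet(sub_sheet.copy())
    sub = df.loc[keep, used]
    if sub.empty:
        raise ValueError("no genes pass the normalized-count filter")
    dm = nbstats.estimate_dispersion(sub, disp_sheet, sf)

    X_alt, X_null, names = build_diffstab_design(sub_sheet, early_h, late_h)
    Y = sub.to_numpy(dtype=float)
    offs = np.log(sf.loc[used].to_numpy(dtype=float))
    alpha = dm.fitted.to_numpy(dtype=float)

    fit0 = nbstats.fit_nb_glm_batch(Y, X_null, alpha, offs)
    fit1 = nbstats.fit_nb_glm_batch(Y, X_alt, alpha, offs)
    converged = fit0["converged"] & fit1["converged"]
    stat = np.maximum(2.0 * (fit1["loglik"] - fit0["loglik"]), 0.0)
    pval = chi2.sf(stat, 1)

    s_early = (actd_early.loc[sub.index] + pseudocount) \
        / (tnf_early.loc[sub.index] + pseudocount)
    s_late = (actd_late.loc[sub.index] + pseudocount) \
        / (tnf_late.loc[sub.index] + pseudocount)
    degree = np.log2(s_late / s_early)

    out = pd.DataFrame({
        "beta_delta": fit1["coef"][:, 3],
        "stabilization_degree": degree,
        "S_early": s_early,
        "S_late": s_late,
        "loglik_null": fit0["loglik"],
        "loglik_alt": fit1["loglik"],
        "stat": stat,
        "pvalue": pval,
        "converged": converged,
    }, index=sub.index)
    n_bad = int((~converged).sum())
    if n_bad:
        warnings.warn(f"{n_bad} gene(s) with non-convergent GLM fits "
                      "excluded from testing")
    out = out[out["converged"]].copy()
    out["padj"] = nbstats.bh_adjust(out["pvalue"].to_numpy())
    sig = out["padj"] < padj_threshold
    out["direction"] = np.where(
        sig & (out["stabilization_degree"] > 0), "stabilized",
        np.where(sig & (out["stabilization_degree"] < 0), "destabilized",
                 "unchanged"))
    out.index.name = "gene_id"
    out.attrs["excluded"] = excluded
    return out


def rank_stabilized(results: pd.DataFrame, top_n: int | None = None) -> pd.DataFrame:
    """Rank by stabilization degree (desc), ties by padj then gene id."""
    tab = results.reset_index().sort_values(
        by=["stabilization_degree", "padj", "gene_id"],
        ascending=[False, True, True]).set_index("gene_id")
    if top_n is not None:
        if top_n > len(tab):
            warnings.warn(
                f"top_n={top_n} exceeds table size {len(tab)}; "
                "returning the full table")
        tab = tab.head(top_n)
    return tab
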