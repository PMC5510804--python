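"""Synthetic transcription-shutoff chase RNA-seq datasets with known truth.

Emulates the study design the pipeline targets: a cytokine-stimulation time
course (default 0, 1, 3, 24, 72 h) with two replicates, a chase arm in which
transcription is arrested for a fixed interval at every stimulated time
point, and an unstimulated control at time 0.  Counts are NB distributed
with a mean-dependent dispersion trend; each gene carries an induction-fold
profile and a per-time first-order decay rate, so the expected stability
ratio at time t is exp(-lambda(t) * t_chase).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counts_io import Arm, CountMatrix, SampleSheet

__all__ = [
    "SimulationDesign",
    "DEFAULT_ARCHETYPES",
    "DEFAULT_MIXTURE",
    "make_truth",
    "simulate_counts",
    "expected_stability",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Layout of the simulated experiment."""

    times: tuple[float, ...] = (0.0, 1.0, 3.0, 24.0, 72.0)
    t_chase: float = 3.0
    n_replicates: int = 2
    library_size_factors: Mapping[str, float] | None = None
    transcription_leak: float = 0.0  # fraction of transcription continuing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.t_chase <= 0:
            raise ValueError("chase duration must be positive")
        if not 0.0 <= self.transcription_leak < 1.0:
            raise ValueError("transcription leak must be in [0, 1)")
        if 0.0 not in self.times:
            raise ValueError("time course must include time 0")

    @property
    def chase_times(self) -> tuple[float, ...]:
        return tuple(t for t in self.times if t > 0)

    def sample_layout(self) -> pd.DataFrame:
        rows = []
        for r in range(1, self.n_replicates + 1):
            rows.append((f"ctrl_r{r}", 0.0, Arm.CONTROL.value, r))
        for t in self.chase_times:
            for r in range(1, self.n_replicates + 1):
                rows.append((f"tnf_{t:g}h_r{r}", t, Arm.TNF.value, r))
            for r in range(1, self.n_replicates + 1):
                rows.append((f"actd_{t:g}h_r{r}", t, Arm.TNF_ACTD.value, r))
        return pd.DataFrame(rows, columns=["sample_id", "time_h", "arm",
                                           "replicate"])


# Archetype profiles over the default stimulated time points.  ``fold`` is
# the induction relative to unstimulated baseline; ``stability`` the true
# chase/no-chase ratio S(t).  The early-transient program is strongly
# induced at 1 h and unstable; late-sustained genes rise to the last time
# point and carry very stable transcripts; intermediate genes peak in the
# middle at modest stability; constitutive genes are unchanging and mostly
# stable; silent genes are essentially unexpressed.
DEFAULT_ARCHETYPES: dict[str, dict[str, dict[float, float]]] = {
    "early_transient": {
        "fold": {1.0: 8.0, 3.0: 3.0, 24.0: 1.2, 72.0: 1.0},
        "stability": {1.0: 0.08, 3.0: 0.12, 24.0: 0.25, 72.0: 0.3},
    },
    "intermediate": {
        "fold": {1.0: 1.3, 3.0: 4.0, 24.0: 6.0, 72.0: 1.5},
        "stability": {1.0: 0.45, 3.0: 0.5, 24.0: 0.55, 72.0: 0.6},
    },
    "late_sustained": {
        "fold": {1.0: 1.0, 3.0: 1.6, 24.0: 4.0, 72.0: 9.0},
        "stability": {1.0: 0.55, 3.0: 0.65, 24.0: 0.88, 72.0: 0.93},
    },
    "constitutive": {
        "fold": {1.0: 1.0, 3.0: 1.0, 24.0: 1.0, 72.0: 1.0},
        "stability": {1.0: 0.88, 3.0: 0.88, 24.0: 0.88, 72.0: 0.88},
    },
    "silent": {
        "fold": {1.0: 1.0, 3.0: 1.0, 24.0: 1.0, 72.0: 1.0},
        "stability": {1.0: 0.5, 3.0: 0.5, 24.0: 0.5, 72.0: 0.5},
    },
}

DEFAULT_MIXTURE: dict[str, float] = {
    "constitutive": 0.60,
    "early_transient": 0.10,
    "intermediate": 0.10,
    "late_sustained": 0.15,
    "silent": 0.05,
}


def _interp_profile(profile: Mapping[float, float],
                    times: Sequence[float]) -> np.ndarray:
    """Log-time interpolation of an archetype profile onto chase times."""
    keys = np.array(sorted(profile))
    vals = np.array([profile[k] for k in keys])
    return np.interp(np.log(np.asarray(times)), np.log(keys), vals)


def make_truth(n_genes: int,
               mixture: Mapping[str, float] | None = None,
               seed: int = 0,
               design: SimulationDesign | None = None,
               archetypes: Mapping[str, dict] | None = None,
               basal_range: tuple[float, float] = (5.0, 5000.0),
               stabilized_fraction: float = 0.0,
               stabilized_s: tuple[float, float] = (0.1, 0.8),
               disp_trend: tuple[float, float] = (0.02, 2.0),
               disp_noise_sd: float = 0.25,
               fold_noise_sd: float = 0.15,
               stability_logit_sd: float = 0.15) -> pd.DataFrame:
    """Draw per-gene generative parameters.

    Returns a frame with one row per gene: archetype, basal mean,
    dispersion, and per-stimulated-time induction fold, true stability
    S(t) and decay rate lambda(t) = -ln S(t) / t_chase.  A
    ``stabilized_fraction`` of non-silent genes gets its stability profile
    replaced by a log-time ramp from ``stabilized_s[0]`` at the first
    stimulated time to ``stabilized_s[1]`` at the last, modelling
    stimulus-induced transcript stabilization.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    design = design or SimulationDesign(seed=seed)
    archetypes = dict(archetypes or DEFAULT_ARCHETYPES)
    mixture = dict(mixture or DEFAULT_MIXTURE)
    unknown = set(mixture) - set(archetypes)
    if unknown:
        raise ValueError(f"mixture names unknown archetypes: {sorted(unknown)}")
    fracs = np.array([mixture.get(a, 0.0) for a in archetypes], dtype=float)
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-8:
        raise ValueError("mixture fractions must be >= 0 and sum to 1")
    if not 0.0 <= stabilized_fraction <= 1.0:
        raise ValueError("stabilized_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    names = list(archetypes)
    labels = rng.choice(len(names), size=n_genes, p=fracs)
    times = np.array(design.chase_times)
    nt = times.size

    lo, hi = basal_range
    basal = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    silent = np.array([names[i] == "silent" for i in labels])
    basal[silent] = rng.uniform(0.01, 0.3, size=int(silent.sum()))

    a0, a1 = disp_trend
    disp = (a0 + a1 / np.maximum(basal, 1e-3)) * np.exp(
        rng.normal(0.0, disp_noise_sd, size=n_genes))

    fold = np.ones((n_genes, nt))
    s_true = np.empty((n_genes, nt))
    for i, name in enumerate(names):
        rows = labels == i
        if not rows.any():
            continue
        fold[rows] = _interp_profile(archetypes[name]["fold"], times)
        s_true[rows] = _interp_profile(archetypes[name]["stability"], times)
    induced = fold > 1.0
    fold = np.where(induced,
                    fold * np.exp(rng.normal(0.0, fold_noise_sd, fold.shape)),
                    fold)
    logit = np.log(s_true / (1.0 - s_true))
    logit += rng.normal(0.0, stability_logit_sd, s_true.shape)
    s_true = np.clip(1.0 / (1.0 + np.exp(-logit)), 1e-3, 1.0 - 1e-3)

    stabilized = np.zeros(n_genes, dtype=bool)
    n_stab = int(round(stabilized_fraction * n_genes))
    if n_stab:
        candidates = np.flatnonzero(~silent)
        chosen = rng.choice(candidates, size=min(n_stab, candidates.size),
                            replace=False)
        stabilized[chosen] = True
        ramp = ((np.log(times) - np.log(times[0]))
                / (np.log(times[-1]) - np.log(times[0])))
        s_ramp = np.exp(np.log(stabilized_s[0])
                        + ramp * (np.log(stabilized_s[1])
                                  - np.log(stabilized_s[0])))
        s_true[stabilized] = s_ramp

    lam = -np.log(s_true) / design.t_chase
    data = {
        "gene_id": [f"g{i:05d}" for i in range(n_genes)],
        "archetype": [names[i] for i in labels],
        "stabilized": stabilized,
        "basal_mean": basal,
        "dispersion": disp,
    }
    for j, t in enumerate(times):
        data[f"fold_{t:g}h"] = fold[:, j]
    for j, t in enumerate(times):
        data[f"s_true_{t:g}h"] = s_true[:, j]
    for j, t in enumerate(times):
        data[f"lambda_{t:g}h"] = lam[:, j]
    return pd.DataFrame(data).set_index("gene_id")


def _truth_arrays(truth: pd.DataFrame,
                  design: SimulationDesign) -> tuple[np.ndarray, np.ndarray]:
    times = design.chase_times
    fold = np.column_stack([truth[f"fold_{t:g}h"].to_numpy() for t in times])
    lam = np.column_stack([truth[f"lambda_{t:g}h"].to_numpy() for t in times])
    return fold, lam


def expected_stability(truth: pd.DataFrame,
                       design: SimulationDesign) -> pd.DataFrame:
    """True stability ratio S(t) = exp(-lambda(t) * t_chase) per gene/time."""
    _, lam = _truth_arrays(truth, design)
    s = np.exp(-lam * design.t_chase)
    return pd.DataFrame(s, index=truth.index,
                        columns=[f"{t:g}" for t in design.chase_times])


def simulate_counts(truth: pd.DataFrame,
                    design: SimulationDesign) -> tuple[CountMatrix, SampleSheet]:
    """Draw NB counts for the full design; fully determined by the seed.

    Expected stimulation-arm count = sf * basal * fold(t); expected
    chase-arm count additionally decays by leak + (1-leak)*exp(-lambda(t) *
    t_chase).  Dispersion 0 falls back to Poisson sampling.
    """
    layout = design.sample_layout()
    sf = pd.Series(1.0, index=layout["sample_id"])
    if design.library_size_factors is not None:
        for k, v in design.library_size_factors.items():
            if k not in sf.index:
                raise KeyError(f"unknown sample in library_size_factors: {k}")
            if v <= 0:
                raise ValueError("library size factors must be positive")
            sf[k] = float(v)

    fold, lam = _truth_arrays(truth, design)
    basal = truth["basal_mean"].to_numpy(dtype=float)
    disp = truth["dispersion"].to_numpy(dtype=float)
    leak = design.transcription_leak
    times = list(design.chase_times)

    mu = np.empty((truth.shape[0], len(layout)))
    for j, row in layout.iterrows():
        s = sf[row["sample_id"]]
        if row["arm"] == Arm.CONTROL.value:
            mu[:, j] = s * basal
        else:
            ti = times.index(row["time_h"])
            m = s * basal * fold[:, ti]
            if row["arm"] == Arm.TNF_ACTD.value:
                m = m * (leak + (1.0 - leak)
                         * np.exp(-lam[:, ti] * design.t_chase))
            mu[:, j] = m

    rng = np.random.default_rng(design.seed)
    counts = np.zeros_like(mu, dtype=np.int64)
    overdispersed = disp > 0
    if overdispersed.any():
        k = disp[overdispersed][:, None]
        m = mu[overdispersed]
        counts[overdispersed] = rng.negative_binomial(
            n=1.0 / k, p=1.0 / (1.0 + k * m))
    if (~overdispersed).any():
        counts[~overdispersed] = rng.poisson(mu[~overdispersed])

    cm = CountMatrix(pd.DataFrame(counts, index=truth.index,
                                  columns=layout["sample_id"].tolist()))
    return cm, SampleSheet(layout)


def simulate_dataset(n_genes: int, seed: int = 0,
                     design: SimulationDesign | None = None,
                     **truth_kwargs) -> tuple[CountMatrix, SampleSheet, pd.DataFrame]:
    """Convenience wrapper: truth + counts + sheet from one seed."""
    design = design or SimulationDesign(seed=seed)
    truth = make_truth(n_genes, seed=seed, design=design, **truth_kwargs)
    counts, sheet = simulate_counts(truth, design)
    return counts, sheet, truth
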