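import numpy as np
import pandas as pd
import pytest

from stabilome.counts_io import CountMatrix, SampleSheet


def nb_draw(rng, mean, k):
    """NB counts with variance mean + k*mean^2 (Poisson when k == 0)."""
    mean = np.asarray(mean, dtype=float)
    k = np.broadcast_to(np.asarray(k, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    over = k > 0
    if over.any():
        out[over] = rng.negative_binomial(1.0 / k[over],
                                          1.0 / (1.0 + k[over] * mean[over]))
    if (~over).any():
        out[~over] = rng.poisson(mean[~over])
    return out


def two_time_dataset(basal, disp, s_early, s_late, seed=0,
                     early_h=1.0, late_h=72.0, n_rep=2):
    """Four-cell chase dataset (two arms x early/late) from given truth.

    All arrays are per-gene; the stimulation-arm mean is ``basal`` at both
    times and the chase-arm mean is basal * S(t).
    """
    rng = np.random.default_rng(seed)
    basal = np.asarray(basal, dtype=float)
    rows, cols = [], {}
    for t, s in ((early_h, np.asarray(s_early)), (late_h, np.asarray(s_late))):
        for arm, pref, factor in (("TNF", "tnf", 1.0), ("TNF_ACTD", "actd", s)):
            for r in range(1, n_rep + 1):
                sid = f"{pref}_{t:g}h_r{r}"
                cols[sid] = nb_draw(rng, basal * factor, disp)
                rows.append((sid, t, arm, r))
    genes = [f"g{i:04d}" for i in range(len(basal))]
    cm = CountMatrix(pd.DataFrame(cols, index=genes))
    sheet = SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "time_h", "arm", "replicate"]))
    return cm, sheet


@pytest.fixture(scope="session")
def small_dataset():
    """300-gene default-mixture simulated dataset shared across tests."""
    from stabilome.synthetic import simulate_dataset

    counts, sheet, truth = simulate_dataset(300, seed=42)
    return counts, sheet, truth
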