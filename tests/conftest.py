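import numpy as np
import pytest

from sglife.quant import IntensityMatrix, ProteinRecord, SampleDesign

TIMECOURSE = ["HS0", "HS10", "HS20", "HS30", "HS60", "HS120", "HS180", "Re5", "Re10"]


def make_matrix(
    log2_profiles: np.ndarray,
    bait: str = "CAPRIN1",
    replicates: int = 3,
    noise_sd: float = 0.0,
    batch_shift=None,
    with_sgls: bool = False,
    seed: int = 0,
    labels=None,
) -> IntensityMatrix:
    """Matrix from per-protein log2 label profiles, replicated with optional
    per-replicate shifts and i.i.d. log2 noise."""
    rng = np.random.default_rng(seed)
    labels = list(labels) if labels is not None else list(TIMECOURSE)
    if with_sgls:
        labels = labels + ["SGls"]
    prof = np.asarray(log2_profiles, dtype=float)
    n = prof.shape[0]
    assert prof.shape[1] == len(labels)
    shift = np.zeros(replicates) if batch_shift is None else np.asarray(batch_shift, float)
    samples, cols = [], []
    for rep in range(1, replicates + 1):
        for j, lab in enumerate(labels):
            samples.append(SampleDesign(f"{bait}_{lab}_r{rep}", lab, rep, bait))
            cols.append(prof[:, j] + shift[rep - 1] + rng.normal(0, noise_sd, n))
    records = [ProteinRecord(f"P{i:04d}", f"G{i}") for i in range(n)]
    return IntensityMatrix(records, samples, 2.0 ** np.column_stack(cols))


@pytest.fixture
def flat_matrix():
    rng = np.random.default_rng(3)
    base = rng.normal(20, 1, size=50)
    prof = np.tile(base[:, None], (1, 9))
    return make_matrix(prof, seed=3)
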