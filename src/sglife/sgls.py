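"""SG-like-condensate (SG-ls) enrichment score.

SG-ls granules form in unstressed cells overexpressing G3BP1; comparing a
protein's SG-ls abundance with its peak abundance across the heat-shock
course separates stress-independent recruitment (positive score) from
stress-dependent recruitment (negative score).

Per protein (G3BP1 pull-down dataset):

    ratio     = mean(SG-ls replicates) / max over HS10..Re10 of replicate means
    log_ratio = log2(ratio)
    z         = cohort-standardized log_ratio

The log transform centers the fold changes around 0 before unit-variance
scaling, so the z-score's sign is interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .quant import HS_WINDOW_LABELS, IntensityMatrix

__all__ = ["SGlsScore", "sgls_scores"]


@dataclass(frozen=True)
class SGlsScore:
    protein: str
    ratio: float
    log_ratio: float
    z: float
    degenerate: bool = False


def sgls_scores(
    m: IntensityMatrix,
    cohort: Iterable[str] | None = None,
    denominator: str = "window_max",
) -> tuple[list[SGlsScore], list[str]]:
    """SG-ls enrichment z-scores over a cohort of proteins.

    ``denominator='window_max'`` compares SG-ls with the HS10..Re10 peak
    (the primary score); ``'hs0'`` compares with the unstressed control
    instead. Proteins without an SG-ls measurement or with a non-positive
    denominator are excluded and returned in the second element.
    """
    if "SGls" not in {s.time_label for s in m.samples}:
        raise ValueError("matrix has no SG-ls samples (G3BP1 dataset required)")
    cohort_set = set(cohort) if cohort is not None else set(m.accessions)

    means = m.time_label_means(["HS0", "SGls", *HS_WINDOW_LABELS])
    excluded: list[str] = []
    prots: list[str] = []
    log_ratios: list[float] = []
    for acc in means.index:
        if acc not in cohort_set:
            continue
        sgls = means.at[acc, "SGls"]
        if denominator == "window_max":
            denom = means.loc[acc, list(HS_WINDOW_LABELS)].to_numpy(dtype=float).max()
        elif denominator == "hs0":
            denom = float(means.at[acc, "HS0"])
        else:
            raise ValueError(f"unknown denominator {denominator!r}")
        if not np.isfinite(sgls) or sgls <= 0 or not np.isfinite(denom) or denom <= 0:
            excluded.append(acc)
            continue
        prots.append(acc)
        log_ratios.append(float(np.log2(sgls / denom)))

    lr = np.asarray(log_ratios)
    degenerate = False
    if lr.size == 0:
        return [], excluded
    sd = lr.std(ddof=1) if lr.size > 1 else 0.0
    if not np.isfinite(sd) or sd < 1e-12 * max(1.0, float(np.abs(lr).max())):
        z = np.zeros_like(lr)
        degenerate = True
    else:
        z = (lr - lr.mean()) / sd
    scores = [
        SGlsScore(protein=p, ratio=float(2.0**l), log_ratio=float(l), z=float(zz),
                  degenerate=degenerate)
        for p, l, zz in zip(prots, lr, z)
    ]
    return scores, excluded
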