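"""Fold-change rule separating dynamic from invariable stress-granule proteins.

For each protein the replicate-mean intensity is computed at every time label;
two fold changes are then taken against the unstressed HS0 control over the
HS10..Re10 window:

* ``fc_up``   = max(window means) / mean(HS0)   ("max/Ctrl")
* ``fc_down`` = mean(HS0) / min(window means)   ("Ctrl/min")

A protein is *dynamic* when either fold change strictly exceeds the threshold
(default 1.2) in **both** pull-down datasets (G3BP1 and CAPRIN1); otherwise it
is *invariable*. SG-ls channels never enter the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant import HS_WINDOW_LABELS, IntensityMatrix

__all__ = ["FoldChangeResult", "DynamicCall", "fold_changes", "classify_dynamic"]


@dataclass(frozen=True)
class FoldChangeResult:
    protein: str
    fc_up: float
    fc_down: float
    bait: str


@dataclass(frozen=True)
class DynamicCall:
    protein: str
    label: str  # "dynamic" | "invariable"
    passing_rule_g3bp1: str  # "up" | "down" | "both" | "none"
    passing_rule_caprin1: str


def fold_changes(m: IntensityMatrix, bait: str) -> tuple[list[FoldChangeResult], list[str]]:
    """Per-protein max/Ctrl and Ctrl/min fold changes for one pull-down dataset.

    Returns the computable results and the accessions excluded because their
    HS0 mean was non-positive (or window means were unusable).
    """
    cols_ok = [s.bait for s in m.samples]
    if bait not in cols_ok:
        raise ValueError(f"matrix has no samples for bait {bait!r}")
    sub_idx = [i for i, s in enumerate(m.samples) if s.bait == bait]
    sub = IntensityMatrix(
        records=list(m.records),
        samples=[m.samples[i] for i in sub_idx],
        values=m.values[:, sub_idx],
    )
    means = sub.time_label_means(["HS0", *HS_WINDOW_LABELS])
    results: list[FoldChangeResult] = []
    excluded: list[str] = []
    window = means[list(HS_WINDOW_LABELS)].to_numpy()
    ctrl = means["HS0"].to_numpy()
    for i, acc in enumerate(means.index):
        c, w = ctrl[i], window[i]
        if not np.isfinite(c) or c <= 0 or not np.all(np.isfinite(w)) or np.any(w <= 0):
            excluded.append(acc)
            continue
        results.append(FoldChangeResult(
            protein=acc, fc_up=float(w.max() / c), fc_down=float(c / w.min()), bait=bait,
        ))
    return results, excluded


def _rule(fc: FoldChangeResult, threshold: float) -> str:
    up = fc.fc_up > threshold
    down = fc.fc_down > threshold
    if up and down:
        return "both"
    if up:
        return "up"
    if down:
        return "down"
    return "none"


def classify_dynamic(
    fc_g3bp1: list[FoldChangeResult],
    fc_caprin1: list[FoldChangeResult],
    threshold: float = 1.2,
) -> list[DynamicCall]:
    """Call each protein dynamic or invariable from both datasets' fold changes.

    The dynamic call requires a strict >threshold fold change (up or down) in
    both baits. Proteins present in only one bait cannot be evaluated against
    the both-datasets rule and raise an error.
    """
    by_g = {f.protein: f for f in fc_g3bp1}
    by_c = {f.protein: f for f in fc_caprin1}
    only_one = set(by_g) ^ set(by_c)
    if only_one:
        raise ValueError(
            f"{len(only_one)} protein(s) present in a single bait only "
            f"(e.g. {sorted(only_one)[:3]}); classification needs both datasets"
        )
    calls = []
    for acc in sorted(by_g):
        rg, rc = _rule(by_g[acc], threshold), _rule(by_c[acc], threshold)
        dynamic = rg != "none" and rc != "none"
        calls.append(DynamicCall(
            protein=acc,
            label="dynamic" if dynamic else "invariable",
            passing_rule_g3bp1=rg,
            passing_rule_caprin1=rc,
        ))
    return calls


def calls_to_frame(calls: list[DynamicCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.protein, c.label, c.passing_rule_g3bp1, c.passing_rule_caprin1) for c in calls],
        columns=["accession", "label", "rule_g3bp1", "rule_caprin1"],
    ).set_index("accession")
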