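"""Per-protein biochemical properties and the three-group statistical tests.

Properties: isoelectric point (pI, from sequence composition via bisection on
the Henderson-Hasselbalch net charge), intrinsically-disordered-region (IDR)
coverage from per-residue predictor tracks, prion-like-domain (PrLD) calls
parsed from PLAAC output, and RNA-binding-protein membership from a gene
list. Group comparisons follow the study design: one-way ANOVA with Tukey HSD
for continuous variables across early/late/invariable, Welch's t-test for
two-group contrasts, and Pearson chi-square for categorical fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "PKA_SETS",
    "isoelectric_point",
    "net_charge",
    "read_score_track",
    "idr_coverage",
    "parse_prld",
    "GroupComparison",
    "compare_groups_continuous",
    "welch_ttest",
    "compare_groups_categorical",
]

# pKa tables: side chains for D,E,C,Y (acidic) and H,K,R (basic) plus termini.
PKA_SETS: dict[str, dict[str, float]] = {
    # EMBOSS iep defaults
    "emboss": {
        "Nterm": 8.6, "Cterm": 3.6,
        "K": 10.8, "R": 12.5, "H": 6.5,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    },
    # Bjellqvist-style values (classic 2D-gel calibration)
    "bjellqvist": {
        "Nterm": 9.69, "Cterm": 2.34,
        "K": 10.5, "R": 12.0, "H": 5.98,
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
    },
}

_ACIDIC = ("D", "E", "C", "Y")
_BASIC = ("K", "R", "H")
_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")


def net_charge(counts: Mapping[str, int], ph: float, pka: Mapping[str, float]) -> float:
    """Net protein charge at a given pH from residue counts (plus 1 N- and
    1 C-terminus)."""
    pos = 1.0 / (1.0 + 10.0 ** (ph - pka["Nterm"]))
    for aa in _BASIC:
        pos += counts.get(aa, 0) / (1.0 + 10.0 ** (ph - pka[aa]))
    neg = 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - ph))
    for aa in _ACIDIC:
        neg += counts.get(aa, 0) / (1.0 + 10.0 ** (pka[aa] - ph))
    return pos - neg


def isoelectric_point(
    sequence: str, pka_set: str | Mapping[str, float] = "emboss", tol: float = 1e-4
) -> float:
    """pI by bisection on pH in (0, 14) solving net charge = 0.

    Non-standard residues are ignored with a warning-free skip (they carry no
    ionizable group in this model). Composition-only: the residue order never
    matters.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    pka = PKA_SETS[pka_set] if isinstance(pka_set, str) else dict(pka_set)
    counts: dict[str, int] = {}
    for aa in seq:
        if aa in _STANDARD:
            counts[aa] = counts.get(aa, 0) + 1
    lo, hi = 0.0, 14.0
    # net charge is monotone decreasing in pH
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(counts, mid, pka)
        if abs(q) < 1e-12 or hi - lo < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# disorder tracks and PrLD calls


def read_score_track(path: str | Path) -> dict[str, np.ndarray]:
    """Read IUPred2/ANCHOR2-style per-residue score tracks.

    Plain text, '#' comment headers; data lines are ``position residue score``
    (whitespace- or tab-separated). Multiple proteins are separated by
    ``# <accession>`` header lines; a file without such headers yields one
    track keyed ''.
    """
    tracks: dict[str, list[float]] = {}
    current = ""
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            name = line.lstrip("#").strip()
            if name:
                current = name.split()[0]
                tracks.setdefault(current, [])
            continue
        parts = line.split()
        tracks.setdefault(current, []).append(float(parts[-1]))
    return {k: np.asarray(v, dtype=float) for k, v in tracks.items() if v}


def idr_coverage(score_track: Sequence[float], threshold: float = 0.5) -> float:
    """Fraction of residues with disorder score strictly above the threshold."""
    t = np.asarray(score_track, dtype=float)
    if t.size == 0:
        raise ValueError("empty score track")
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("disorder scores must lie in [0, 1]")
    return float(np.count_nonzero(t > threshold) / t.size)


def parse_prld(plaac_output: str | Path) -> dict[str, bool]:
    """PrLD presence per protein from a PLAAC summary table.

    Expects a TSV with a sequence-id column (SEQid) and a core-length column
    (CORELEN); a positive core length is a PrLD call.
    """
    df = pd.read_csv(plaac_output, sep="\t", comment="#")
    cols = {c.upper(): c for c in df.columns}
    if "SEQID" not in cols or "CORELEN" not in cols:
        raise ValueError(f"PLAAC table {plaac_output} lacks SEQid/CORELEN columns")
    out: dict[str, bool] = {}
    for _, row in df.iterrows():
        corelen = row[cols["CORELEN"]]
        out[str(row[cols["SEQID"]])] = bool(pd.notna(corelen) and float(corelen) > 0)
    return out


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class GroupComparison:
    variable: str
    group_n: dict[str, int]
    group_mean: dict[str, float]
    group_median: dict[str, float]
    statistic: float
    p_value: float
    test: str
    df: float | None = None
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)


def compare_groups_continuous(
    values_by_group: Mapping[str, Sequence[float]],
    variable: str = "value",
    pairwise: bool = True,
) -> GroupComparison:
    """One-way ANOVA across groups with Tukey HSD pairwise tests.

    Unequal group sizes are handled by the Tukey-Kramer adjustment (the
    statsmodels implementation).
    """
    names = list(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >=2 groups with >=2 values each")
    if all(a.var(ddof=1) == 0 for a in arrays):
        if len({a.mean() for a in arrays}) > 1:
            raise ValueError("zero within-group variance with differing means")
    f, p = stats.f_oneway(*arrays)
    if not np.isfinite(f):  # identical groups: no between- or within-variance
        f, p = 0.0, 1.0
    comp = GroupComparison(
        variable=variable,
        group_n={g: int(a.size) for g, a in zip(names, arrays)},
        group_mean={g: float(a.mean()) for g, a in zip(names, arrays)},
        group_median={g: float(np.median(a)) for g, a in zip(names, arrays)},
        statistic=float(f),
        p_value=float(p),
        test="anova",
    )
    if pairwise and len(names) > 2:
        flat = np.concatenate(arrays)
        labels = np.concatenate([[g] * a.size for g, a in zip(names, arrays)])
        tk = pairwise_tukeyhsd(flat, labels)
        for row in tk.summary().data[1:]:
            comp.pairwise_p[(str(row[0]), str(row[1]))] = float(row[3])
    return comp


def welch_ttest(a: Sequence[float], b: Sequence[float], variable: str = "value") -> GroupComparison:
    """Two-sided Welch's t-test (unequal variances)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        variable=variable,
        group_n={"a": int(a.size), "b": int(b.size)},
        group_mean={"a": float(a.mean()), "b": float(b.mean())},
        group_median={"a": float(np.median(a)), "b": float(np.median(b))},
        statistic=float(t),
        p_value=float(p),
        test="welch_t",
    )


def compare_groups_categorical(
    contingency: Sequence[Sequence[int]] | np.ndarray, variable: str = "count"
) -> GroupComparison:
    """Pearson chi-square test (no continuity correction) on a 2 x k table."""
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("contingency must be a nonnegative 2-D table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    cols = [f"col{j}" for j in range(table.shape[1])]
    return GroupComparison(
        variable=variable,
        group_n={c: int(table[:, j].sum()) for j, c in enumerate(cols)},
        group_mean={c: float(table[0, j] / table[:, j].sum()) for j, c in enumerate(cols)},
        group_median={},
        statistic=float(chi2),
        p_value=float(p),
        test="chi_square",
        df=float(df),
    )
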