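"""Temporal clustering of dynamic proteins and sigmoid inflection fitting.

Dynamic proteins are z-scored over the nine time labels of the CAPRIN1
dataset, clustered hierarchically (Chebyshev distance, average linkage) into
two temporal groups, and labeled *early* (declining across the course) or
*late* (rising). Each group's average profile is then fitted with a
four-parameter logistic whose midpoint is reported as the inflection time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import least_squares
from sklearn.decomposition import PCA

from .quant import IntensityMatrix

__all__ = [
    "TIMECOURSE_LABELS",
    "TIMECOURSE_MINUTES",
    "TemporalProfile",
    "ClusterAssignment",
    "SigmoidFit",
    "zscore_profiles",
    "hierarchical_cluster",
    "pca_loadings",
    "assign_early_late",
    "fit_sigmoid",
    "logistic4",
]

#: The nine labels of the time course (SG-ls excluded).
TIMECOURSE_LABELS = ("HS0", "HS10", "HS20", "HS30", "HS60", "HS120", "HS180", "Re5", "Re10")

#: Heat-shock minutes used for sigmoid fitting (recovery points excluded by default).
TIMECOURSE_MINUTES = (0.0, 10.0, 20.0, 30.0, 60.0, 120.0, 180.0)


@dataclass(frozen=True)
class TemporalProfile:
    protein: str
    time_labels: tuple[str, ...]
    z: np.ndarray
    degenerate: bool = False  # zero-variance row, z forced to zeros


@dataclass(frozen=True)
class ClusterAssignment:
    protein: str
    cluster: str  # "early" | "late"
    pc1_loading: float
    pc2_loading: float


@dataclass(frozen=True)
class SigmoidFit:
    lower: float
    upper: float
    t0: float
    slope: float
    direction: str  # "decreasing" | "increasing"
    rss: float
    converged: bool


def zscore_profiles(
    m: IntensityMatrix,
    bait: str = "CAPRIN1",
    labels: Sequence[str] = TIMECOURSE_LABELS,
    log_transform: bool = True,
) -> list[TemporalProfile]:
    """Unit-variance row scaling of replicate-mean profiles (sample sd, ddof=1).

    With ``log_transform`` (default) the label means are log2-transformed
    before scaling, so that the z-profile is an affine image of the log-scale
    kinetics; intensities span decades and the abundance kinetics are
    multiplicative, so scaling raw means would let the exponential curvature
    distort profile shapes (and bias downstream inflection fits).
    """
    idx = [i for i, s in enumerate(m.samples) if s.bait == bait and s.time_label in labels]
    if not idx:
        raise ValueError(f"no samples for bait {bait!r}")
    sub = IntensityMatrix(list(m.records), [m.samples[i] for i in idx], m.values[:, idx])
    means = sub.time_label_means(list(labels))
    profiles = []
    for acc, row in means.iterrows():
        v = row.to_numpy(dtype=float)
        if log_transform:
            if np.any(v <= 0):
                raise ValueError(f"non-positive label mean for {acc}; cannot log-transform")
            v = np.log2(v)
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            profiles.append(TemporalProfile(acc, tuple(labels), np.zeros_like(v), degenerate=True))
        else:
            profiles.append(TemporalProfile(acc, tuple(labels), (v - v.mean()) / sd))
    return profiles


def _profile_matrix(profiles: Sequence[TemporalProfile]) -> tuple[np.ndarray, list[str]]:
    order = np.argsort([p.protein for p in profiles], kind="stable")
    ordered = [profiles[i] for i in order]
    return np.vstack([p.z for p in ordered]), [p.protein for p in ordered]


def hierarchical_cluster(
    profiles: Sequence[TemporalProfile], k: int = 2,
    metric: str = "chebyshev", linkage: str = "average",
) -> tuple[np.ndarray, dict[str, int]]:
    """Agglomerative clustering of z-profiles; returns (linkage matrix, labels).

    Chebyshev (maximum coordinate difference) distance with average linkage,
    cut at ``k`` clusters. Rows are sorted by accession first so the result is
    invariant to input order.
    """
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds number of profiles ({len(profiles)})")
    z, accs = _profile_matrix(profiles)
    Z = hierarchy.linkage(z, method=linkage, metric=metric)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return Z, dict(zip(accs, flat.tolist()))


def pca_loadings(profiles: Sequence[TemporalProfile]) -> tuple[pd.DataFrame, np.ndarray]:
    """First two PC loadings per protein (proteins as observations).

    Sign convention: each component axis, viewed as a profile over the time
    labels, is flipped so that it correlates negatively with time order —
    i.e. positive loadings mean decreasing-in-time profiles. Ties fall back
    to making the largest-magnitude axis element positive.
    """
    if len(profiles) < 3:
        raise ValueError("PCA needs at least 3 profiles")
    z, accs = _profile_matrix(profiles)
    if np.allclose(z, z.mean(axis=0, keepdims=True)):
        # rank-0 across proteins: no variance to decompose
        df = pd.DataFrame(0.0, index=accs, columns=["PC1", "PC2"])
        return df, np.zeros(2)
    pca = PCA(n_components=2)
    scores = pca.fit_transform(z)
    t = np.arange(z.shape[1], dtype=float)
    for j in range(2):
        axis = pca.components_[j]
        c = np.corrcoef(axis, t)[0, 1]
        if np.isfinite(c) and abs(c) > 1e-12:
            flip = c > 0
        else:
            flip = axis[np.argmax(np.abs(axis))] < 0
        if flip:
            scores[:, j] *= -1
            pca.components_[j] *= -1
    df = pd.DataFrame(scores, index=accs, columns=["PC1", "PC2"])
    return df, pca.explained_variance_ratio_


def assign_early_late(
    labels: dict[str, int],
    profiles: Sequence[TemporalProfile],
    early_label: str = "HS10",
    late_label: str = "HS180",
) -> tuple[list[ClusterAssignment], list[str]]:
    """Name the two clusters: the one with higher mean z at HS10 than at HS180
    is *early*, the other *late*. Returns assignments plus any warnings.

    If both clusters decline (or both rise), the steeper-declining one is
    early and a warning is emitted; an exact tie is an error.
    """
    by_prot = {p.protein: p for p in profiles}
    ids = sorted(set(labels.values()))
    if len(ids) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {len(ids)}")
    lab_idx = {lab: profiles[0].time_labels.index(lab) for lab in (early_label, late_label)}
    drop = {}
    for cid in ids:
        zs = np.vstack([by_prot[a].z for a, c in labels.items() if c == cid])
        drop[cid] = zs[:, lab_idx[early_label]].mean() - zs[:, lab_idx[late_label]].mean()
    warnings: list[str] = []
    if drop[ids[0]] == drop[ids[1]]:
        raise ValueError("clusters have identical HS10-HS180 mean-z drop; cannot orient early/late")
    early_id = max(ids, key=lambda c: drop[c])
    if all(d > 0 for d in drop.values()) or all(d < 0 for d in drop.values()):
        warnings.append(
            "both clusters trend the same way; the steeper-declining cluster was named early"
        )
    pc, _ = pca_loadings(profiles) if len(profiles) >= 3 else (None, None)
    out = []
    for acc in sorted(labels):
        cid = labels[acc]
        pc1 = float(pc.loc[acc, "PC1"]) if pc is not None else float("nan")
        pc2 = float(pc.loc[acc, "PC2"]) if pc is not None else float("nan")
        out.append(ClusterAssignment(
            protein=acc, cluster="early" if cid == early_id else "late",
            pc1_loading=pc1, pc2_loading=pc2,
        ))
    return out, warnings


def logistic4(t: np.ndarray, lower: float, upper: float, t0: float, slope: float) -> np.ndarray:
    """Four-parameter logistic: lower + (upper-lower) / (1 + exp(-slope (t - t0)))."""
    x = np.clip(-slope * (np.asarray(t, float) - t0), -700.0, 700.0)
    return lower + (upper - lower) / (1.0 + np.exp(x))


def fit_sigmoid(times: Sequence[float], values: Sequence[float]) -> SigmoidFit:
    """Least-squares 4-parameter logistic fit with multi-start on the midpoint.

    The inflection time is the fitted midpoint ``t0``. Flat inputs are flagged
    as non-converged/degenerate rather than fitted.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValueError("sigmoid fit needs at least 4 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    span = float(v.max() - v.min())
    if span < 1e-9:
        return SigmoidFit(float(v.mean()), float(v.mean()), float(t.mean()), 0.0,
                          "increasing", 0.0, converged=False)

    def resid(p):
        return logistic4(t, *p) - v

    best = None
    scale = 4.0 / (t.max() - t.min())
    for t0_start in t:
        for sgn in (1.0, -1.0):
            p0 = np.array([v.min(), v.max(), t0_start, sgn * scale])
            try:
                sol = least_squares(resid, p0, method="lm", max_nfev=5000)
            except Exception:
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0] - 1e-12:
                best = (rss, sol)
    if best is None:
        return SigmoidFit(float(v.min()), float(v.max()), float(t.mean()), 0.0,
                          "increasing", float("inf"), converged=False)
    rss, sol = best
    lower, upper, t0, slope = (float(x) for x in sol.x)
    # canonical form: positive slope, direction carried by (upper - lower)
    if slope < 0:
        lower, upper, slope = upper, lower, -slope
    direction = "increasing" if upper >= lower else "decreasing"
    converged = bool(sol.success and (t.min() - 1e-9 <= t0 <= t.max() + 1e-9))
    return SigmoidFit(lower, upper, float(t0), slope, direction, rss, converged)
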