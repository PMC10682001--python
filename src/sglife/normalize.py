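"""Between-sample normalization for TMT intensity matrices.

Three stages, applied in this order by :func:`normalize_pipeline`:

1. :func:`scale_columns_to_mean` — every channel is scaled so that all column
   sums equal the mean column sum (equal-loading correction).
2. :func:`combat_adjust` — empirical-Bayes location/scale batch correction
   across TMT replicates, with the time course collapsed into early / middle /
   late covariate groups so that batch estimation is not confounded with the
   kinetics of interest.
3. :func:`tmm_factors` / :func:`apply_tmm` — trimmed-mean-of-M-values scaling
   factors computed against a reference channel.

All three operate on raw-scale intensities; ComBat works on log2 values
internally. Zeros and missing values are floored to half the smallest positive
intensity before logging (a standard proteomics floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .quant import IntensityMatrix

__all__ = [
    "NormalizationError",
    "BatchModel",
    "TMMFactors",
    "scale_columns_to_mean",
    "combat_adjust",
    "tmm_factors",
    "apply_tmm",
    "normalize_pipeline",
]


class NormalizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# column scaling


def scale_columns_to_mean(m: IntensityMatrix) -> IntensityMatrix:
    """Scale each column so all column sums equal the mean column sum.

    Missing values are treated as 0 for the sums and stay missing afterwards.
    """
    sums = np.nansum(m.values, axis=0)
    zero = np.where(sums <= 0)[0]
    if zero.size:
        bad = [m.samples[i].sample_id for i in zero]
        raise NormalizationError(f"column(s) with non-positive sum: {bad}")
    target = sums.mean()
    out = m.copy()
    out.values = m.values * (target / sums)[None, :]
    return out


# ---------------------------------------------------------------------------
# ComBat (parametric empirical-Bayes location/scale adjustment)


@dataclass
class BatchModel:
    """Fitted ComBat model: per-(batch, protein) location and scale effects.

    ``gamma_hat``/``delta_hat`` are the method-of-moments estimates,
    ``gamma_star``/``delta_star`` their EB-shrunk counterparts under a normal
    (location) and inverse-gamma (scale) prior. Gammas are reported on the
    log2-intensity scale; deltas are variance ratios relative to the pooled
    per-protein variance. Arrays are shaped (n_batches, n_proteins).
    """

    batches: list[object]
    batch_of_sample: dict[str, object]
    group_of_sample: dict[str, str]
    gamma_hat: np.ndarray
    delta_hat: np.ndarray
    gamma_star: np.ndarray
    delta_star: np.ndarray
    prior_params: dict[str, np.ndarray] = field(default_factory=dict)


def _log2_floor(values: np.ndarray) -> tuple[np.ndarray, float]:
    """log2 with zeros/missing replaced by half the smallest positive value."""
    v = np.array(values, dtype=float)
    pos = v[np.isfinite(v) & (v > 0)]
    if pos.size == 0:
        raise NormalizationError("matrix has no positive intensities")
    floor = pos.min() / 2.0
    v[~np.isfinite(v) | (v <= 0)] = floor
    return np.log2(v), floor


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (2 * s2 + m**2) / s2 if s2 > 0 else np.inf


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (m * s2 + m**3) / s2 if s2 > 0 else np.inf


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(sdat: np.ndarray, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterative solution for the EB batch-effect posteriors (one batch)."""
    n = np.isfinite(sdat).sum(axis=0).astype(float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = np.nansum((sdat - g_new[None, :]) ** 2, axis=0)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_adjust(
    m: IntensityMatrix,
    parametric: bool = True,
) -> tuple[IntensityMatrix, BatchModel]:
    """Empirical-Bayes batch correction across TMT replicates.

    Batches are the replicates; the biological covariate is the sample's
    combat group (early = HS0/HS10, middle = HS20-HS60, late = HS120-Re10,
    plus an "sgls" level for SG-ls channels). The algorithm standardizes each
    protein with the group covariates, estimates per-batch location (gamma)
    and scale (delta) effects, shrinks them with parametric priors, adjusts,
    and back-transforms to the raw intensity scale.
    """
    if not parametric:
        raise NotImplementedError("only the parametric EB priors are implemented")

    samples = m.samples
    batch_ids = [s.replicate for s in samples]
    batches = sorted(set(batch_ids))
    if len(batches) < 2:
        raise NormalizationError("ComBat needs at least 2 batches (replicates)")
    for b in batches:
        if batch_ids.count(b) < 2:
            raise NormalizationError(f"batch {b!r} has fewer than 2 samples")

    groups = [s.combat_group for s in samples]
    group_levels = sorted(set(groups))
    # Confounding check: the (batch x group) incidence must leave the design
    # full-rank after dropping one group level.
    for b in batches:
        gset = {g for g, bb in zip(groups, batch_ids) if bb == b}
        if len(gset) < 2 and len(group_levels) > 1:
            raise NormalizationError(
                f"batch {b!r} contains only group {gset}; batch is confounded with the covariate"
            )

    logv, _ = _log2_floor(m.values)
    n_prot, n_samp = logv.shape

    # design: one column per batch (cell-means for batch), plus group covariates
    # with the first level dropped.
    batch_design = np.zeros((n_samp, len(batches)))
    for j, b in enumerate(batch_ids):
        batch_design[j, batches.index(b)] = 1.0
    grp_design = np.zeros((n_samp, len(group_levels) - 1))
    for j, g in enumerate(groups):
        k = group_levels.index(g)
        if k > 0:
            grp_design[j, k - 1] = 1.0
    design = np.hstack([batch_design, grp_design])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise NormalizationError("design matrix is singular: batches confounded with groups")

    # per-protein OLS of log intensity on the design
    beta, *_ = np.linalg.lstsq(design, logv.T, rcond=None)  # (p_design, n_prot)
    n_per_batch = batch_design.sum(axis=0)
    grand_mean = (n_per_batch / n_samp) @ beta[: len(batches), :]  # (n_prot,)
    fitted = design @ beta
    resid = logv.T - fitted
    var_pooled = (resid**2).mean(axis=0)  # (n_prot,)
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = grand_mean[None, :] + grp_design @ beta[len(batches):, :]  # (n_samp, n_prot)
    s_data = (logv.T - stand_mean) / np.sqrt(var_pooled)[None, :]  # (n_samp, n_prot)

    gamma_hat = np.zeros((len(batches), n_prot))
    delta_hat = np.zeros((len(batches), n_prot))
    for i, b in enumerate(batches):
        rows = [j for j, bb in enumerate(batch_ids) if bb == b]
        sub = s_data[rows, :]
        gamma_hat[i] = sub.mean(axis=0)
        # ddof=0 to match the pooled-variance normalization: with no batch
        # effect, delta_hat is then exactly 1 and the adjustment is an identity
        delta_hat[i] = sub.var(axis=0, ddof=0)
    delta_hat = np.maximum(delta_hat, 1e-12)

    gamma_star = np.zeros_like(gamma_hat)
    delta_star = np.zeros_like(delta_hat)
    priors = {"gamma_bar": np.zeros(len(batches)), "t2": np.zeros(len(batches)),
              "a_prior": np.zeros(len(batches)), "b_prior": np.zeros(len(batches))}
    for i, b in enumerate(batches):
        rows = [j for j, bb in enumerate(batch_ids) if bb == b]
        g_bar = gamma_hat[i].mean()
        t2 = gamma_hat[i].var()
        a, b_ = _aprior(delta_hat[i]), _bprior(delta_hat[i])
        priors["gamma_bar"][i], priors["t2"][i] = g_bar, t2
        priors["a_prior"][i], priors["b_prior"][i] = a, b_
        if t2 <= 0 or not np.isfinite(a) or not np.isfinite(b_):
            # degenerate prior (e.g. no real batch effect variance): fall back
            # to the unshrunk estimates
            gamma_star[i], delta_star[i] = gamma_hat[i], delta_hat[i]
        else:
            gamma_star[i], delta_star[i] = _it_sol(
                s_data[rows, :], gamma_hat[i], delta_hat[i], g_bar, t2, a, b_
            )
    delta_star = np.maximum(delta_star, 1e-12)

    adjusted = s_data.copy()
    for i, b in enumerate(batches):
        rows = [j for j, bb in enumerate(batch_ids) if bb == b]
        adjusted[rows, :] = (adjusted[rows, :] - gamma_star[i][None, :]) / np.sqrt(
            delta_star[i]
        )[None, :]
    adjusted = adjusted * np.sqrt(var_pooled)[None, :] + stand_mean

    out = m.copy()
    vals = 2.0 ** adjusted.T
    vals[~np.isfinite(m.values)] = np.nan  # keep original missingness
    out.values = vals
    # report gamma on the log2 scale and delta as a log2-variance ratio scale
    sd_pooled = np.sqrt(var_pooled)[None, :]
    model = BatchModel(
        batches=batches,
        batch_of_sample={s.sample_id: s.replicate for s in samples},
        group_of_sample={s.sample_id: s.combat_group for s in samples},
        gamma_hat=gamma_hat * sd_pooled,
        delta_hat=delta_hat,
        gamma_star=gamma_star * sd_pooled,
        delta_star=delta_star,
        prior_params=priors,
    )
    return out, model


# ---------------------------------------------------------------------------
# TMM


@dataclass
class TMMFactors:
    reference_sample: str
    factor_of_sample: dict[str, float]
    trim_M: float = 0.30
    trim_A: float = 0.05


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, trim_M: float, trim_A: float) -> float:
    """Weighted trimmed mean of M-values between one column and the reference."""
    ok = np.isfinite(obs) & np.isfinite(ref) & (obs > 0) & (ref > 0)
    if ok.sum() < 10:
        raise NormalizationError(f"fewer than 10 positive pairs for TMM ({int(ok.sum())})")
    o, r = obs[ok], ref[ok]
    M = np.log2(o / r)
    A = 0.5 * np.log2(o * r)
    # delta-method variance of M, used as precision weights
    w = 1.0 / o + 1.0 / r
    finite = np.isfinite(M) & np.isfinite(A) & np.isfinite(w)
    M, A, w = M[finite], A[finite], w[finite]
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = len(M)
    lo_M, hi_M = np.floor(n * trim_M) + 1, n + 1 - (np.floor(n * trim_M) + 1)
    lo_A, hi_A = np.floor(n * trim_A) + 1, n + 1 - (np.floor(n * trim_A) + 1)
    rank_M = stats.rankdata(M, method="average")
    rank_A = stats.rankdata(A, method="average")
    keep = (rank_M >= lo_M) & (rank_M <= hi_M) & (rank_A >= lo_A) & (rank_A <= hi_A)
    if not keep.any():
        return 1.0
    f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0**f)


def tmm_factors(
    m: IntensityMatrix,
    reference: str = "auto",
    trim_M: float = 0.30,
    trim_A: float = 0.05,
    recenter: bool = False,
) -> TMMFactors:
    """Trimmed-mean-of-M-values scaling factor per sample.

    ``reference='auto'`` picks the sample whose upper quartile is closest to
    the mean upper quartile. With ``recenter`` the factors are divided by
    their geometric mean so they multiply to 1 across samples.
    """
    ids = m.sample_ids
    if reference == "auto":
        with np.errstate(invalid="ignore"):
            uq = np.nanquantile(np.where(m.values > 0, m.values, np.nan), 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - np.nanmean(uq))))
    else:
        ref_idx = m.sample_index(reference)
    ref_col = m.values[:, ref_idx]
    factors = {}
    for j, sid in enumerate(ids):
        factors[sid] = 1.0 if j == ref_idx else _tmm_pair(m.values[:, j], ref_col, trim_M, trim_A)
    if recenter:
        gm = float(np.exp(np.mean(np.log(list(factors.values())))))
        factors = {k: v / gm for k, v in factors.items()}
    return TMMFactors(
        reference_sample=ids[ref_idx], factor_of_sample=factors,
        trim_M=trim_M, trim_A=trim_A,
    )


def apply_tmm(m: IntensityMatrix, factors: TMMFactors) -> IntensityMatrix:
    """Divide each column by its TMM factor."""
    out = m.copy()
    f = np.array([factors.factor_of_sample[sid] for sid in m.sample_ids])
    out.values = m.values / f[None, :]
    return out


def normalize_pipeline(m: IntensityMatrix) -> tuple[IntensityMatrix, BatchModel, TMMFactors]:
    """Full chain: column scaling -> ComBat (replicates as batches) -> TMM."""
    scaled = scale_columns_to_mean(m)
    adjusted, model = combat_adjust(scaled)
    factors = tmm_factors(adjusted, reference="auto", recenter=True)
    return apply_tmm(adjusted, factors), model, factors
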