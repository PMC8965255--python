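"""Depth normalization, variance stabilization, batch adjustment, strain means.

The chain applied to the estimated counts of the detected-above-background
transcriptome, in order:

1. ``upper_quartile_normalize`` — per-library scaling so the 75th percentile
   of counts (over transcripts expressed somewhere) is equal across
   libraries.
2. ``regularized_log`` — ``log2(count + c)`` followed by empirical-Bayes
   shrinkage of each library value toward the transcript mean with weight
   ``lambda/(lambda + n_libraries)``.  A moderated log: the downstream
   statistics (rank correlation, ANOVA R^2, regression LOD) only require a
   monotone variance-stabilized scale, and this transform is strictly
   monotone in the count for fixed ``lam`` and ``c``.
3. ``batch_adjust`` — parametric empirical-Bayes location/scale adjustment:
   per-transcript standardization, per-batch location/scale estimates shrunk
   toward batch-level moment-matched priors, then removal and
   de-standardization.  The location adjustment is re-centered so every
   transcript's grand mean is preserved exactly.
4. ``strain_means`` — arithmetic mean over each strain's libraries;
   loading-control libraries are excluded.

Each transform appends a tag to the matrix's provenance chain (stored in
``DataFrame.attrs['transforms']``).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def _tag(df: pd.DataFrame, parent: pd.DataFrame | None, label: str) -> pd.DataFrame:
    chain = list(parent.attrs.get("transforms", [])) if parent is not None else []
    df.attrs["transforms"] = chain + [label]
    return df


def upper_quartile_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each library so its upper-quartile count equals the across-
    library mean upper quartile.

    The quartile is computed over transcripts with a nonzero count in at
    least one library, so uniformly absent transcripts do not dilute the
    reference.
    """
    expressed = counts.index[(counts > 0).any(axis=1)]
    if len(expressed) == 0:
        raise ValueError("count matrix has no nonzero entries")
    uq = counts.loc[expressed].quantile(0.75, axis=0)
    bad = uq.index[uq <= 0]
    if len(bad):
        raise ValueError(f"degenerate upper quartile (0) in libraries: {list(bad)}")
    reference = uq.mean()
    scaled = counts * (reference / uq)
    return _tag(scaled, counts, f"upper_quartile(ref={reference:.6g})")


def regularized_log(
    counts: pd.DataFrame, c: float = 1.0, lam: float = 1.0
) -> pd.DataFrame:
    """Moderated log transform with shrinkage toward the transcript mean.

    ``y = log2(count + c)`` then ``y' = m + (y - m) * n/(n + lam)`` with
    ``m`` the per-transcript mean over libraries.  ``lam = 0`` is a plain
    shifted log; ``lam -> inf`` collapses every library to the transcript
    mean.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    y = np.log2(counts + c)
    n = counts.shape[1]
    keep = n / (n + lam)
    m = y.mean(axis=1)
    out = y.mul(keep).add(m * (1.0 - keep), axis=0)
    return _tag(out, counts, f"moderated_log2(c={c},lam={lam})")


def batch_adjust(
    expr: pd.DataFrame, batches: pd.Series, min_batch_size: int = 2
) -> pd.DataFrame:
    """Empirical-Bayes location/scale batch-effect removal.

    Per transcript, values are standardized against the grand mean and
    pooled standard deviation; per-batch location (gamma) and scale
    (delta^2) estimates are shrunk toward batch-level priors with
    moment-matched hyperparameters; the shrunken effects are subtracted and
    rescaled; values are de-standardized.  The prior variance of the
    location effects is debiased by the expected estimation noise, so with
    randomly permuted batch labels the adjustment vanishes as the number of
    transcripts grows.  Each transcript's grand mean is restored exactly
    after adjustment.

    With a single batch the input is returned unchanged.  Batches that are
    confounded 1:1 with a single strain-like column grouping cannot be
    checked here; callers see a warning when any batch has fewer than
    ``min_batch_size`` libraries.
    """
    batches = batches.reindex(expr.columns)
    if batches.isna().any():
        raise ValueError("every library needs a batch label")
    levels = batches.unique()
    if len(levels) < 2:
        return _tag(expr.copy(), expr, "batch_adjust(identity)")

    X = expr.to_numpy(dtype=float)
    n_t, n_lib = X.shape
    grand = X.mean(axis=1)
    resid = X - grand[:, None]
    pooled_sd = resid.std(axis=1, ddof=1)
    pooled_sd = np.where(pooled_sd > 0, pooled_sd, 1.0)
    Z = resid / pooled_sd[:, None]

    adjusted = np.array(Z)
    for b in levels:
        cols = np.flatnonzero((batches == b).to_numpy())
        nb = len(cols)
        if nb < min_batch_size:
            warnings.warn(f"batch {b!r} has {nb} library(ies); effect poorly estimated")
        Zb = Z[:, cols]
        gamma_hat = Zb.mean(axis=1)
        if nb > 1:
            delta2_hat = Zb.var(axis=1, ddof=1)
        else:
            delta2_hat = np.ones(n_t)
        delta2_hat = np.maximum(delta2_hat, 1e-12)

        # location prior: Normal(gamma_bar, tau2), tau2 debiased for
        # estimation noise so null batches shrink to ~0
        gamma_bar = gamma_hat.mean()
        noise = float(np.mean(delta2_hat)) / nb
        tau2 = max(float(np.var(gamma_hat, ddof=1)) - noise, 0.0)
        w = tau2 / (tau2 + delta2_hat / nb) if tau2 > 0 else np.zeros(n_t)
        gamma_star = gamma_bar + w * (gamma_hat - gamma_bar)

        # scale prior: inverse-gamma, moment matched on the delta2_hat pool
        m = float(np.mean(delta2_hat))
        v = float(np.var(delta2_hat, ddof=1)) if n_t > 1 else 0.0
        if v > 0:
            a_prior = m * m / v + 2.0
            b_prior = m * (a_prior - 1.0)
        else:
            a_prior, b_prior = 2.0, m  # degenerate pool: prior at the mean
        df_b = max(nb - 1, 1)
        delta2_star = (b_prior + 0.5 * df_b * delta2_hat) / (a_prior + 0.5 * df_b - 1.0)
        delta2_star = np.maximum(delta2_star, 1e-12)

        adjusted[:, cols] = (Zb - gamma_star[:, None]) / np.sqrt(delta2_star)[:, None]

    out = adjusted * pooled_sd[:, None] + grand[:, None]
    # location adjustment is mean-zero by construction: restore grand means
    out += (grand - out.mean(axis=1))[:, None]
    res = pd.DataFrame(out, index=expr.index, columns=expr.columns)
    return _tag(res, expr, f"batch_adjust(n_batches={len(levels)})")


def strain_means(
    expr: pd.DataFrame, meta: pd.DataFrame, exclude_controls: bool = True
) -> pd.DataFrame:
    """Average library-level expression to strain level.

    ``meta`` maps library -> strain (columns ``library``, ``strain``, and
    optionally ``is_control``).  Loading-control libraries are excluded from
    the panel summary by default.  Strains with no libraries after exclusion
    are dropped with a warning.
    """
    meta = meta.set_index("library") if "library" in meta.columns else meta
    missing = [c for c in expr.columns if c not in meta.index]
    if missing:
        raise ValueError(f"libraries missing from metadata: {missing[:5]}")
    use = list(expr.columns)
    if exclude_controls and "is_control" in meta.columns:
        use = [c for c in use if not bool(meta.loc[c, "is_control"])]
        dropped = set(expr.columns) - set(use)
        if dropped:
            strains = sorted({str(meta.loc[c, "strain"]) for c in dropped})
            warnings.warn(f"excluding loading-control libraries of strain(s) {strains}")
    if not use:
        raise ValueError("no panel libraries left after excluding controls")
    groups = meta.loc[use, "strain"]
    out = expr[use].T.groupby(groups).mean().T
    out.columns.name = "strain"
    return _tag(out, expr, "strain_means")
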