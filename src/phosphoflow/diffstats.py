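"""Empirical-Bayes moderated contrasts, q-values and class-specific calls.

Model: per site, a one-way fixed-effects model over the tumour classes.
The residual variance of each site is shrunk toward a prior estimated from
all sites by the standard method of moments on log sample variances;
moderated t statistics for each pairwise class contrast are referenced to a
t distribution with (prior + residual) degrees of freedom.  Multiplicity is
handled with tail-area q-values from a two-component model (Storey-type
null-proportion estimate over a lambda grid with cubic smoothing).

A site is called class-specific for class C when its contrasts against BOTH
other classes are significant (q < threshold) and its class mean is the
highest — i.e. significance plus increased intensity.  An optional omnibus
moderated-F screen (q < threshold) gates the pairwise calls.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .preprocess import IntensityMatrix

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class VariancePrior:
    """Empirical-Bayes variance prior: d0 prior df (may be inf), s0_sq prior variance."""

    d0: float
    s0_sq: float

    def posterior_variance(self, s_sq: np.ndarray, df: float) -> np.ndarray:
        if np.isinf(self.d0):
            return np.full_like(np.asarray(s_sq, dtype=float), self.s0_sq)
        return (self.d0 * self.s0_sq + df * s_sq) / (self.d0 + df)


@dataclass
class ContrastTable:
    """Per-site moderated statistics for every ordered class pair."""

    class_means: pd.DataFrame  # sites x classes
    stats: pd.DataFrame  # sites x (diff_/t_/p_/q_ per contrast + F/p_F/q_F)
    contrasts: list[tuple[str, str]]
    prior: VariancePrior
    residual_df: float
    calls: pd.Series | None = None  # site -> class label or "none"


class ContrastError(ValueError):
    pass


# ---------------------------------------------------------------------------
# variance prior (method of moments on log variances)
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    # standard starting value
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s_sq: np.ndarray, df: float) -> VariancePrior:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Uses the distribution of z = log(s^2): under the model z - log(s0^2)
    has mean digamma(df/2) - digamma(d0/2) + log(d0/df) and variance
    trigamma(df/2) + trigamma(d0/2).
    """
    s_sq = np.maximum(np.asarray(s_sq, dtype=float), _VAR_FLOOR)
    z = np.log(s_sq)
    m = len(z)
    if m < 2:
        return VariancePrior(d0=np.inf, s0_sq=float(np.exp(z.mean())))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = ((e - e_mean) ** 2).sum() * m / (m - 1.0) / m
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        # sample variances homogeneous beyond chi-square scatter
        return VariancePrior(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    d0 = 2.0 * _trigamma_inverse(float(excess))
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return VariancePrior(d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# moderated contrasts
# ---------------------------------------------------------------------------


def fit_moderated_contrasts(
    matrix: IntensityMatrix, prior_df_override: float | None = None
) -> ContrastTable:
    """Fit the one-way class model and moderated t for all pairwise contrasts.

    ``prior_df_override`` forces d0 (0 recovers the ordinary pooled t, used
    by the oracle tests).
    """
    if not matrix.is_complete():
        raise ContrastError("matrix must be complete (imputed) before contrasts")
    classes = matrix.classes()
    if len(classes) < 2:
        raise ContrastError("need >= 2 classes")
    cols_of = {c: matrix.samples_of(c) for c in classes}
    for c, cols in cols_of.items():
        if len(cols) < 2:
            raise ContrastError(f"class {c!r} has < 2 samples")

    vals = matrix.values
    n_total = len(matrix.samples)
    df = float(n_total - len(classes))

    means = pd.DataFrame(
        {c: vals[cols_of[c]].mean(axis=1) for c in classes}, index=vals.index
    )
    rss = np.zeros(len(vals))
    for c in classes:
        sub = vals[cols_of[c]].to_numpy()
        rss += ((sub - means[c].to_numpy()[:, None]) ** 2).sum(axis=1)
    s_sq = rss / df

    if prior_df_override is not None:
        if prior_df_override == 0:
            prior = VariancePrior(d0=0.0, s0_sq=1.0)
        else:
            prior = VariancePrior(
                d0=float(prior_df_override),
                s0_sq=estimate_variance_prior(s_sq, df).s0_sq,
            )
    else:
        prior = estimate_variance_prior(s_sq, df)

    if prior.d0 == 0:
        post_var = np.maximum(s_sq, _VAR_FLOOR)
        df_total = df
    else:
        post_var = prior.posterior_variance(s_sq, df)
        df_total = prior.d0 + df

    out = pd.DataFrame(index=vals.index)
    contrasts = list(itertools.combinations(classes, 2))
    for a, b in contrasts:
        na, nb = len(cols_of[a]), len(cols_of[b])
        diff = means[a] - means[b]
        se = np.sqrt(post_var * (1.0 / na + 1.0 / nb))
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        tag = f"{a}_vs_{b}"
        out[f"diff_{tag}"] = diff
        out[f"t_{tag}"] = t
        out[f"p_{tag}"] = p
        out[f"q_{tag}"] = estimate_qvalues(p)

    # omnibus moderated F
    grand = vals.mean(axis=1).to_numpy()
    ss_between = np.zeros(len(vals))
    for c in classes:
        ss_between += len(cols_of[c]) * (means[c].to_numpy() - grand) ** 2
    df1 = len(classes) - 1
    f = (ss_between / df1) / np.maximum(post_var, _VAR_FLOOR)
    p_f = stats.f.sf(f, df1, df_total)
    out["F"] = f
    out["p_F"] = p_f
    out["q_F"] = estimate_qvalues(p_f)

    return ContrastTable(
        class_means=means,
        stats=out,
        contrasts=contrasts,
        prior=prior,
        residual_df=df,
    )


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------


def estimate_null_proportion(pvals: np.ndarray) -> float:
    """Storey-type eta0 estimate over a lambda grid with cubic smoothing.

    Grid 0.05..0.95 step 0.05; eta0(lambda) = #{p > lambda} / (m (1-lambda));
    a cubic polynomial is fit to eta0(lambda) and evaluated at the largest
    lambda; the estimate is clipped to (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if m == 0:
        return 1.0
    lambdas = np.arange(0.05, 0.96, 0.05)
    eta = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if m < 20:
        return float(min(1.0, max(eta[0], 1.0 / m)))
    coeffs = np.polyfit(lambdas, eta, 3)
    eta0 = float(np.polyval(coeffs, lambdas[-1]))
    return float(min(1.0, max(eta0, 1.0 / m)))


def estimate_qvalues(pvals, eta0: float | None = None) -> np.ndarray:
    """Tail-area q-values: q(p) = eta0 * p * m / rank(p), monotone-enforced.

    Monotonicity is imposed by a running minimum from the largest p down;
    values are capped at 1.  Empty input yields empty output.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    if eta0 is None:
        eta0 = estimate_null_proportion(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = eta0 * ranked * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# class-specific calling
# ---------------------------------------------------------------------------


def call_class_specific(
    table: ContrastTable,
    q_threshold: float = 0.05,
    require_omnibus: bool = True,
) -> dict[str, list[str]]:
    """Call each site for at most one class.

    Site is C-specific iff both contrasts of C against the other classes
    have q strictly below ``q_threshold`` and C's class mean exceeds both
    other class means.  With ``require_omnibus`` the omnibus moderated-F
    q must also clear the threshold.  Updates ``table.calls`` in place and
    returns class -> sorted site list.
    """
    classes = list(table.class_means.columns)
    stats_df = table.stats
    calls = pd.Series("none", index=stats_df.index, dtype=object)

    def q_col(a: str, b: str) -> pd.Series:
        if f"q_{a}_vs_{b}" in stats_df:
            return stats_df[f"q_{a}_vs_{b}"]
        return stats_df[f"q_{b}_vs_{a}"]

    omnibus_ok = (
        stats_df["q_F"] < q_threshold
        if require_omnibus
        else pd.Series(True, index=stats_df.index)
    )
    for c in classes:
        others = [o for o in classes if o != c]
        sig = omnibus_ok.copy()
        for o in others:
            sig &= q_col(c, o) < q_threshold
        elevated = pd.Series(True, index=stats_df.index)
        for o in others:
            elevated &= table.class_means[c] > table.class_means[o]
        hit = sig & elevated
        calls[hit] = c

    table.calls = calls
    result = {c: sorted(calls.index[calls == c]) for c in classes}
    logger.info(
        "call_class_specific: %s",
        {c: len(v) for c, v in result.items()},
    )
    return result


def results_frame(table: ContrastTable) -> pd.DataFrame:
    """Flat results table: class means, per-contrast stats, call column."""
    df = pd.concat(
        [table.class_means.add_prefix("mean_"), table.stats], axis=1
    )
    df["call"] = table.calls if table.calls is not None else "none"
    return df
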