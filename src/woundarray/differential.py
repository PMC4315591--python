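"""Per-gene linear models and empirical-Bayes moderated t-statistics.

Each gene is modelled by its four condition means on log2 scale, with a
pooled residual variance ``s2`` on ``df_resid = n_samples - 4`` degrees of
freedom.  The prior ``(d0, s0²)`` is estimated by the method of moments on
log residual variances (digamma/trigamma matching to a scaled F), the
posterior variance shrinks each gene's ``s2`` toward ``s0²``, and contrasts
are tested with a Student-t reference on ``d0 + df_resid`` degrees of
freedom.  A log posterior odds of differential expression (``B``) is
available under a two-component normal prior on the contrast effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import DesignTable, ExpressionMatrix, ValidationError

#: Named contrasts over the condition means, in canonical condition order
#: (JNK+W, JNK-W, JNK+, JNK-).  ``W`` and ``NW`` compare JNK-positive to
#: JNK-negative cells within wounded / non-wounded discs; ``D`` is their
#: interaction; ``dJNK+`` / ``dJNK-`` compare wounded to non-wounded discs
#: within a single cell population.
CONTRASTS: dict[str, tuple[float, float, float, float]] = {
    "W": (1.0, -1.0, 0.0, 0.0),
    "NW": (0.0, 0.0, 1.0, -1.0),
    "D": (1.0, -1.0, -1.0, 1.0),
    "dJNK+": (1.0, 0.0, -1.0, 0.0),
    "dJNK-": (0.0, 1.0, 0.0, -1.0),
}


@dataclass
class GeneModelFits:
    """Condition means, residual variances and residual df for all genes."""

    means: pd.DataFrame  # genes × conditions (log2)
    s2: pd.Series  # pooled residual variance per gene
    df_resid: float
    n_per_condition: dict[str, int]

    @property
    def genes(self) -> pd.Index:
        return self.means.index


@dataclass
class ModeratedTParams:
    """Prior degrees of freedom and prior variance (may be ``inf`` df)."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValidationError("prior df d0 must be non-negative (or inf)")
        if not (self.s0_sq > 0):
            raise ValidationError("prior variance s0² must be positive")


def fit_gene_models(m: ExpressionMatrix, design: DesignTable) -> GeneModelFits:
    """Fit the one-way (cell-means) model per gene on log2 data."""
    if m.scale != "log2":
        raise ValidationError("fit_gene_models requires log2-scale input")
    design.validate_against(m)
    conditions = design.conditions
    means = {}
    rss = np.zeros(m.shape[0])
    n_total = 0
    n_per = {}
    for cond in conditions:
        cols = design.samples_for(cond)
        missing = [s for s in cols if s not in m.values.columns]
        if missing or not cols:
            raise ValidationError(f"condition {cond!r} absent from matrix/design")
        sub = m.values[cols].to_numpy(dtype=float)
        mu = sub.mean(axis=1)
        means[cond] = mu
        rss += ((sub - mu[:, None]) ** 2).sum(axis=1)
        n_total += len(cols)
        n_per[cond] = len(cols)
    df_resid = n_total - len(conditions)
    if df_resid <= 0:
        raise ValidationError("no residual degrees of freedom (need >1 rep)")
    means_df = pd.DataFrame(means, index=m.genes)[list(conditions)]
    s2 = pd.Series(rss / df_resid, index=m.genes, name="s2")
    return GeneModelFits(means=means_df, s2=s2, df_resid=float(df_resid), n_per_condition=n_per)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_prior(fits: GeneModelFits) -> ModeratedTParams:
    """Method-of-moments fit of (d0, s0²) to the residual variances.

    Matches the mean and variance of ``log s2`` to the scaled-F model
    ``s2 ~ s0² · chi²(df)/df · chi²(d0)/d0`` via digamma/trigamma.  When the
    empirical spread of ``log s2`` does not exceed the sampling component,
    the prior df is infinite and ``s0²`` is the geometric-mean-based value.
    """
    s2 = fits.s2.to_numpy(dtype=float)
    s2 = s2[s2 > 0]
    if len(s2) < 10:
        raise ValidationError("need ≥10 genes with positive residual variance")
    d = fits.df_resid
    z = np.log(s2)
    e = z - float(special.digamma(d / 2.0)) + math.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    evar_resid = evar - float(special.polygamma(1, d / 2.0))
    if evar_resid > 0:
        d0 = 2.0 * _trigamma_inverse(evar_resid)
        s0_sq = math.exp(
            emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
    else:
        # under-dispersed log-variances → infinite prior df.  With literally
        # zero spread the observed common value is the only sensible estimate;
        # otherwise correct the geometric mean for chi² sampling bias.
        d0 = math.inf
        s0_sq = math.exp(float(z.mean())) if evar < 1e-15 else math.exp(emean)
    return ModeratedTParams(d0=d0, s0_sq=s0_sq)


def posterior_variance(fits: GeneModelFits, params: ModeratedTParams) -> pd.Series:
    """Shrunken variance s̃² = (d0·s0² + d·s²)/(d0 + d)."""
    if math.isinf(params.d0):
        return pd.Series(params.s0_sq, index=fits.genes, name="s2_post")
    d = fits.df_resid
    s2_post = (params.d0 * params.s0_sq + d * fits.s2) / (params.d0 + d)
    return s2_post.rename("s2_post")


def contrast_coefficients(contrast: str) -> tuple[float, ...]:
    try:
        return CONTRASTS[contrast]
    except KeyError:
        raise ValidationError(f"undefined contrast {contrast!r}") from None


def _contrast_variance_factor(
    coefs: tuple[float, ...], fits: GeneModelFits
) -> float:
    """Unscaled variance of the contrast estimate: Σ c²/n per condition."""
    n = [fits.n_per_condition[c] for c in fits.means.columns]
    return sum(c * c / ni for c, ni in zip(coefs, n))


def moderated_t(
    fits: GeneModelFits,
    params: ModeratedTParams | None,
    contrast: str,
) -> pd.DataFrame:
    """Contrast table with estimate, fold change, moderated t, p and BH-p.

    ``params=None`` (or ``d0=0`` passed explicitly via a zero-df sentinel)
    yields the classical per-gene t-statistic.
    """
    coefs = contrast_coefficients(contrast)
    beta = fits.means.to_numpy(dtype=float) @ np.asarray(coefs)
    v_c = _contrast_variance_factor(coefs, fits)
    if params is None:
        s2_post = fits.s2.to_numpy(dtype=float)
        df_total = fits.df_resid
    else:
        s2_post = posterior_variance(fits, params).to_numpy(dtype=float)
        df_total = params.d0 + fits.df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(s2_post * v_c)
    t = np.where(beta == 0.0, 0.0, t)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    fc = np.sign(beta) * np.exp2(np.abs(beta))
    fc = np.where(beta == 0.0, 1.0, fc)
    table = pd.DataFrame(
        {
            "beta": beta,
            "FC": fc,
            "t": t,
            "df": df_total,
            "p": p,
            "p_adj": bh_adjust(p),
        },
        index=fits.genes,
    )
    table.index.name = "gene"
    return table


def estimate_v0(
    t: np.ndarray,
    v_c: float,
    df_total: float,
    proportion: float = 0.01,
) -> float:
    """Estimate the prior variance of the contrast effect from the top |t| tail.

    For the top ``ceil(proportion·n)`` genes by |t|, equates each observed
    t² to its expected null quantile inflated by ``(v_c + v0)/v_c`` and
    averages the implied v0 (floored at a small positive value).
    """
    t = np.abs(np.asarray(t, dtype=float))
    n = len(t)
    ntarget = max(int(math.ceil(proportion * n)), 1)
    top = np.sort(t)[::-1][:ntarget]
    probs = (np.arange(ntarget) + 0.5) / n  # upper-tail probabilities
    if math.isinf(df_total):
        tref = stats.norm.isf(probs / 2.0)
    else:
        tref = stats.t.isf(probs / 2.0, df_total)
    ratio = (top / tref) ** 2
    v0 = v_c * np.maximum(ratio - 1.0, 0.0)
    return float(max(v0.mean(), 1e-9 * v_c))


def log_odds(
    fits: GeneModelFits,
    params: ModeratedTParams,
    contrast: str,
    prior_de: float = 0.01,
    v0: float | None = None,
) -> pd.Series:
    """Log posterior odds of differential expression (B statistic).

    Two-component model: with prior probability ``prior_de`` the contrast
    effect has extra variance ``v0`` (estimated from the top |t| tail when
    not given).  Monotone increasing in |t| at fixed df.
    """
    if not (0.0 < prior_de < 1.0):
        raise ValidationError("prior_de must lie strictly in (0, 1)")
    table = moderated_t(fits, params, contrast)
    t = table["t"].to_numpy(dtype=float)
    coefs = contrast_coefficients(contrast)
    v_c = _contrast_variance_factor(coefs, fits)
    df_total = params.d0 + fits.df_resid
    if v0 is None:
        v0 = estimate_v0(t, v_c, df_total, proportion=prior_de)
    r = (v_c + v0) / v_c
    t2 = t**2
    if math.isinf(df_total):
        kernel = 0.5 * t2 * (1.0 - 1.0 / r)
    else:
        kernel = (df_total / 2.0) * np.log((t2 + df_total) / (t2 / r + df_total))
    b = math.log(prior_de / (1.0 - prior_de)) - 0.5 * math.log(r) + kernel
    return pd.Series(b, index=fits.genes, name="B")


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("p-value input must be one-dimensional")
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValidationError("p-values must lie in [0, 1]")
    n = len(arr)
    if n == 0:
        return arr.copy()
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def select_genes(
    table: pd.DataFrame,
    fc_cut: float,
    p_cut: float,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Directed gene selection: |FC| ≥ fc_cut AND p (raw or BH) < p_cut.

    Returns a frame indexed by the selected genes with a ``direction``
    column in {"up", "down"}.
    """
    if fc_cut <= 0 or p_cut <= 0:
        raise ValidationError("thresholds must be positive")
    pcol = "p_adj" if use_adjusted else "p"
    mask = (table["FC"].abs() >= fc_cut) & (table[pcol] < p_cut)
    sel = table.loc[mask].copy()
    sel["direction"] = np.where(sel["FC"] > 0, "up", "down")
    return sel
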