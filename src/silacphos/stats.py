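"""Replicate statistics: one-sample tests on log2 ratios and BH-FDR.

Peptides quantified in at least ``min_replicates`` biological replicates
are tested for a nonzero mean normalized log2 treated/control ratio with a
two-sided one-sample Student t test, and the resulting p-values are
subjected to Benjamini-Hochberg step-up FDR control.  Peptides passing
the FDR threshold (10% by default) are classified up or down by the sign
of their mean log2 ratio; the same table carries the volcano-plot surface
(mean log2 ratio vs -log10 p).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ValidationError

__all__ = [
    "filter_min_replicates",
    "test_peptide",
    "test_peptides",
    "fit_f_dist",
    "moderated_t",
    "bh_fdr",
    "classify",
    "volcano_table",
    "differential_analysis",
]

log = logging.getLogger(__name__)

# smallest positive subnormal double: sentinel p for zero-variance nonzero-mean
_P_SENTINEL = float(np.nextafter(0.0, 1.0))


def filter_min_replicates(
    normalized: pd.DataFrame, min_replicates: int = 3
) -> tuple[pd.DataFrame, int]:
    """Keep peptides with >= ``min_replicates`` defined normalized ratios.

    Returns the filtered long table (quantified rows only) and the number
    of peptides excluded by the filter.
    """
    if min_replicates < 2:
        raise ConfigurationError("min_replicates must be >= 2")
    ok = normalized[normalized["normalized_log2_ratio"].notna()]
    counts = ok.groupby("peptide_key")["replicate_id"].nunique()
    keep = counts.index[counts >= min_replicates]
    n_excluded = int(normalized["peptide_key"].nunique() - keep.size)
    filtered = ok[ok["peptide_key"].isin(keep)].copy()
    log.info("filter_min_replicates: kept %d peptides, excluded %d",
             keep.size, n_excluded)
    return filtered, n_excluded


def _t_pvalue(mean: np.ndarray, sd: np.ndarray, n: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided one-sample t p-values with degenerate-variance handling."""
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    sd = np.atleast_1d(np.asarray(sd, dtype=float))
    n = np.atleast_1d(np.asarray(n, dtype=float))
    flagged = np.zeros(mean.shape, dtype=bool)
    p = np.empty(mean.shape, dtype=float)
    degen = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        p_t = 2.0 * sps.t.sf(np.abs(t), n - 1)
    p[~degen] = np.minimum(p_t[~degen], 1.0)
    p[degen & (mean == 0)] = 1.0
    p[degen & (mean != 0)] = _P_SENTINEL
    flagged[degen] = True
    p = np.maximum(p, _P_SENTINEL)  # keep p strictly positive
    return p, flagged


def test_peptide(values) -> tuple[float, float]:
    """Test one peptide's normalized log2 ratios against zero.

    Returns ``(mean_log2, p_value)`` from a two-sided one-sample Student
    t test.  Zero-variance inputs are degenerate: p = 1 when the mean is
    also zero, else the smallest positive double as a sentinel.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("test_peptide requires >= 2 replicate ratios")
    if np.isnan(x).any():
        raise ValidationError("test_peptide requires defined (non-NaN) ratios")
    p, _ = _t_pvalue(x.mean(), x.std(ddof=1), x.size)
    return float(x.mean()), float(p[0])


def test_peptides(filtered: pd.DataFrame) -> pd.DataFrame:
    """Vectorized per-peptide one-sample t tests on the filtered long table."""
    g = filtered.groupby("peptide_key")["normalized_log2_ratio"]
    res = pd.DataFrame({
        "n_replicates_quantified": g.count(),
        "mean_log2": g.mean(),
        "sd_log2": g.std(ddof=1),
    })
    p, flagged = _t_pvalue(res["mean_log2"], res["sd_log2"], res["n_replicates_quantified"])
    res["p_value"] = p
    res["degenerate"] = flagged
    if "protein_id" in filtered.columns:
        res["protein_id"] = filtered.groupby("peptide_key")["protein_id"].first()
    return res.reset_index()


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, y > 0)."""
    from scipy.special import polygamma

    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_f_dist(s2, df1) -> tuple[float, float]:
    """Moment-fit a scaled F prior to sample variances.

    Models s2_i ~ s0^2 * F(df1_i, d0) and returns ``(d0, s0_squared)``
    — the empirical-Bayes prior degrees of freedom and location used for
    variance moderation.  ``d0`` is ``inf`` when the observed log
    variances are less dispersed than chi-square sampling alone implies.
    """
    from scipy.special import digamma, polygamma

    s2 = np.asarray(s2, dtype=float)
    df1 = np.broadcast_to(np.asarray(df1, dtype=float), s2.shape)
    if s2.size < 2:
        raise ValidationError("variance moderation needs >= 2 peptides")
    x = np.maximum(s2, 1e-300)
    e = np.log(x) - digamma(df1 / 2.0) + np.log(df1 / 2.0)
    emean = float(e.mean())
    evar = float(((e - emean) ** 2).sum() / (e.size - 1))
    evar -= float(np.mean(polygamma(1, df1 / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s20 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # log-variances no more dispersed than chi-square sampling alone:
        # infinite prior df, prior variance = mean sample variance
        d0 = np.inf
        s20 = float(x.mean())
    return d0, s20


def moderated_t(filtered: pd.DataFrame) -> pd.DataFrame:
    """Per-peptide moderated one-sample t tests (empirical-Bayes variance).

    Each peptide's sample variance is shrunk toward an F-prior fitted
    across all peptides: the posterior variance is
    ``(d0*s0^2 + d*s^2) / (d0 + d)`` and the t statistic gains ``d0``
    degrees of freedom.  With few replicates this stabilizes the volcano
    against unlucky variance estimates; it is off by default in
    :func:`differential_analysis`.
    """
    g = filtered.groupby("peptide_key")["normalized_log2_ratio"]
    res = pd.DataFrame({
        "n_replicates_quantified": g.count(),
        "mean_log2": g.mean(),
        "sd_log2": g.std(ddof=1),
    })
    n = res["n_replicates_quantified"].to_numpy(dtype=float)
    s2 = res["sd_log2"].to_numpy(dtype=float) ** 2
    df1 = n - 1.0
    d0, s20 = fit_f_dist(s2, df1)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s20)
    else:
        s2_post = (d0 * s20 + df1 * s2) / (d0 + df1)
    # total df capped at the pooled residual df (all variances equal at most
    # amounts to pooling, never more information than that)
    df_total = np.minimum(df1 + d0, df1.sum())
    mean = res["mean_log2"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(s2_post / n)
    p = 2.0 * sps.t.sf(np.abs(t), df_total)
    res["p_value"] = np.clip(p, _P_SENTINEL, 1.0)
    res["degenerate"] = False
    res["prior_df"] = d0
    res["prior_var"] = s20
    if "protein_id" in filtered.columns:
        res["protein_id"] = filtered.groupby("peptide_key")["protein_id"].first()
    return res.reset_index()


def bh_fdr(p_values, fdr: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and pass flags.

    q_i = min over j with p_j >= p_i of p_(j) * n / rank(j), capped at 1;
    a peptide passes when q <= ``fdr``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return q, q <= fdr


def classify(results: pd.DataFrame, fdr: float = 0.10) -> pd.DataFrame:
    """Attach q-values and up/down/unchanged calls to test results."""
    out = results.copy()
    q, passed = bh_fdr(out["p_value"].to_numpy(), fdr=fdr)
    out["q_value"] = q
    direction = np.full(len(out), "unchanged", dtype=object)
    direction[passed & (out["mean_log2"].to_numpy() > 0)] = "up"
    direction[passed & (out["mean_log2"].to_numpy() < 0)] = "down"
    out["direction"] = direction
    return out


def volcano_table(classified: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot surface: mean log2 ratio vs -log10 p, with class."""
    return pd.DataFrame({
        "peptide_key": classified["peptide_key"],
        "mean_log2": classified["mean_log2"],
        "neg_log10_p": -np.log10(classified["p_value"]),
        "direction": classified["direction"],
    })


def differential_analysis(
    normalized: pd.DataFrame,
    min_replicates: int = 3,
    fdr: float = 0.10,
    phospho_only: bool = True,
    moderated: bool = False,
) -> pd.DataFrame:
    """Filter, test and classify peptides in one pass.

    By default only phosphopeptides are tested (non-phosphorylated
    peptides take part in normalization upstream but are not part of the
    differential phosphoproteome) with the unmoderated Student t;
    ``moderated=True`` switches to empirical-Bayes variance moderation.
    """
    table = normalized
    if phospho_only and "is_phospho" in table.columns:
        table = table[table["is_phospho"]]
    filtered, _ = filter_min_replicates(table, min_replicates=min_replicates)
    if filtered.empty:
        raise ValidationError("no peptides pass the replicate filter")
    tested = moderated_t(filtered) if moderated else test_peptides(filtered)
    return classify(tested, fdr=fdr)
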