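"""Iterative binomial phosphorylation-motif extraction and signed logos.

Given a foreground of fixed-width site windows (e.g. the up-regulated
sites) and a background (e.g. all confidently localized sites with the
same central residue class), motifs are grown greedily in the Motif-X
style: at each step every (offset, residue) pair whose foreground count
reaches ``min_occurrences`` is scored with an upper-tail binomial p-value
against its current background frequency; the most significant pair below
``p_threshold`` is fixed, both sets are reduced to the windows matching
every fixed pair, and the search repeats until no pair qualifies.  The
motif's score is the sum of the stage-wise -log10 p values and its fold
change compares foreground/background match proportions at the sizes
before any reduction.  Matched foreground windows are removed and the
search restarts for further motifs.

The logo matrix is the per-cell signed analogue: -log10 of the
upper-tail p for over-represented residues, +log10 of the lower-tail p
for under-represented ones, magnitudes capped for display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

from .errors import ValidationError

__all__ = [
    "MotifModel",
    "LogoMatrix",
    "position_residue_counts",
    "binomial_enrichment",
    "binomial_enrichment_log10",
    "binomial_depletion",
    "binomial_depletion_log10",
    "extract_motifs",
    "logo_matrix",
    "split_by_central_class",
]

log = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "_"


@dataclass(frozen=True)
class MotifModel:
    """One extracted motif: ordered fixed (offset, residue) pairs."""

    fixed: tuple[tuple[int, str], ...]
    central_residues: str            # e.g. "ST" for the pooled S/T class
    score: float                     # sum of stage-wise -log10 binomial p
    fold_change: float               # (fg frac)/(bg frac) at pre-reduction sizes
    fg_matches: int
    fg_size0: int
    bg_matches: int
    bg_size0: int
    stage_log10_pvalues: tuple[float, ...] = field(default=())

    @property
    def stage_pvalues(self) -> tuple[float, ...]:
        """Stage p-values on the linear scale (0.0 when below double range)."""
        return tuple(10.0 ** l for l in self.stage_log10_pvalues)

    @property
    def pattern(self) -> str:
        """13-char pattern, '.' for unconstrained, lowercase center."""
        half = 6
        chars = ["."] * (2 * half + 1)
        center = self.central_residues[0].lower() if len(self.central_residues) == 1 \
            else "s"  # pooled S/T class rendered as the canonical pS
        chars[half] = center
        for off, res in self.fixed:
            chars[half + off] = res
        return "".join(chars)


@dataclass(frozen=True)
class LogoMatrix:
    """Signed enrichment matrix over offsets x residues."""

    values: pd.DataFrame  # index: offsets, columns: residues
    fg_size: int
    bg_size: int
    cap: float


def _check_windows(windows, half_width: int = 6) -> list[str]:
    width = 2 * half_width + 1
    out = list(windows)
    for w in out:
        if len(w) != width:
            raise ValidationError(
                f"window {w!r} has length {len(w)}, expected {width}"
            )
    return out


def position_residue_counts(windows, half_width: int = 6) -> pd.DataFrame:
    """Count residues per window offset; '_' padding is ignored.

    Returns a DataFrame indexed by offsets -half_width..+half_width with
    one column per amino acid.
    """
    ws = _check_windows(windows, half_width)
    offsets = range(-half_width, half_width + 1)
    counts = pd.DataFrame(0, index=list(offsets), columns=list(AMINO_ACIDS))
    if not ws:
        return counts
    arr = np.array([list(w) for w in ws])
    for j, off in enumerate(offsets):
        col = arr[:, j]
        vals, cnts = np.unique(col[col != PAD], return_counts=True)
        for v, c in zip(vals, cnts):
            if v not in counts.columns:
                raise ValidationError(f"unexpected character {v!r} in window")
            counts.loc[off, v] = int(c)
    return counts


def _validate_tail_args(k: int, n: int, p0: float) -> None:
    if not 0 <= k <= n:
        raise ValidationError("require 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise ValidationError("background frequency p0 must lie in (0, 1)")


def binomial_enrichment_log10(k: int, n: int, p0: float) -> float:
    """log10 of the upper-tail p-value P(X >= k), X ~ Binomial(n, p0).

    Exact term-by-term summation in log space, so motif scores stay
    finite even when the p-value underflows double precision.
    """
    _validate_tail_args(k, n, p0)
    if k == 0:
        return 0.0
    j = np.arange(k, n + 1)
    return float(logsumexp(binom.logpmf(j, n, p0)) / np.log(10.0))


def binomial_enrichment(k: int, n: int, p0: float) -> float:
    """Upper-tail binomial p-value P(X >= k), X ~ Binomial(n, p0)."""
    return float(10.0 ** binomial_enrichment_log10(k, n, p0))


def binomial_depletion_log10(k: int, n: int, p0: float) -> float:
    """log10 of the lower-tail p-value P(X <= k)."""
    _validate_tail_args(k, n, p0)
    j = np.arange(0, k + 1)
    return float(logsumexp(binom.logpmf(j, n, p0)) / np.log(10.0))


def binomial_depletion(k: int, n: int, p0: float) -> float:
    """Lower-tail binomial p-value P(X <= k)."""
    return float(10.0 ** binomial_depletion_log10(k, n, p0))


def _matches(window: str, fixed: tuple[tuple[int, str], ...], half_width: int) -> bool:
    return all(window[half_width + off] == res for off, res in fixed)


def _best_pair(fg: list[str], bg: list[str], fixed_offsets: set[int],
               p_threshold: float, min_occurrences: int, half_width: int):
    """Most significant qualifying (offset, residue) pair, or None.

    Ties on p are broken by larger foreground count, then lexicographic
    (offset, residue), so extraction is deterministic.
    """
    fg_counts = position_residue_counts(fg, half_width)
    bg_counts = position_residue_counts(bg, half_width)
    fg_n = fg_counts.sum(axis=1)
    bg_n = bg_counts.sum(axis=1)
    best = None
    for off in fg_counts.index:
        if off == 0 or off in fixed_offsets:
            continue
        n = int(fg_n.loc[off])
        nb = int(bg_n.loc[off])
        if n == 0 or nb == 0:
            continue
        for res in AMINO_ACIDS:
            k = int(fg_counts.loc[off, res])
            if k < min_occurrences:
                continue
            kb = int(bg_counts.loc[off, res])
            p0 = (kb if kb > 0 else 0.5) / nb  # pseudo-count keeps p0 in (0,1)
            p0 = min(p0, 1.0 - 1e-12)
            l10 = binomial_enrichment_log10(k, n, p0)
            if l10 >= np.log10(p_threshold):
                continue
            cand = (l10, -k, off, res)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    l10, negk, off, res = best
    return off, res, l10


def _extract_one(fg: list[str], bg: list[str], p_threshold: float,
                 min_occurrences: int, half_width: int,
                 central_residues: str) -> MotifModel | None:
    fg_size0, bg_size0 = len(fg), len(bg)
    cur_fg, cur_bg = list(fg), list(bg)
    fixed: list[tuple[int, str]] = []
    stage_l10: list[float] = []
    while True:
        hit = _best_pair(cur_fg, cur_bg, {o for o, _ in fixed},
                         p_threshold, min_occurrences, half_width)
        if hit is None:
            break
        off, res, l10 = hit
        fixed.append((off, res))
        stage_l10.append(l10)
        cur_fg = [w for w in cur_fg if w[half_width + off] == res]
        cur_bg = [w for w in cur_bg if w[half_width + off] == res]
    if not fixed:
        return None
    fg_frac = len(cur_fg) / fg_size0
    bg_frac = max(len(cur_bg), 0.5) / bg_size0  # pseudo-count: fold stays finite
    score = float(-sum(stage_l10))
    return MotifModel(
        fixed=tuple(fixed),
        central_residues=central_residues,
        score=score,
        fold_change=fg_frac / bg_frac,
        fg_matches=len(cur_fg),
        fg_size0=fg_size0,
        bg_matches=len(cur_bg),
        bg_size0=bg_size0,
        stage_log10_pvalues=tuple(stage_l10),
    )


def extract_motifs(
    foreground,
    background,
    p_threshold: float = 1e-6,
    min_occurrences: int = 20,
    half_width: int = 6,
    central_residues: str = "ST",
) -> list[MotifModel]:
    """Greedy iterative motif extraction (Motif-X style).

    Extracts motifs one at a time; after each motif, its matching
    foreground windows are removed and the search restarts against the
    full background.  Returns motifs in extraction order.
    """
    fg = _check_windows(foreground, half_width)
    bg = _check_windows(background, half_width)
    if not fg or not bg:
        raise ValidationError("foreground and background must be nonempty")
    if min_occurrences > len(fg):
        log.warning(
            "min_occurrences=%d exceeds foreground size %d; no motifs possible",
            min_occurrences, len(fg),
        )
        return []
    motifs: list[MotifModel] = []
    remaining = fg
    while remaining:
        model = _extract_one(remaining, bg, p_threshold, min_occurrences,
                             half_width, central_residues)
        if model is None:
            break
        motifs.append(model)
        remaining = [w for w in remaining if not _matches(w, model.fixed, half_width)]
    return motifs


def logo_matrix(
    foreground, background, cap: float = 10.0, half_width: int = 6
) -> LogoMatrix:
    """Signed information logo matrix over offsets x residues.

    Positive values mark over-representation (-log10 upper-tail p),
    negative values under-representation (+log10 lower-tail p);
    magnitudes are capped at ``cap``.  The center cell reports the
    central-residue composition like any other cell.
    """
    fg = _check_windows(foreground, half_width)
    bg = _check_windows(background, half_width)
    if not fg or not bg:
        raise ValidationError("foreground and background must be nonempty")
    fg_counts = position_residue_counts(fg, half_width)
    bg_counts = position_residue_counts(bg, half_width)
    fg_n = fg_counts.sum(axis=1)
    bg_n = bg_counts.sum(axis=1)
    values = pd.DataFrame(0.0, index=fg_counts.index, columns=fg_counts.columns)
    for off in fg_counts.index:
        n = int(fg_n.loc[off])
        nb = int(bg_n.loc[off])
        if n == 0 or nb == 0:
            continue
        for res in AMINO_ACIDS:
            k = int(fg_counts.loc[off, res])
            kb = int(bg_counts.loc[off, res])
            p0 = (kb if kb > 0 else 0.5) / nb
            p0 = min(p0, 1.0 - 1e-12)
            if k / n > p0:
                v = min(-binomial_enrichment_log10(k, n, p0), cap)
            else:
                v = -min(-binomial_depletion_log10(k, n, p0), cap)
            values.loc[off, res] = v
    return LogoMatrix(values=values, fg_size=len(fg), bg_size=len(bg), cap=cap)


def split_by_central_class(
    windows, pool_st: bool = True, half_width: int = 6
) -> dict[str, list[str]]:
    """Group windows by central residue class ('ST' pooled by default, 'Y')."""
    ws = _check_windows(windows, half_width)
    out: dict[str, list[str]] = {}
    for w in ws:
        c = w[half_width]
        key = "ST" if (pool_st and c in "ST") else c
        out.setdefault(key, []).append(w)
    return out
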