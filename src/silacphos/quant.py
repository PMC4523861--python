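"""Peptide-level SILAC quantification: ratio of summed channel intensities.

The quantification of a unique peptide (its full modified sequence,
including phosphosite placement, is the identity key) in one biological
replicate is the sum of its raw channel intensities over all charge
states, SCX fractions and repeated PSM events — a *ratio of sums*, not a
mean of per-event ratios.  The treated/control log2 ratio is then
normalized by subtracting the replicate's median log2 ratio, computed by
default over all quantified peptides including those from the
non-phosphorylated fractions.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "is_phospho_key",
    "sum_by_peptide",
    "compute_ratio",
    "normalize_replicates",
]

log = logging.getLogger(__name__)

_REQUIRED = ("peptide_key", "replicate_id", "heavy", "light")


def is_phospho_key(peptide_key: str) -> bool:
    """A peptide key encodes phosphosites as lowercase residues."""
    return any(c.islower() for c in peptide_key)


def _validate_records(records: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED if c not in records.columns]
    if missing:
        raise ValidationError(f"quantification table missing columns: {missing}")
    if len(records) and (
        (records["heavy"] < 0).any() or (records["light"] < 0).any()
    ):
        raise ValidationError("channel intensities must be >= 0")


def sum_by_peptide(records: pd.DataFrame) -> pd.DataFrame:
    """Sum channel intensities per (peptide_key, replicate).

    Events differing only in charge state, fraction or PSM multiplicity
    collapse into one row; peptides with different modification placements
    have different keys and stay distinct.  An event with one zero channel
    still contributes its other channel to that channel's sum.
    """
    _validate_records(records)
    if records.empty:
        return pd.DataFrame(columns=[
            "peptide_key", "replicate_id", "protein_id",
            "summed_heavy", "summed_light", "is_phospho",
        ])
    keep_protein = "protein_id" in records.columns
    grouped = records.groupby(["peptide_key", "replicate_id"], sort=True)
    out = grouped[["heavy", "light"]].sum().rename(
        columns={"heavy": "summed_heavy", "light": "summed_light"}
    )
    if keep_protein:
        out["protein_id"] = grouped["protein_id"].first()
    out = out.reset_index()
    out["is_phospho"] = out["peptide_key"].map(is_phospho_key)
    cols = ["peptide_key", "replicate_id"]
    if keep_protein:
        cols.append("protein_id")
    cols += ["summed_heavy", "summed_light", "is_phospho"]
    return out[cols]


def compute_ratio(
    summed: pd.DataFrame,
    orientation: str | Mapping[str, str] = "heavy",
) -> pd.DataFrame:
    """Attach log2 treated/control ratios to summed intensities.

    ``orientation`` names the treated channel, globally ('heavy', the
    default, or 'light') or per replicate as a mapping.  Rows where either
    channel sum is zero are flagged with a reason code in ``status``
    rather than dropped; their ``log2_ratio`` is NaN.
    """
    reps = summed["replicate_id"].unique() if len(summed) else np.array([])
    if isinstance(orientation, str):
        if orientation not in ("heavy", "light"):
            raise ConfigurationError("orientation must be 'heavy' or 'light'")
        omap = {r: orientation for r in reps}
    else:
        unknown = set(orientation) - set(reps)
        if unknown:
            raise ConfigurationError(
                f"orientation names unknown replicates: {sorted(unknown)}"
            )
        missing = set(reps) - set(orientation)
        if missing:
            raise ConfigurationError(
                f"orientation missing replicates: {sorted(missing)}"
            )
        bad = {r: c for r, c in orientation.items() if c not in ("heavy", "light")}
        if bad:
            raise ConfigurationError(f"invalid treated channel: {bad}")
        omap = dict(orientation)

    out = summed.copy()
    if not len(out):
        for c in ("treated_sum", "control_sum", "log2_ratio"):
            out[c] = pd.Series(dtype=float)
        out["status"] = pd.Series(dtype=object)
        return out
    treated_is_heavy = out["replicate_id"].map(omap).eq("heavy").to_numpy()
    h = out["summed_heavy"].to_numpy(dtype=float)
    l = out["summed_light"].to_numpy(dtype=float)
    treated = np.where(treated_is_heavy, h, l)
    control = np.where(treated_is_heavy, l, h)
    out["treated_sum"] = treated
    out["control_sum"] = control
    status = np.full(len(out), "ok", dtype=object)
    status[(treated == 0) & (control > 0)] = "zero-numerator"
    status[(control == 0) & (treated > 0)] = "zero-denominator"
    status[(treated == 0) & (control == 0)] = "zero-both"
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(treated) - np.log2(control)
    ratio[status != "ok"] = np.nan
    out["log2_ratio"] = ratio
    out["status"] = status
    n_bad = int((status != "ok").sum())
    if n_bad:
        log.info("compute_ratio: %d rows unquantified (zero channel sum)", n_bad)
    return out


def normalize_replicates(
    ratios: pd.DataFrame, include_nonphospho: bool = True
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Median-center log2 ratios within each biological replicate.

    The normalization offset is the median log2 ratio of the normalization
    population: all quantified peptides by default (phospho and
    non-phospho), or phosphopeptides only when ``include_nonphospho`` is
    False.  Returns the table with a ``normalized_log2_ratio`` column and
    the per-replicate offsets.  After normalization the median of the
    normalization population is exactly 0 in each replicate (a single
    refinement pass absorbs floating-point residue).
    """
    if ratios.empty:
        raise ValidationError("cannot normalize an empty ratio table")
    out = ratios.copy()
    out["normalized_log2_ratio"] = np.nan
    offsets: dict[str, float] = {}
    for rep, idx in out.groupby("replicate_id").groups.items():
        sub = out.loc[idx]
        quantified = sub["status"] == "ok"
        if not quantified.any():
            raise ValidationError(f"replicate {rep!r} has no quantified peptides")
        pop = quantified if include_nonphospho else quantified & sub["is_phospho"]
        if not pop.any():
            raise ValidationError(
                f"replicate {rep!r}: empty normalization population"
            )
        vals = sub.loc[pop, "log2_ratio"].to_numpy()
        offset = float(np.median(vals))
        # one refinement pass so the post-normalization median is exactly 0
        offset += float(np.median(vals - offset))
        offsets[str(rep)] = offset
        out.loc[idx, "normalized_log2_ratio"] = sub["log2_ratio"] - offset
    return out, offsets
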