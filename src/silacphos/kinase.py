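"""Kinase-motif classification of site windows and PSSM scoring.

Windows are assigned to broad kinase substrate classes by a declarative
rule table evaluated in priority order: proline-directed (P at +1;
strict mode additionally requires P at -2) characteristic of CDK/MAPK
substrates, basophilic (R/K at -3 or -2, H at -3) characteristic of
AGC/CAMK substrates, acidophilic (>= 2 acidic residues at +1..+3,
CK2-like), else 'other'.  Sites can additionally be scored against
user-supplied kinase position-specific scoring matrices (log-odds
weights over offsets x residues, additive over non-padding positions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "MotifClassRule",
    "KinasePSSM",
    "default_rules",
    "classify_window",
    "summarize_classes",
    "pssm_score",
    "score_table",
]

PAD = "_"
HALF = 6


@dataclass(frozen=True)
class MotifClassRule:
    """One class rule: fires when >= min_matches of (offset, residue) hold."""

    name: str
    features: tuple[tuple[int, str], ...]
    min_matches: int = 1

    def matches(self, window: str, half_width: int = HALF) -> bool:
        hits = sum(
            1 for off, res in self.features
            if window[half_width + off] == res
        )
        return hits >= self.min_matches


def default_rules(strict_proline: bool = False) -> tuple[MotifClassRule, ...]:
    """Priority-ordered rule table (data, editable without code changes)."""
    if strict_proline:
        proline = MotifClassRule(
            "proline-directed", ((+1, "P"), (-2, "P")), min_matches=2
        )
    else:
        proline = MotifClassRule("proline-directed", ((+1, "P"),))
    return (
        proline,
        MotifClassRule(
            "basophilic",
            ((-3, "R"), (-3, "K"), (-3, "H"), (-2, "R"), (-2, "K")),
        ),
        MotifClassRule(
            "acidophilic",
            ((+1, "D"), (+1, "E"), (+2, "D"), (+2, "E"), (+3, "D"), (+3, "E")),
            min_matches=2,
        ),
    )


def classify_window(
    window: str,
    rules: tuple[MotifClassRule, ...] | None = None,
    half_width: int = HALF,
) -> str:
    """Assign a window to exactly one motif class (first matching rule)."""
    if len(window) != 2 * half_width + 1:
        raise ValidationError(
            f"window {window!r} has length {len(window)}, "
            f"expected {2 * half_width + 1}"
        )
    for rule in rules if rules is not None else default_rules():
        if rule.matches(window, half_width):
            return rule.name
    return "other"


def summarize_classes(
    up_windows, down_windows,
    rules: tuple[MotifClassRule, ...] | None = None,
) -> pd.DataFrame:
    """Class x direction contingency table with proportions, by count."""
    rows = []
    for direction, windows in (("up", up_windows), ("down", down_windows)):
        windows = list(windows)
        classes = pd.Series(
            [classify_window(w, rules) for w in windows], dtype=object
        )
        total = len(windows)
        names = [r.name for r in (rules if rules is not None else default_rules())]
        names.append("other")
        counts = classes.value_counts()
        for name in names:
            c = int(counts.get(name, 0))
            rows.append({
                "direction": direction,
                "motif_class": name,
                "count": c,
                "proportion": c / total if total else 0.0,
            })
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["direction", "count"], ascending=[True, False]
    ).reset_index(drop=True)


@dataclass(frozen=True)
class KinasePSSM:
    """Additive log-odds matrix for one kinase's substrate preference."""

    name: str
    family: str
    weights: pd.DataFrame  # index: offsets, columns: residues

    def __post_init__(self) -> None:
        if not np.isfinite(self.weights.to_numpy(dtype=float)).all():
            raise ValidationError(f"PSSM {self.name}: weights must be finite")


def pssm_score(window: str, pssm: KinasePSSM, half_width: int = HALF) -> float:
    """Sum of matrix weights over the window's non-padding offsets."""
    if len(window) != 2 * half_width + 1:
        raise ValidationError(f"window {window!r} has wrong length")
    total = 0.0
    for off in pssm.weights.index:
        res = window[half_width + int(off)]
        if res == PAD:
            continue
        if res not in pssm.weights.columns:
            raise ValidationError(
                f"residue {res!r} absent from PSSM {pssm.name} alphabet"
            )
        total += float(pssm.weights.loc[off, res])
    return total


def score_table(windows, pssms) -> pd.DataFrame:
    """Score every window against every PSSM (windows x kinases)."""
    data = {
        pssm.name: [pssm_score(w, pssm) for w in windows] for pssm in pssms
    }
    out = pd.DataFrame(data, index=list(windows))
    out.index.name = "window"
    return out
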