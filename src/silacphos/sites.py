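"""Anchor phosphopeptides to protein coordinates and extract site windows.

Peptide-level evidence is mapped onto protein sequences (1-based
coordinates), filtered by phosphosite localization confidence (a
phosphoRS-style 0-100 score; sites are retained when their best
supporting score is strictly above the threshold), and summarized as
fixed-width sequence windows (13-mer by default, '_'-padded at protein
termini) centered on the phosphorylated residue — the substrate for motif
analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import MappingError, ValidationError
from .quant import is_phospho_key

__all__ = [
    "map_peptide_to_protein",
    "extract_window",
    "peptide_site_events",
    "build_site_table",
    "filter_localization",
    "aggregate_peptides_to_sites",
]

log = logging.getLogger(__name__)

PAD = "_"


def map_peptide_to_protein(
    peptide_key: str, protein_seq: str, protein_id: str = "?"
) -> list[tuple[int, str]]:
    """Locate a phosphopeptide's sites in its protein.

    Returns ``(protein_position, residue)`` pairs, 1-based, one per
    phosphosite (lowercase residue) in the key.  The peptide's plain
    sequence must occur as a substring of the protein; if it occurs more
    than once the first occurrence is used and a warning logged.
    """
    plain = peptide_key.upper()
    start = protein_seq.find(plain)
    if start < 0:
        raise MappingError(
            f"peptide {peptide_key!r} not found in protein {protein_id}"
        )
    if protein_seq.find(plain, start + 1) >= 0:
        log.warning(
            "peptide %s occurs more than once in %s; using first occurrence",
            peptide_key, protein_id,
        )
    sites = []
    for i, c in enumerate(peptide_key):
        if c.islower():
            pos = start + i + 1  # 1-based protein coordinate
            sites.append((pos, c.upper()))
    return sites


def extract_window(protein_seq: str, position: int, half_width: int = 6) -> str:
    """Sequence window of ``2*half_width + 1`` residues centered on ``position``.

    ``position`` is 1-based; out-of-range flanks are padded with '_'.
    """
    if not 1 <= position <= len(protein_seq):
        raise ValidationError(
            f"position {position} outside protein of length {len(protein_seq)}"
        )
    i = position - 1
    left = protein_seq[max(0, i - half_width):i]
    right = protein_seq[i + 1:i + 1 + half_width]
    return (PAD * (half_width - len(left)) + left + protein_seq[i]
            + right + PAD * (half_width - len(right)))


def peptide_site_events(
    records: pd.DataFrame, proteome: dict[str, str]
) -> pd.DataFrame:
    """Explode PSM events into per-site rows with protein coordinates.

    Input rows carry semicolon-separated ``site_positions`` (1-based
    within the peptide) and aligned ``localization_scores``.  Output has
    one row per (event, site) with protein position, residue and score.
    """
    phos = records[records["peptide_key"].map(is_phospho_key)]
    if phos.empty:
        return pd.DataFrame(columns=[
            "peptide_key", "protein_id", "replicate_id",
            "position", "residue", "localization_score",
        ])
    # map each unique peptide once
    site_map: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for key, pid in phos[["peptide_key", "protein_id"]].drop_duplicates().itertuples(index=False):
        if pid not in proteome:
            raise MappingError(f"protein {pid} absent from proteome")
        site_map[(key, pid)] = map_peptide_to_protein(key, proteome[pid], pid)
    rows = []
    for rec in phos.itertuples(index=False):
        mapped = site_map[(rec.peptide_key, rec.protein_id)]
        scores = [float(s) for s in str(rec.localization_scores).split(";") if s != ""]
        if len(scores) != len(mapped):
            raise ValidationError(
                f"peptide {rec.peptide_key!r}: {len(scores)} localization scores "
                f"for {len(mapped)} sites"
            )
        for (pos, res), score in zip(mapped, scores):
            rows.append((rec.peptide_key, rec.protein_id, rec.replicate_id,
                         pos, res, score))
    return pd.DataFrame(rows, columns=[
        "peptide_key", "protein_id", "replicate_id",
        "position", "residue", "localization_score",
    ])


def build_site_table(
    records: pd.DataFrame, proteome: dict[str, str], half_width: int = 6
) -> pd.DataFrame:
    """Unique protein sites with best localization score and window.

    The best score is the max over all supporting PSM events (one
    confident observation suffices to localize a site).
    """
    events = peptide_site_events(records, proteome)
    if events.empty:
        return pd.DataFrame(columns=[
            "protein_id", "position", "residue",
            "best_localization_score", "window", "peptide_keys",
        ])
    grouped = events.groupby(["protein_id", "position"], sort=True)
    out = pd.DataFrame({
        "residue": grouped["residue"].first(),
        "best_localization_score": grouped["localization_score"].max(),
        "peptide_keys": grouped["peptide_key"].unique().map(lambda a: ";".join(sorted(a))),
    }).reset_index()
    out["window"] = [
        extract_window(proteome[pid], pos, half_width)
        for pid, pos in zip(out["protein_id"], out["position"])
    ]
    return out[["protein_id", "position", "residue",
                "best_localization_score", "window", "peptide_keys"]]


def filter_localization(sites: pd.DataFrame, threshold: float = 80.0) -> pd.DataFrame:
    """Keep sites whose best localization score is strictly above threshold."""
    scores = sites["best_localization_score"]
    if len(sites) and ((scores < 0).any() or (scores > 100).any()):
        raise ValidationError("localization scores must lie in [0, 100]")
    return sites[scores > threshold].copy()


def aggregate_peptides_to_sites(
    classified: pd.DataFrame, site_table: pd.DataFrame
) -> pd.DataFrame:
    """Roll peptide-level differential calls up to unique sites.

    A site inherits the direction of its supporting tested peptide(s);
    duplicates (e.g. missed-cleavage variants) collapse to one record.  A
    site supported by both an up and a down peptide is flagged
    ``conflict`` and should be excluded from motif foregrounds.  Regulated
    evidence outranks 'unchanged' support.
    """
    calls = dict(zip(classified["peptide_key"], classified["direction"]))
    rows = []
    for rec in site_table.itertuples(index=False):
        dirs = {calls[k] for k in rec.peptide_keys.split(";") if k in calls}
        if not dirs:
            continue  # no supporting peptide was testable
        if "up" in dirs and "down" in dirs:
            direction = "conflict"
        elif "up" in dirs:
            direction = "up"
        elif "down" in dirs:
            direction = "down"
        else:
            direction = "unchanged"
        rows.append(rec._asdict() | {"direction": direction})
    out = pd.DataFrame(rows)
    n_conf = int((out["direction"] == "conflict").sum()) if len(out) else 0
    if n_conf:
        log.warning("aggregate_peptides_to_sites: %d conflicting sites", n_conf)
    return out
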