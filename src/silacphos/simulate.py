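"""Synthetic SILAC phosphoproteomics data with planted ground truth.

Emulates the structure of a two-channel (heavy/light) SILAC experiment on
cultured cells: a proteome of random protein sequences, tryptic-scale
peptides observed as multiple PSM events across charge states and strong
cation exchange (SCX) fractions, several biological replicates with
log-normal intensities, per-replicate global log2 biases (to exercise
median normalization), missing replicates, and phosphosite localization
scores drawn from a high-confidence / ambiguous mixture.

A configurable fraction of phosphopeptides carries a planted log2
treated/control effect tied to a sequence motif written into the protein
itself (by default arginine at -3 for up-regulated sites — a basophilic
kinase motif — and proline at +1 for down-regulated sites — a
proline-directed motif), so every downstream stage of the pipeline can be
checked against known truth.

The log2 measurement noise is drawn once per peptide x replicate and
shared by that pair's PSM events; intensities are split across events by a
Dirichlet-like partition.  This preserves the ratio-of-sums identity
``log2(sum H / sum L) = effect + bias + noise`` exactly, so the planted
effect is recoverable without estimator bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "PlantedMotif",
    "SyntheticConfig",
    "GroundTruth",
    "generate_proteome",
    "generate_quant_table",
    "simulate_dataset",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Approximate vertebrate proteome residue frequencies; renormalized in code.
DEFAULT_RESIDUE_FREQS: dict[str, float] = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.048, "C": 0.022,
    "Q": 0.044, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.044,
    "L": 0.100, "K": 0.058, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.054, "W": 0.011, "Y": 0.027, "V": 0.060,
}

# Reserved stretch per peptide within a protein; edits (site + planted motif
# residues) stay inside the slot so peptides never interfere.
_SLOT_LEN = 30
_SLOT_MARGIN = 8

QUANT_COLUMNS = [
    "peptide_key", "protein_id", "charge", "fraction_id", "replicate_id",
    "heavy", "light", "site_positions", "localization_scores",
]


@dataclass(frozen=True)
class PlantedMotif:
    """A fixed (offset, residue) feature tied to a regulation direction."""

    offset: int
    residue: str
    direction: str  # "up" or "down"

    def __post_init__(self) -> None:
        if self.offset == 0:
            raise ValidationError("planted_motifs: offset 0 is the phosphosite itself")
        if abs(self.offset) > 6:
            raise ValidationError("planted_motifs: offset must lie in [-6, 6]")
        if self.residue not in AMINO_ACIDS:
            raise ValidationError(f"planted_motifs: unknown residue {self.residue!r}")
        if self.direction not in ("up", "down"):
            raise ValidationError("planted_motifs: direction must be 'up' or 'down'")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic experiment.

    Defaults describe the emulated study design: four biological
    replicates, SCX fractionation, peptides seen in charge states 2-3,
    ~5% of phosphopeptides regulated in each direction with a planted
    |log2| effect of 1.0 and log2 measurement noise of 0.3.
    """

    n_proteins: int = 300
    protein_length_mean: float = 400.0
    protein_length_sd: float = 80.0
    n_phosphopeptides: int = 2000
    n_nonphospho_peptides: int = 1000
    n_replicates: int = 4
    n_fractions: int = 6
    charge_states: tuple[int, ...] = (2, 3)
    frac_up: float = 0.05
    frac_down: float = 0.05
    effect_log2: float = 1.0
    noise_sd: float = 0.3
    intensity_log10_mean: float = 6.5
    intensity_log10_sd: float = 0.6
    global_bias: float | Sequence[float] = 0.0
    planted_motifs: tuple[PlantedMotif, ...] = (
        PlantedMotif(-3, "R", "up"),
        PlantedMotif(+1, "P", "down"),
    )
    loc_high_weight: float = 0.75
    loc_high_mean: float = 93.0
    loc_high_sd: float = 4.0
    loc_low_mean: float = 60.0
    loc_low_sd: float = 12.0
    missing_rate: float = 0.1
    treated_channel: str | Mapping[str, str] = "heavy"
    residue_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_FREQS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_phosphopeptides", "n_nonphospho_peptides",
                     "n_replicates", "n_fractions"):
            if int(getattr(self, name)) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not self.charge_states:
            raise ValidationError("charge_states must be nonempty")
        if any(int(z) < 1 for z in self.charge_states):
            raise ValidationError("charge_states must be integers >= 1")
        if not (0.0 <= self.frac_up <= 1.0 and 0.0 <= self.frac_down <= 1.0):
            raise ValidationError("frac_up/frac_down must lie in [0, 1]")
        if self.frac_up + self.frac_down > 1.0:
            raise ValidationError("frac_up + frac_down must be <= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.protein_length_sd < 0:
            raise ValidationError("protein_length_sd must be >= 0")
        if not 0.0 <= float(np.min(self.missing_rate)) or not 0.0 <= float(np.max(self.missing_rate)) <= 1.0:
            raise ValidationError("missing_rate must lie in [0, 1]")
        freqs = np.asarray([self.residue_freqs.get(a, 0.0) for a in AMINO_ACIDS])
        if freqs.sum() <= 0 or (freqs < 0).any():
            raise ValidationError("residue_freqs must be nonnegative with positive sum")
        bias = np.atleast_1d(np.asarray(self.global_bias, dtype=float))
        if bias.size not in (1, self.n_replicates):
            raise ValidationError(
                "global_bias must be a scalar or one value per replicate"
            )
        if isinstance(self.treated_channel, str):
            if self.treated_channel not in ("heavy", "light"):
                raise ValidationError("treated_channel must be 'heavy' or 'light'")
        else:
            for rep, ch in self.treated_channel.items():
                if ch not in ("heavy", "light"):
                    raise ValidationError(
                        f"treated_channel[{rep!r}] must be 'heavy' or 'light'"
                    )

    # -- derived views ---------------------------------------------------
    @property
    def replicate_ids(self) -> list[str]:
        return [f"R{i + 1}" for i in range(self.n_replicates)]

    def bias_vector(self) -> np.ndarray:
        bias = np.atleast_1d(np.asarray(self.global_bias, dtype=float))
        if bias.size == 1:
            bias = np.repeat(bias, self.n_replicates)
        return bias

    def orientation_map(self) -> dict[str, str]:
        """Which channel carries the treated sample, per replicate."""
        if isinstance(self.treated_channel, str):
            return {r: self.treated_channel for r in self.replicate_ids}
        missing = set(self.replicate_ids) - set(self.treated_channel)
        if missing:
            raise ValidationError(
                f"treated_channel missing replicates: {sorted(missing)}"
            )
        return {r: self.treated_channel[r] for r in self.replicate_ids}


@dataclass
class GroundTruth:
    """Planted truth for one simulated dataset.

    ``peptides`` has one row per peptide with its true log2 treated/control
    effect, regulation flag/direction, planted motif class and protein
    coordinates.  ``proteome`` is the (possibly edited) protein set the
    quantified peptides were extracted from: planted motif residues are
    written into the proteins so site windows genuinely carry the motif.
    """

    peptides: pd.DataFrame
    proteome: dict[str, str]
    config: SyntheticConfig


def _length_bounds(cfg: SyntheticConfig) -> tuple[int, int]:
    lo = max(2 * _SLOT_MARGIN + _SLOT_LEN,
             int(cfg.protein_length_mean - 3 * cfg.protein_length_sd))
    hi = int(math.ceil(cfg.protein_length_mean + 3 * cfg.protein_length_sd))
    return lo, max(hi, lo)


def generate_proteome(config: SyntheticConfig) -> dict[str, str]:
    """Draw ``n_proteins`` random sequences over the 20 amino acids.

    Lengths are normal(mean, sd) truncated to mean +/- 3 sd (and to the
    minimum length that can host one peptide slot); residues are i.i.d.
    from ``config.residue_freqs``.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    freqs = np.asarray([config.residue_freqs.get(a, 0.0) for a in AMINO_ACIDS])
    freqs = freqs / freqs.sum()
    lo, hi = _length_bounds(config)
    lengths = rng.normal(config.protein_length_mean, config.protein_length_sd,
                         config.n_proteins)
    lengths = np.clip(np.rint(lengths), lo, hi).astype(int)
    letters = np.array(list(AMINO_ACIDS))
    proteome: dict[str, str] = {}
    for i, n in enumerate(lengths):
        seq = "".join(rng.choice(letters, size=n, p=freqs))
        proteome[f"SYNP{i + 1:05d}"] = seq
    return proteome


def _allocate_slots(proteome: dict[str, str], n_needed: int,
                    rng: np.random.Generator) -> list[tuple[str, int]]:
    slots: list[tuple[str, int]] = []
    for pid, seq in proteome.items():
        start = _SLOT_MARGIN
        while start + _SLOT_LEN <= len(seq) - _SLOT_MARGIN:
            slots.append((pid, start))
            start += _SLOT_LEN
    if len(slots) < n_needed:
        raise ValidationError(
            f"proteome hosts only {len(slots)} peptide slots; "
            f"{n_needed} peptides requested (raise n_proteins or lengths)"
        )
    order = rng.permutation(len(slots))
    return [slots[i] for i in order[:n_needed]]


def _build_peptides(config: SyntheticConfig, proteome: dict[str, str],
                    rng: np.random.Generator) -> tuple[pd.DataFrame, dict[str, str]]:
    """Carve peptides out of (a mutable copy of) the proteome and plant truth."""
    seqs = {pid: list(s) for pid, s in proteome.items()}
    n_total = config.n_phosphopeptides + config.n_nonphospho_peptides
    slots = _allocate_slots(proteome, n_total, rng)

    n_up = int(round(config.frac_up * config.n_phosphopeptides))
    n_down = int(round(config.frac_down * config.n_phosphopeptides))
    directions = (["up"] * n_up + ["down"] * n_down
                  + ["none"] * (config.n_phosphopeptides - n_up - n_down))

    rows = []
    # Phase 1: choose sites and write site/motif residues into the proteins.
    placements = []
    for i in range(config.n_phosphopeptides):
        pid, start = slots[i]
        site_idx = start + _SLOT_LEN // 2  # 0-based protein index
        seqs[pid][site_idx] = "S" if rng.random() < 0.7 else "T"
        direction = directions[i]
        if direction != "none":
            for m in config.planted_motifs:
                if m.direction == direction:
                    seqs[pid][site_idx + m.offset] = m.residue
        placements.append((pid, site_idx, direction))
    # Phase 2: extract peptide sequences after all edits are in place.
    for pid, site_idx, direction in placements:
        a = int(rng.integers(4, 11))
        b = int(rng.integers(4, 11))
        left, right = site_idx - a, site_idx + b  # inclusive
        seq = "".join(seqs[pid][left:right + 1])
        pep_pos = site_idx - left + 1  # 1-based position of site in peptide
        key = seq[:pep_pos - 1] + seq[pep_pos - 1].lower() + seq[pep_pos:]
        effect = {"up": config.effect_log2, "down": -config.effect_log2,
                  "none": 0.0}[direction]
        motif_class = ""
        if direction != "none":
            motif_class = ";".join(
                f"{m.residue}@{m.offset:+d}" for m in config.planted_motifs
                if m.direction == direction
            )
        rows.append({
            "peptide_key": key, "protein_id": pid, "is_phospho": True,
            "site_protein_pos": site_idx + 1, "site_peptide_pos": pep_pos,
            "true_log2_effect": effect, "regulated": direction != "none",
            "direction": direction, "motif_class": motif_class,
        })
    for i in range(config.n_nonphospho_peptides):
        pid, start = slots[config.n_phosphopeptides + i]
        length = int(rng.integers(9, 22))
        left = start + 4
        seq = "".join(seqs[pid][left:left + length])
        rows.append({
            "peptide_key": seq, "protein_id": pid, "is_phospho": False,
            "site_protein_pos": 0, "site_peptide_pos": 0,
            "true_log2_effect": 0.0, "regulated": False,
            "direction": "none", "motif_class": "",
        })
    peptides = pd.DataFrame(rows)
    edited = {pid: "".join(chars) for pid, chars in seqs.items()}
    return peptides, edited


def generate_quant_table(
    config: SyntheticConfig, proteome: dict[str, str]
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the PSM-level quantification table.

    Returns the event table (one row per peptide x charge x fraction x
    replicate with heavy/light intensities) and the :class:`GroundTruth`.
    Use ``GroundTruth.proteome`` downstream: planted motif residues are
    written into those sequences.
    """
    if not proteome:
        raise ValidationError("proteome must be nonempty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    peptides, edited = _build_peptides(config, proteome, rng)

    n_pep = len(peptides)
    n_rep = config.n_replicates
    bias = config.bias_vector()
    missing = np.broadcast_to(
        np.atleast_1d(np.asarray(config.missing_rate, dtype=float)), (n_rep,)
    ) if np.ndim(config.missing_rate) else np.full(n_rep, config.missing_rate)

    present = rng.random((n_pep, n_rep)) >= missing[None, :]
    noise = rng.normal(0.0, config.noise_sd, (n_pep, n_rep))
    true = peptides["true_log2_effect"].to_numpy()
    r_log2 = true[:, None] + bias[None, :] + noise  # log2 treated/control
    base = np.power(10.0, rng.normal(config.intensity_log10_mean,
                                     config.intensity_log10_sd, (n_pep, n_rep)))

    pep_i, rep_i = np.nonzero(present)
    n_pairs = pep_i.size
    max_events = max(2, len(config.charge_states)) * 2
    n_events = rng.integers(1, max_events + 1, n_pairs)
    total = int(n_events.sum())
    ev_pair = np.repeat(np.arange(n_pairs), n_events)
    offsets = np.concatenate(([0], np.cumsum(n_events)[:-1]))

    charges = rng.choice(np.asarray(config.charge_states), size=total)
    fractions = rng.integers(0, config.n_fractions, total)
    w = rng.exponential(1.0, total)
    w = w / np.add.reduceat(w, offsets)[ev_pair]

    control_total = base[pep_i, rep_i]
    ratio = np.exp2(r_log2[pep_i, rep_i])
    control_e = control_total[ev_pair] * w
    treated_e = control_e * ratio[ev_pair]

    orientation = config.orientation_map()
    rep_ids = np.asarray(config.replicate_ids)
    treated_is_heavy = np.asarray(
        [orientation[r] == "heavy" for r in config.replicate_ids]
    )[rep_i][ev_pair]
    heavy = np.where(treated_is_heavy, treated_e, control_e)
    light = np.where(treated_is_heavy, control_e, treated_e)

    # localization scores: high-confidence vs ambiguous mixture, clipped
    is_high = rng.random(total) < config.loc_high_weight
    loc = np.where(
        is_high,
        rng.normal(config.loc_high_mean, config.loc_high_sd, total),
        rng.normal(config.loc_low_mean, config.loc_low_sd, total),
    )
    loc = np.clip(loc, 0.0, 100.0)

    keys = peptides["peptide_key"].to_numpy()
    prots = peptides["protein_id"].to_numpy()
    is_phos = peptides["is_phospho"].to_numpy()
    pep_pos = peptides["site_peptide_pos"].to_numpy()
    ev_pep = pep_i[ev_pair]

    site_positions = np.where(is_phos[ev_pep], pep_pos[ev_pep].astype(str), "")
    loc_strings = np.where(is_phos[ev_pep], np.char.mod("%.1f", loc), "")

    table = pd.DataFrame({
        "peptide_key": keys[ev_pep],
        "protein_id": prots[ev_pep],
        "charge": charges,
        "fraction_id": np.char.add("F", (fractions + 1).astype(str)),
        "replicate_id": rep_ids[rep_i][ev_pair],
        "heavy": heavy,
        "light": light,
        "site_positions": site_positions,
        "localization_scores": loc_strings,
    })
    truth = GroundTruth(peptides=peptides, proteome=edited, config=config)
    return table, truth


def simulate_dataset(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Convenience: proteome + quantification table in one call."""
    proteome = generate_proteome(config)
    return generate_quant_table(config, proteome)
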