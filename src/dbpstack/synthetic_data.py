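"""Labeled synthetic datasets: sequences, PSSM and secondary-structure profiles.

The generator emulates the three per-protein inputs the pipeline consumes,
with a tunable class signal so every stage is testable without running
PSI-BLAST or a secondary-structure predictor:

* sequences are drawn i.i.d. from the 20-letter alphabet, positives biased
  toward a fixed 5-residue subset by ``comp_effect``;
* PSSM scores are Gaussian noise (sd ``noise_sd``); for positives,
  ``pssm_effect`` is added to the 5 designated residue-type columns over
  the first half of the sequence only — a position-localized signal
  (think of an N-terminal binding region) that survives the per-column
  z-scoring applied by the evolutionary encoders, which a column-wide
  constant shift would not;
* secondary-structure rows come from a 3-state Markov chain whose
  helix-state stay-probability grows with ``ss_effect`` for positives.

With all effects zero the two classes are exchangeable in distribution.
Everything is fully determined by the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io_formats import (
    ALPHABET,
    PSSM_ALPHABET,
    PssmProfile,
    ProteinRecord,
    SsProfile,
)

#: Residue types carrying the planted PSSM/composition signal for positives.
PLANTED_RESIDUES: tuple[str, ...] = ("R", "K", "D", "E", "Q")

_STAY_BASE = 0.70  # baseline Markov stay-probability per SS state
_DOMINANT_WEIGHT = 0.80  # probability mass added to the current SS state


@dataclass(frozen=True)
class SyntheticConfig:
    n_pos: int = 100
    n_neg: int = 100
    length_range: tuple[int, int] = (50, 120)
    pssm_effect: float = 0.0
    ss_effect: float = 0.0
    comp_effect: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("sample counts must be non-negative")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError("length_range must satisfy 2 <= min <= max")
        if min(self.pssm_effect, self.ss_effect, self.comp_effect) < 0:
            raise ValueError("effects must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass(eq=False)
class SyntheticDataset:
    records: list[ProteinRecord]
    pssms: dict[str, PssmProfile]
    ss: dict[str, SsProfile]
    truth: SyntheticConfig


def _sample_sequence(rng: np.random.Generator, length: int, comp_bias: float) -> str:
    weights = np.ones(20)
    if comp_bias > 0:
        for res in PLANTED_RESIDUES:
            weights[ALPHABET.index(res)] *= 1.0 + comp_bias
    weights /= weights.sum()
    return "".join(rng.choice(list(ALPHABET), size=length, p=weights))


def _sample_pssm(
    rng: np.random.Generator, rid: str, length: int, cfg: SyntheticConfig, positive: bool
) -> PssmProfile:
    scores = rng.normal(0.0, cfg.noise_sd, size=(length, 20))
    if positive and cfg.pssm_effect > 0:
        cols = [PSSM_ALPHABET.index(res) for res in PLANTED_RESIDUES]
        scores[: length // 2, cols] += cfg.pssm_effect
    return PssmProfile(record_id=rid, scores=scores)


def _sample_ss(
    rng: np.random.Generator, rid: str, length: int, cfg: SyntheticConfig, positive: bool
) -> SsProfile:
    stay = np.full(3, _STAY_BASE)
    if positive:
        stay[0] = min(0.95, _STAY_BASE + cfg.ss_effect)  # helix persistence
    state = int(rng.integers(3))
    rows = np.empty((length, 3))
    for i in range(length):
        row = rng.uniform(0.02, 0.10, size=3)
        row[state] += _DOMINANT_WEIGHT
        rows[i] = row / row.sum()
        if rng.random() >= stay[state]:
            state = int((state + 1 + rng.integers(2)) % 3)
    return SsProfile(record_id=rid, probs=rows)


def generate(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate a labeled dataset fully determined by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    records: list[ProteinRecord] = []
    pssms: dict[str, PssmProfile] = {}
    ss: dict[str, SsProfile] = {}
    lo, hi = cfg.length_range
    plan = [("pos", 1, i) for i in range(cfg.n_pos)]
    plan += [("neg", 0, i) for i in range(cfg.n_neg)]
    for prefix, label, i in plan:
        rid = f"{prefix}{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        seq = _sample_sequence(rng, length, cfg.comp_effect if label else 0.0)
        records.append(ProteinRecord(id=rid, sequence=seq, label=label))
        pssms[rid] = _sample_pssm(rng, rid, length, cfg, bool(label))
        ss[rid] = _sample_ss(rng, rid, length, cfg, bool(label))
    return SyntheticDataset(records=records, pssms=pssms, ss=ss, truth=cfg)


def _write_pssm_file(profile: PssmProfile, path: Path) -> None:
    """Write the two-block PSI-BLAST ASCII dialect (log-odds to 2 decimals,
    zero percentage block, footer statistics line)."""
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            "
        + "  ".join(profile.column_order)
        + "   "
        + "  ".join(profile.column_order),
    ]
    for i, row in enumerate(profile.scores, start=1):
        residue = "A"  # placeholder; the sequence travels in the FASTA
        cells = " ".join(f"{v:7.2f}" for v in row)
        pct = " ".join("0" for _ in range(20))
        lines.append(f"{i:5d} {residue}  {cells}   {pct}  0.00 0.00")
    lines += [
        "",
        "                      K         Lambda",
        "Standard Ungapped    0.1347     0.3190",
        "",
    ]
    path.write_text("\n".join(lines), encoding="utf-8")


def _write_ss2_file(profile: SsProfile, sequence: str, path: Path) -> None:
    lines = ["# PSIPRED VFORMAT (synthetic profile)", ""]
    state_letters = ("H", "E", "C")
    for i, (h, e, c) in enumerate(profile.probs):
        state = state_letters[int(np.argmax((h, e, c)))]
        residue = sequence[i]
        # file column order is (coil, helix, strand)
        lines.append(f"{i + 1:4d} {residue} {state}  {c:6.3f} {h:6.3f} {e:6.3f}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_fixture_tree(ds: SyntheticDataset, directory) -> None:
    """Emit ``dataset.fasta``, ``pssm/<id>.pssm``, ``ss2/<id>.ss2`` and
    ``labels.tsv`` in the exact dialects the readers accept."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta_lines: list[str] = []
    label_lines: list[str] = []
    if ds.records:
        (directory / "pssm").mkdir(exist_ok=True)
        (directory / "ss2").mkdir(exist_ok=True)
    for rec in ds.records:
        fasta_lines.append(f">{rec.id}")
        fasta_lines.extend(
            rec.sequence[i : i + 60] for i in range(0, len(rec.sequence), 60)
        )
        if rec.label is not None:
            label_lines.append(f"{rec.id}\t{rec.label}")
        _write_pssm_file(ds.pssms[rec.id], directory / "pssm" / f"{rec.id}.pssm")
        _write_ss2_file(
            ds.ss[rec.id], rec.sequence, directory / "ss2" / f"{rec.id}.ss2"
        )
    (directory / "dataset.fasta").write_text(
        ("\n".join(fasta_lines) + "\n") if fasta_lines else "", encoding="utf-8"
    )
    if label_lines:
        (directory / "labels.tsv").write_text(
            "\n".join(label_lines) + "\n", encoding="utf-8"
        )
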