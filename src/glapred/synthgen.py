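"""Synthetic benchmark generator for Gla-site prediction.

Emulates the statistical shape of the benchmark set — about 560 positive and
600 negative 41-residue glutamate-centred windows — without any downloads.
Positive windows carry a tunable positional motif: at each designated flank
position the motif residue appears with probability ``motif_strength``,
otherwise a background residue is drawn. Negative windows are pure background.

Every emitted protein hosts exactly one planted site, flanked by 25 residues
of random padding, so no window needs terminal padding. The background
distribution assigns zero mass to glutamate, so every E in the output is a
planted site centre and window counts match the configured class sizes
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import AMINO_ACIDS, DEFAULT_FLANK, AnnotatedProtein

#: Window positions (1-based, centre = 21) and residues of the default motif:
#: tandem conserved aromatic residues flanking the modified glutamate. Rare,
#: high-code residues (W, Y) give the motif a clear signature in both the
#: window-matrix moments and the PRIM offset accumulators, which is the point
#: of the benchmark: at full strength the moment pipeline must recover it.
DEFAULT_MOTIF: tuple[tuple[int, str], ...] = (
    (17, "W"), (18, "W"), (19, "Y"), (23, "Y"), (24, "W"), (25, "W"),
)

_PAD_LENGTH = 25


def _default_background() -> np.ndarray:
    bg = np.ones(len(AMINO_ACIDS))
    bg[AMINO_ACIDS.index("E")] = 0.0
    return bg / bg.sum()


@dataclass
class SynthConfig:
    """Generator settings; defaults mirror the benchmark's class sizes."""

    n_positive: int = 560
    n_negative: int = 600
    motif_strength: float = 0.8
    motif_positions: tuple[tuple[int, str], ...] = DEFAULT_MOTIF
    background: np.ndarray = field(default_factory=_default_background)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("class counts must be non-negative")
        if not 0.0 <= self.motif_strength <= 1.0:
            raise ValueError("motif_strength must lie in [0, 1]")
        center = DEFAULT_FLANK + 1
        for pos, residue in self.motif_positions:
            if pos == center:
                raise ValueError(f"motif position {pos} is the centre (always 'E')")
            if not 1 <= pos <= 2 * DEFAULT_FLANK + 1:
                raise ValueError(f"motif position {pos} outside the 41-mer window")
            if residue not in AMINO_ACIDS:
                raise ValueError(f"motif residue {residue!r} not a standard amino acid")
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (len(AMINO_ACIDS),):
            raise ValueError("background must have one weight per residue")
        if self.background.min() < 0 or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be a probability vector")


def _draw_residues(rng: np.random.Generator, background: np.ndarray, size: int) -> list[str]:
    codes = rng.choice(len(AMINO_ACIDS), size=size, p=background)
    return [AMINO_ACIDS[c] for c in codes]


def _make_window(rng: np.random.Generator, config: SynthConfig, positive: bool) -> str:
    length = 2 * DEFAULT_FLANK + 1
    residues = _draw_residues(rng, config.background, length)
    residues[DEFAULT_FLANK] = "E"
    if positive:
        for pos, residue in config.motif_positions:
            if rng.random() < config.motif_strength:
                residues[pos - 1] = residue
    return "".join(residues)


def generate(config: SynthConfig | None = None) -> tuple[list[AnnotatedProtein], pd.DataFrame]:
    """Generate annotated proteins plus the matching site-annotation table.

    One protein per sample: 25 residues of background padding, the 41-mer
    window, 25 more padding residues; the planted site sits at position 46.
    The table has the ``protein_id / position / label`` TSV dialect, one row
    per planted site (positives labelled 1, negatives 0). Deterministic for a
    fixed seed.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    site_position = _PAD_LENGTH + DEFAULT_FLANK + 1

    proteins: list[AnnotatedProtein] = []
    rows = []
    labels = [1] * config.n_positive + [0] * config.n_negative
    for idx, label in enumerate(labels):
        window = _make_window(rng, config, positive=bool(label))
        pad_left = "".join(_draw_residues(rng, config.background, _PAD_LENGTH))
        pad_right = "".join(_draw_residues(rng, config.background, _PAD_LENGTH))
        pid = f"SYNP{idx + 1:04d}"
        sequence = pad_left + window + pad_right
        proteins.append(
            AnnotatedProtein(
                id=pid,
                sequence=sequence,
                positive_sites={site_position} if label else set(),
            )
        )
        rows.append({"protein_id": pid, "position": site_position, "label": label})
    return proteins, pd.DataFrame(rows)


def write_fasta(proteins: list[AnnotatedProtein], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n{p.sequence}\n")


def write_annotations(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
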