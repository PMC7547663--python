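"""Sequence input/output and peptide-window extraction.

Candidate 4-carboxyglutamate (Gla) sites are glutamate (E) residues. Each
candidate is represented by a fixed-length 41-mer peptide window: 20 residues
upstream, the glutamate itself at (1-based) position 21, and 20 residues
downstream. Windows that would run past a protein terminus are padded with the
symbol ``X`` so that every window has exactly 41 residues.

Coordinates are 1-based throughout the annotation interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical 20-letter amino-acid alphabet, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Pad symbol for window positions beyond a protein terminus.
PAD = "X"
#: Default number of flanking residues on each side of the candidate site.
DEFAULT_FLANK = 20
#: Window length under the default flank.
WINDOW_LENGTH = 2 * DEFAULT_FLANK + 1
#: 1-based index of the candidate glutamate within the window.
CENTER_INDEX = DEFAULT_FLANK + 1

_AA_SET = frozenset(AMINO_ACIDS)


@dataclass
class AnnotatedProtein:
    """A protein sequence with labelled carboxylation sites.

    ``positive_sites`` holds 1-based positions of glutamate residues that carry
    the 4-carboxyglutamate modification; every other E in the sequence is a
    negative candidate.
    """

    id: str
    sequence: str
    positive_sites: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        for pos in self.positive_sites:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"site {pos} out of range for protein {self.id!r} "
                    f"(length {len(self.sequence)})"
                )
            if self.sequence[pos - 1] != "E":
                raise ValueError(
                    f"site {pos} of protein {self.id!r} is "
                    f"{self.sequence[pos - 1]!r}, expected 'E'"
                )


@dataclass(frozen=True)
class PeptideWindow:
    """Fixed-length peptide window centred on a candidate glutamate."""

    residues: str
    label: int
    source_id: str
    center_position: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        bad = set(self.residues) - _AA_SET - {PAD}
        if bad:
            raise ValueError(f"unexpected residue symbols {sorted(bad)}")

    @property
    def center_residue(self) -> str:
        return self.residues[len(self.residues) // 2]


def _clean_sequence(raw: str, record_id: str) -> str:
    seq = str(raw).upper()
    cleaned = []
    for i, ch in enumerate(seq):
        if ch in _AA_SET:
            cleaned.append(ch)
        else:
            logger.warning(
                "protein %s: residue %r at position %d is not a standard "
                "amino acid; replaced with %r",
                record_id, ch, i + 1, PAD,
            )
            cleaned.append(PAD)
    return "".join(cleaned)


def read_fasta(path: str | Path) -> list[AnnotatedProtein]:
    """Read a FASTA file into :class:`AnnotatedProtein` records (no sites).

    Sequences are upper-cased; characters outside the 20-letter alphabet are
    replaced with ``X`` (with a logged warning). Records with an empty
    sequence are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    proteins: list[AnnotatedProtein] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = _clean_sequence(str(record.seq), record.id)
        if not seq:
            logger.warning("protein %s has an empty sequence; skipped", record.id)
            continue
        proteins.append(AnnotatedProtein(id=record.id, sequence=seq))
    if not proteins:
        logger.warning("no sequence records read from %s", path)
    return proteins


def read_site_annotations(
    path: str | Path, proteins: list[AnnotatedProtein]
) -> list[AnnotatedProtein]:
    """Attach positive-site annotations from a TSV table.

    The table must have columns ``protein_id``, ``position`` (1-based) and
    ``label`` (0 or 1). Rows with label 1 populate ``positive_sites``. Rows
    naming unknown proteins, or positions whose residue is not E, are rejected
    with a logged reason. A position outside the protein raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    except Exception as exc:  # malformed TSV
        raise ValueError(f"cannot parse annotation table {path}: {exc}") from exc
    required = {"protein_id", "position", "label"}
    if not required.issubset(table.columns):
        raise ValueError(
            f"annotation table {path} must have columns {sorted(required)}, "
            f"found {list(table.columns)}"
        )

    by_id = {p.id: p for p in proteins}
    sites: dict[str, set[int]] = {p.id: set() for p in proteins}
    for row in table.itertuples():
        line_no = row.Index + 2  # 1-based, counting the header line
        try:
            pid = str(row.protein_id)
            pos = int(row.position)
            label = int(row.label)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{line_no}: malformed row: {exc}") from exc
        if label not in (0, 1):
            raise ValueError(f"{path}:{line_no}: label must be 0 or 1, got {label}")
        if pid not in by_id:
            logger.warning("%s:%d: unknown protein %r; row rejected", path, line_no, pid)
            continue
        protein = by_id[pid]
        if not 1 <= pos <= len(protein.sequence):
            raise ValueError(
                f"{path}:{line_no}: position {pos} out of range for protein "
                f"{pid!r} (length {len(protein.sequence)})"
            )
        if protein.sequence[pos - 1] != "E":
            logger.warning(
                "%s:%d: position %d of protein %s is %r, not 'E'; row rejected",
                path, line_no, pos, pid, protein.sequence[pos - 1],
            )
            continue
        if label == 1:
            sites[pid].add(pos)
    return [
        AnnotatedProtein(id=p.id, sequence=p.sequence, positive_sites=sites[p.id])
        for p in proteins
    ]


def extract_windows(protein: AnnotatedProtein, flank: int = DEFAULT_FLANK) -> list[PeptideWindow]:
    """Extract one peptide window per glutamate residue.

    Every E in the sequence yields a window of ``2*flank + 1`` residues with
    the E at the centre; positions beyond a terminus are padded with ``X``.
    The window is labelled positive iff its centre is in ``positive_sites``.
    Windows are returned in ascending centre position.
    """
    if flank < 1:
        raise ValueError(f"flank must be >= 1, got {flank}")
    seq = protein.sequence
    windows: list[PeptideWindow] = []
    for pos0, residue in enumerate(seq):
        if residue != "E":
            continue
        lo, hi = pos0 - flank, pos0 + flank + 1
        core = seq[max(lo, 0): hi]
        left_pad = PAD * max(-lo, 0)
        right_pad = PAD * max(hi - len(seq), 0)
        windows.append(
            PeptideWindow(
                residues=left_pad + core + right_pad,
                label=int(pos0 + 1 in protein.positive_sites),
                source_id=protein.id,
                center_position=pos0 + 1,
            )
        )
    return windows


def extract_all_windows(
    proteins: list[AnnotatedProtein], flank: int = DEFAULT_FLANK
) -> list[PeptideWindow]:
    """Extract windows for every protein, concatenated in input order."""
    out: list[PeptideWindow] = []
    for protein in proteins:
        out.extend(extract_windows(protein, flank=flank))
    return out


def position_frequency_matrix(windows: list[PeptideWindow]) -> np.ndarray:
    """Per-position residue frequencies over a set of equal-length windows.

    Returns a ``20 x L`` array whose rows follow :data:`AMINO_ACIDS` order.
    Pad symbols are excluded from each column's denominator, so each column
    with at least one real residue sums to 1. This is the numeric matrix
    behind a sequence logo.
    """
    if not windows:
        raise ValueError("cannot build a frequency matrix from an empty window list")
    length = len(windows[0].residues)
    if any(len(w.residues) != length for w in windows):
        raise ValueError("all windows must have the same length")
    counts = np.zeros((len(AMINO_ACIDS), length), dtype=float)
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for w in windows:
        for col, ch in enumerate(w.residues):
            if ch != PAD:
                counts[index[ch], col] += 1.0
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, 0.0)
    return freqs


def write_windows_tsv(windows: list[PeptideWindow], path: str | Path) -> None:
    """Write windows as TSV: source_id, center_position, residues, label."""
    frame = pd.DataFrame(
        {
            "source_id": [w.source_id for w in windows],
            "center_position": [w.center_position for w in windows],
            "residues": [w.residues for w in windows],
            "label": [w.label for w in windows],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_windows_tsv(path: str | Path) -> list[PeptideWindow]:
    frame = pd.read_csv(path, sep="\t", dtype={"source_id": str})
    return [
        PeptideWindow(
            residues=row.residues,
            label=int(row.label),
            source_id=row.source_id,
            center_position=int(row.center_position),
        )
        for row in frame.itertuples()
    ]


def write_windows_fasta(windows: list[PeptideWindow], path: str | Path) -> None:
    """Write windows as FASTA with headers ``>source_id|center_position|label``."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.source_id}|{w.center_position}|{w.label}\n{w.residues}\n")
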