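"""Sequence/site input, K-centered window extraction and train/test splitting.

All residue coordinates are 1-based inclusive. Site annotation tables are
TSV with a header line: ``protein_id<TAB>position<TAB>label``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .residues import ALPHABET22_INDEX

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 16  # 2*16+1 = 33-residue windows


@dataclass(frozen=True)
class ProteinRecord:
    """A full-length protein sequence over the 22-letter alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = {c for c in self.sequence if c not in ALPHABET22_INDEX}
        if bad:
            raise ValueError(f"protein {self.id!r}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteAnnotation:
    """A candidate modification site: protein, 1-based lysine position, label."""

    protein_id: str
    position: int
    label: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-length peptide centered on a candidate site.

    The sequence has odd length 2*flank+1 with the candidate lysine at the
    center; positions falling outside the protein are padded with 'X'.
    """

    protein_id: str
    center_position: int
    sequence: str
    label: int

    def __post_init__(self) -> None:
        if len(self.sequence) % 2 != 1:
            raise ValueError("window length must be odd")
        bad = {c for c in self.sequence if c not in ALPHABET22_INDEX}
        if bad:
            raise ValueError(f"window contains invalid residues {sorted(bad)}")

    @property
    def flank(self) -> int:
        return len(self.sequence) // 2

    @property
    def center_residue(self) -> str:
        return self.sequence[self.flank]


@dataclass
class DatasetSplit:
    """A train/test partition of peptide windows."""

    train: list[PeptideWindow]
    test: list[PeptideWindow]
    seed: int = 0


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are upper-cased; characters outside the 22-letter alphabet are
    mapped to 'X' with a logged warning. Duplicate record ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        cleaned = "".join(c if c in ALPHABET22_INDEX else "X" for c in seq)
        if cleaned != seq:
            bad = sorted({c for c in seq if c not in ALPHABET22_INDEX})
            logger.warning("protein %s: mapped %s to 'X'", rec.id, bad)
        records.append(ProteinRecord(rec.id, cleaned))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_sites(path: str | Path) -> list[SiteAnnotation]:
    """Read a site annotation TSV (header: protein_id, position, label)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "position", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"site table must have columns {sorted(required)}")
    return [
        SiteAnnotation(str(r.protein_id), int(r.position), int(r.label))
        for r in df.itertuples()
    ]


def write_sites(sites: Iterable[SiteAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(s.protein_id, s.position, s.label) for s in sites],
        columns=["protein_id", "position", "label"],
    ).to_csv(path, sep="\t", index=False)


def extract_window(
    protein: ProteinRecord,
    position: int,
    flank: int = DEFAULT_FLANK,
    label: int = 0,
    force: bool = False,
) -> PeptideWindow:
    """Cut the 2*flank+1 window centered at ``position`` (1-based).

    Out-of-protein positions are filled with the placeholder 'X'. The center
    residue must be 'K' unless ``force`` is given (annotated sites are
    K-centered by definition; ``force`` exists for stress testing).
    """
    if not 1 <= position <= len(protein):
        raise ValueError(
            f"position {position} outside protein {protein.id!r} (length {len(protein)})"
        )
    center = protein.sequence[position - 1]
    if center != "K" and not force:
        raise ValueError(
            f"residue at {protein.id}:{position} is {center!r}, expected 'K'"
        )
    lo = position - 1 - flank
    hi = position + flank  # exclusive, 0-based
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(protein))
    core = protein.sequence[max(0, lo) : min(len(protein), hi)]
    seq = "X" * left_pad + core + "X" * right_pad
    return PeptideWindow(protein.id, position, seq, label)


def extract_windows(
    proteins: Sequence[ProteinRecord],
    sites: Sequence[SiteAnnotation],
    flank: int = DEFAULT_FLANK,
    force: bool = False,
) -> list[PeptideWindow]:
    """Extract one window per annotation, preserving annotation order."""
    by_id = {p.id: p for p in proteins}
    windows = []
    for s in sites:
        if s.protein_id not in by_id:
            raise KeyError(f"annotation references unknown protein {s.protein_id!r}")
        windows.append(
            extract_window(by_id[s.protein_id], s.position, flank, s.label, force)
        )
    return windows


def enumerate_negative_sites(
    protein: ProteinRecord, positive_positions: Iterable[int]
) -> list[SiteAnnotation]:
    """All K residues of ``protein`` not in ``positive_positions``, labelled 0."""
    positives = set(positive_positions)
    return [
        SiteAnnotation(protein.id, i + 1, 0)
        for i, c in enumerate(protein.sequence)
        if c == "K" and (i + 1) not in positives
    ]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(
    windows: Sequence[PeptideWindow],
    test_fraction: float = 0.25,
    stratified: bool = True,
    seed: int = 0,
) -> DatasetSplit:
    """Stratified train/test split of peptide windows.

    Per-class test counts are round(class_count * test_fraction); if their
    sum disagrees with round(total * test_fraction) the larger class donates
    or absorbs the difference. Deterministic given ``seed``.
    """
    if not windows:
        raise ValueError("empty window list")
    if not 0 <= test_fraction < 1:
        raise ValueError(f"test_fraction must be in [0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    labels = np.array([w.label for w in windows])
    total_target = _round_half_up(len(windows) * test_fraction)

    if not stratified:
        order = rng.permutation(len(windows))
        test_idx = set(order[:total_target].tolist())
        return DatasetSplit(
            train=[w for i, w in enumerate(windows) if i not in test_idx],
            test=[w for i, w in enumerate(windows) if i in test_idx],
            seed=seed,
        )

    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("stratified split requires both classes present")
    counts = {c: int((labels == c).sum()) for c in classes}
    n_test = {c: _round_half_up(counts[c] * test_fraction) for c in classes}
    # repair rounding drift against the overall target, one sample at a time,
    # always adjusting the largest class (which has the most room)
    while sum(n_test.values()) != total_target:
        largest = max(classes, key=lambda c: (counts[c], c))
        n_test[largest] += 1 if sum(n_test.values()) < total_target else -1

    test_idx: set[int] = set()
    for c in classes:
        members = np.flatnonzero(labels == c)
        order = rng.permutation(len(members))
        test_idx.update(members[order[: n_test[c]]].tolist())
    return DatasetSplit(
        train=[w for i, w in enumerate(windows) if i not in test_idx],
        test=[w for i, w in enumerate(windows) if i in test_idx],
        seed=seed,
    )


def write_windows(windows: Iterable[PeptideWindow], path: str | Path) -> None:
    """Persist windows as TSV: protein_id, center_position, sequence, label."""
    pd.DataFrame(
        [(w.protein_id, w.center_position, w.sequence, w.label) for w in windows],
        columns=["protein_id", "center_position", "sequence", "label"],
    ).to_csv(path, sep="\t", index=False)


def read_windows(path: str | Path) -> list[PeptideWindow]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "sequence": str})
    return [
        PeptideWindow(str(r.protein_id), int(r.center_position), str(r.sequence), int(r.label))
        for r in df.itertuples()
    ]
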