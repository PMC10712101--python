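"""Feature encoders: seven fixed-width blocks over 33-residue peptide windows.

Block dimensional contracts for a window of length 33:

====== ===== =========================================================
block  width definition
====== ===== =========================================================
BE       726 33 one-hot vectors over the 22-letter alphabet
EAAC     580 (33-5+1) sliding windows x 20 standard-residue frequencies
CKSAAP   484 frequencies of the 484 ordered residue pairs at gap k=0
CTDC      39 13 physicochemical properties x 3 group fractions
BLOSUM62 660 33 substitution-score rows of 20 entries ('U'/'X' -> zeros)
STRUCT    66 33 secondary-structure letters through a 2-bit codebook
PSSM     660 33 rows of the protein's L x 20 evolutionary profile
====== ===== =========================================================

Assembled width with all seven blocks: 3215 columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import PeptideWindow, ProteinRecord
from .residues import (
    ALPHABET22,
    ALPHABET22_INDEX,
    SS_ALPHABET,
    SS_CODEBOOK,
    STANDARD20,
    STANDARD20_INDEX,
    blosum62_rows,
    ctd_group_index,
    ctd_groups,
)

logger = logging.getLogger(__name__)

BLOCK_ORDER = ("BE", "EAAC", "CKSAAP", "CTDC", "BLOSUM62", "STRUCT", "PSSM")

PSSM_VALUE_RANGE = (-15, 13)  # typical PSI-BLAST log-odds range


@dataclass
class FeatureBlock:
    """One named, row-aligned column block of the feature matrix."""

    name: str
    column_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("block values must be 2-D")
        if self.values.shape[1] != len(self.column_labels):
            raise ValueError(
                f"block {self.name}: {self.values.shape[1]} columns vs "
                f"{len(self.column_labels)} labels"
            )
        if not np.isfinite(self.values).all():
            raise ValueError(f"block {self.name}: non-finite values")


@dataclass
class FeatureMatrix:
    """Ordered feature blocks over a row-aligned set of peptide windows."""

    blocks: list[FeatureBlock]
    row_keys: list[tuple[str, int]]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.row_keys)
        for b in self.blocks:
            if b.values.shape[0] != n:
                raise ValueError(f"block {b.name}: {b.values.shape[0]} rows, expected {n}")
        if self.labels.shape != (n,):
            raise ValueError("labels length mismatch")

    @property
    def values(self) -> np.ndarray:
        return np.hstack([b.values for b in self.blocks])

    @property
    def column_labels(self) -> list[str]:
        return [f"{b.name}:{c}" for b in self.blocks for c in b.column_labels]

    @property
    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.column_labels)
        df.insert(0, "protein_id", [k[0] for k in self.row_keys])
        df.insert(1, "position", [k[1] for k in self.row_keys])
        df.insert(2, "label", self.labels)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        row_keys = list(zip(df["protein_id"].astype(str), df["position"].astype(int)))
        labels = df["label"].to_numpy(dtype=int)
        feat = df.drop(columns=["protein_id", "position", "label"])
        blocks: list[FeatureBlock] = []
        for name in BLOCK_ORDER:
            cols = [c for c in feat.columns if c.startswith(name + ":")]
            if cols:
                blocks.append(
                    FeatureBlock(
                        name,
                        [c.split(":", 1)[1] for c in cols],
                        feat[cols].to_numpy(dtype=float),
                    )
                )
        return cls(blocks, row_keys, labels)


def _check_window(window: str | PeptideWindow) -> str:
    seq = window.sequence if isinstance(window, PeptideWindow) else window
    bad = {c for c in seq if c not in ALPHABET22_INDEX}
    if bad:
        raise ValueError(f"invalid residues in window: {sorted(bad)}")
    return seq


def encode_be(window: str | PeptideWindow) -> np.ndarray:
    """Binary (one-hot) encoding: 22 bits per residue, 726 for length 33."""
    seq = _check_window(window)
    out = np.zeros(len(seq) * 22)
    for i, c in enumerate(seq):
        out[i * 22 + ALPHABET22_INDEX[c]] = 1.0
    return out


def be_labels(length: int = 33) -> list[str]:
    return [f"p{i + 1}.{aa}" for i in range(length) for aa in ALPHABET22]


def encode_eaac(window: str | PeptideWindow, win_size: int = 5) -> np.ndarray:
    """Enhanced amino-acid composition over sliding windows.

    For each of the L-w+1 windows of width ``win_size``, the frequency
    f(t, win) = N(t, win) / win_size of each of the 20 standard residues.
    'U' and 'X' never count toward a numerator, so window columns need not
    sum to 1 on padded peptides.
    """
    seq = _check_window(window)
    if not 1 <= win_size <= len(seq):
        raise ValueError(f"win_size must be in [1, {len(seq)}], got {win_size}")
    n_windows = len(seq) - win_size + 1
    out = np.zeros((n_windows, 20))
    for w in range(n_windows):
        for c in seq[w : w + win_size]:
            j = STANDARD20_INDEX.get(c)
            if j is not None:
                out[w, j] += 1.0
    return (out / win_size).ravel()


def eaac_labels(length: int = 33, win_size: int = 5) -> list[str]:
    return [
        f"win{w + 1}.{aa}" for w in range(length - win_size + 1) for aa in STANDARD20
    ]


def encode_cksaap(window: str | PeptideWindow, k: int = 0) -> np.ndarray:
    """Composition of k-spaced amino-acid pairs over the 22-letter alphabet.

    Counts the 484 ordered residue pairs separated by exactly k residues,
    normalized by N_total = L - k - 1 so the vector sums to 1.
    """
    seq = _check_window(window)
    if not 0 <= k <= len(seq) - 2:
        raise ValueError(f"k must be in [0, {len(seq) - 2}], got {k}")
    counts = np.zeros(484)
    for i in range(len(seq) - k - 1):
        a = ALPHABET22_INDEX[seq[i]]
        b = ALPHABET22_INDEX[seq[i + k + 1]]
        counts[a * 22 + b] += 1.0
    return counts / (len(seq) - k - 1)


def cksaap_labels(k: int = 0) -> list[str]:
    return [f"{a}{b}.gap{k}" for a in ALPHABET22 for b in ALPHABET22]


def encode_ctdc(window: str | PeptideWindow) -> np.ndarray:
    """CTD composition: per property, the fraction of residues in each group.

    N counts only the 20 standard residues; a window with none raises.
    """
    seq = _check_window(window)
    standard = [c for c in seq if c in STANDARD20_INDEX]
    if not standard:
        raise ValueError("window contains no standard residues")
    index = ctd_group_index()
    out = np.zeros(len(index) * 3)
    for p, (prop, lookup) in enumerate(index.items()):
        for c in standard:
            out[p * 3 + lookup[c]] += 1.0
    return out / len(standard)


def ctdc_labels() -> list[str]:
    return [f"{prop}.g{g + 1}" for prop in ctd_groups() for g in range(3)]


def encode_blosum62(window: str | PeptideWindow) -> np.ndarray:
    """Per-residue BLOSUM62 score rows; 'U'/'X' rows are all-zero."""
    seq = _check_window(window)
    table = blosum62_rows()
    return np.concatenate([table[ALPHABET22_INDEX[c]] for c in seq])


def blosum62_labels(length: int = 33) -> list[str]:
    return [f"p{i + 1}.{aa}" for i in range(length) for aa in STANDARD20]


@dataclass(frozen=True)
class SecondaryStructureAnnotation:
    """Per-protein secondary-structure string over {C, H, E, X}.

    'O' in input files is accepted as a variant spelling of strand and
    normalized to 'E'.
    """

    protein_id: str
    ss_string: str

    def __post_init__(self) -> None:
        normalized = self.ss_string.upper().replace("O", "E")
        object.__setattr__(self, "ss_string", normalized)
        bad = {c for c in normalized if c not in SS_ALPHABET}
        if bad:
            raise ValueError(f"invalid secondary-structure letters: {sorted(bad)}")


def read_ss(path: str | Path) -> dict[str, SecondaryStructureAnnotation]:
    """Read secondary structure TSV (protein_id<TAB>ss_string, with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        str(r.protein_id): SecondaryStructureAnnotation(str(r.protein_id), str(r.ss_string))
        for r in df.itertuples()
    }


def write_ss(ss: Mapping[str, SecondaryStructureAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(a.protein_id, a.ss_string) for a in ss.values()],
        columns=["protein_id", "ss_string"],
    ).to_csv(path, sep="\t", index=False)


def encode_structure(
    ss_annotation: SecondaryStructureAnnotation, position: int, flank: int = 16
) -> np.ndarray:
    """2-bit encoding of the secondary-structure window around ``position``.

    Codebook: C -> 00, H -> 01, E -> 10, X -> 11; out-of-protein positions
    are padded with 'X'. Length 2*(2*flank+1) = 66 for flank 16.
    """
    ss = ss_annotation.ss_string
    if not 1 <= position <= len(ss):
        raise ValueError(f"position {position} outside structure string (length {len(ss)})")
    lo, hi = position - 1 - flank, position + flank
    chars = [
        ss[i] if 0 <= i < len(ss) else "X" for i in range(lo, hi)
    ]
    return np.array([bit for c in chars for bit in SS_CODEBOOK[c]], dtype=float)


def struct_labels(length: int = 33) -> list[str]:
    return [f"p{i + 1}.b{b}" for i in range(length) for b in range(2)]


@dataclass
class PssmProfile:
    """An L x 20 position-specific scoring matrix for one protein.

    ``residue_order`` records the 20-letter column order of the source file
    (PSI-BLAST's, not this package's alphabet); no silent reordering is done.
    """

    protein_id: str
    matrix: np.ndarray
    residue_order: str
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError("PSSM must be L x 20")
        if len(set(self.residue_order)) != 20:
            raise ValueError("residue_order must contain 20 distinct letters")
        if self.sequence is not None and len(self.sequence) != self.matrix.shape[0]:
            raise ValueError("PSSM row count disagrees with its sequence length")


#: Column order PSI-BLAST prints in ASCII PSSM output.
PSIBLAST_RESIDUE_ORDER = "ARNDCQEGHILKMFPSTWYV"

def parse_pssm(path: str | Path, protein_id: str | None = None) -> PssmProfile:
    """Parse a PSI-BLAST ASCII PSSM file (``-out_ascii_pssm`` dialect).

    Of each residue row's 40+ numeric columns, only the first 20 (log-odds
    scores) are kept; the weighted-percentage and information columns are
    ignored. Values outside the typical [-15, 13] range are accepted with a
    warning.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    residue_order: str | None = None
    rows: list[list[int]] = []
    sequence: list[str] = []
    last_index = 0
    for line in path.read_text().splitlines():
        parts = line.split()
        is_row = len(parts) >= 3 and parts[0].isdigit() and len(parts[1]) == 1 and parts[1].isalpha()
        if is_row:
            idx = int(parts[0])
            try:
                values = [int(v) for v in parts[2:22]]
            except ValueError as exc:
                raise ValueError(f"{path}: malformed PSSM row {idx}: {exc}") from exc
            if len(values) < 20:
                raise ValueError(f"{path}: malformed PSSM row {idx}: fewer than 20 scores")
            if idx != last_index + 1:
                raise ValueError(f"{path}: non-consecutive PSSM row index {idx}")
            last_index = idx
            rows.append(values)
            sequence.append(parts[1].upper())
        elif residue_order is None:
            letters = parts
            if len(letters) >= 20 and all(len(t) == 1 and t.isalpha() for t in letters):
                residue_order = "".join(letters[:20])
    if not rows:
        raise ValueError(f"{path}: no PSSM rows found")
    matrix = np.array(rows, dtype=float)
    lo, hi = PSSM_VALUE_RANGE
    if matrix.min() < lo or matrix.max() > hi:
        logger.warning("%s: PSSM values outside [%d, %d]", path, lo, hi)
    return PssmProfile(
        protein_id,
        matrix,
        residue_order or PSIBLAST_RESIDUE_ORDER,
        "".join(sequence),
    )


def write_pssm(profile: PssmProfile, path: str | Path) -> None:
    """Write a profile back in the ASCII dialect :func:`parse_pssm` reads."""
    lines = [
        "",
        "Last position-specific scoring matrix computed",
        "            " + "   ".join(profile.residue_order),
    ]
    seq = profile.sequence or "X" * profile.matrix.shape[0]
    for i, row in enumerate(profile.matrix):
        scores = " ".join(f"{int(v):4d}" for v in row)
        lines.append(f"{i + 1:5d} {seq[i]} {scores}")
    Path(path).write_text("\n".join(lines) + "\n")


def encode_pssm_window(
    profile: PssmProfile, position: int, flank: int = 16
) -> np.ndarray:
    """Concatenate the PSSM rows of the window around ``position``.

    Rows outside the protein are zeros; output width (2*flank+1)*20 = 660.
    """
    n = profile.matrix.shape[0]
    if not 1 <= position <= n:
        raise ValueError(f"position {position} outside PSSM of {n} rows")
    out = np.zeros(((2 * flank + 1), 20))
    for j, i in enumerate(range(position - 1 - flank, position + flank)):
        if 0 <= i < n:
            out[j] = profile.matrix[i]
    return out.ravel()


def pssm_labels(residue_order: str = PSIBLAST_RESIDUE_ORDER, length: int = 33) -> list[str]:
    return [f"p{i + 1}.{aa}" for i in range(length) for aa in residue_order]


def read_pssm_dir(directory: str | Path) -> dict[str, PssmProfile]:
    """Read every ``<protein_id>.pssm`` file in a directory."""
    directory = Path(directory)
    return {p.stem: parse_pssm(p) for p in sorted(directory.glob("*.pssm"))}


def assemble(
    blocks: Sequence[FeatureBlock],
    row_keys: Sequence[tuple[str, int]],
    labels: Sequence[int] | np.ndarray,
) -> FeatureMatrix:
    """Assemble blocks into a FeatureMatrix in the fixed canonical order.

    Optional blocks (STRUCT, PSSM) may be absent; duplicates are an error.
    """
    names = [b.name for b in blocks]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate block names: {names}")
    unknown = set(names) - set(BLOCK_ORDER)
    if unknown:
        raise ValueError(f"unknown block names: {sorted(unknown)}")
    ordered = sorted(blocks, key=lambda b: BLOCK_ORDER.index(b.name))
    missing = [n for n in ("STRUCT", "PSSM") if n not in names]
    if missing:
        logger.info("assembling without optional blocks: %s", missing)
    return FeatureMatrix(list(ordered), list(row_keys), np.asarray(labels))


def encode_windows(
    windows: Sequence[PeptideWindow],
    pssms: Mapping[str, PssmProfile] | None = None,
    ss: Mapping[str, SecondaryStructureAnnotation] | None = None,
    eaac_win: int = 5,
    cksaap_k: int = 0,
) -> FeatureMatrix:
    """Encode windows into all available blocks (the end-to-end front door).

    STRUCT and PSSM blocks are included only when annotations are supplied
    for every window's protein.
    """
    if not windows:
        raise ValueError("no windows to encode")
    length = len(windows[0].sequence)
    flank = length // 2
    blocks = [
        FeatureBlock("BE", be_labels(length), np.stack([encode_be(w) for w in windows])),
        FeatureBlock(
            "EAAC",
            eaac_labels(length, eaac_win),
            np.stack([encode_eaac(w, eaac_win) for w in windows]),
        ),
        FeatureBlock(
            "CKSAAP",
            cksaap_labels(cksaap_k),
            np.stack([encode_cksaap(w, cksaap_k) for w in windows]),
        ),
        FeatureBlock("CTDC", ctdc_labels(), np.stack([encode_ctdc(w) for w in windows])),
        FeatureBlock(
            "BLOSUM62",
            blosum62_labels(length),
            np.stack([encode_blosum62(w) for w in windows]),
        ),
    ]
    if ss is not None:
        blocks.append(
            FeatureBlock(
                "STRUCT",
                struct_labels(length),
                np.stack(
                    [
                        encode_structure(ss[w.protein_id], w.center_position, flank)
                        for w in windows
                    ]
                ),
            )
        )
    if pssms is not None:
        order = next(iter(pssms.values())).residue_order if pssms else PSIBLAST_RESIDUE_ORDER
        blocks.append(
            FeatureBlock(
                "PSSM",
                pssm_labels(order, length),
                np.stack(
                    [
                        encode_pssm_window(pssms[w.protein_id], w.center_position, flank)
                        for w in windows
                    ]
                ),
            )
        )
    return assemble(
        blocks,
        [(w.protein_id, w.center_position) for w in windows],
        [w.label for w in windows],
    )


@dataclass
class ScalerParams:
    """Per-column min/max learned on training rows (min-max normalization)."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if self.minimum.shape != self.maximum.shape:
            raise ValueError("min/max shape mismatch")
        if np.any(self.maximum < self.minimum):
            raise ValueError("max < min in scaler parameters")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"minimum": self.minimum.tolist(), "maximum": self.maximum.tolist()})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalerParams":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["minimum"]), np.array(d["maximum"]))


def minmax_fit(train_matrix: np.ndarray) -> ScalerParams:
    """Learn per-column min/max on the training rows only."""
    X = np.asarray(train_matrix, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in training matrix")
    return ScalerParams(X.min(axis=0), X.max(axis=0))


def minmax_apply(matrix: np.ndarray, params: ScalerParams) -> np.ndarray:
    """Affine map into [0, 1] per the fitted range.

    Constant training columns map to 0; test values outside the training
    range are preserved (no clipping), so values may fall outside [0, 1].
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[1] != params.minimum.shape[0]:
        raise ValueError(
            f"matrix has {X.shape[1]} columns, scaler expects {params.minimum.shape[0]}"
        )
    span = params.maximum - params.minimum
    span = np.where(span == 0, 1.0, span)
    return (X - params.minimum) / span
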