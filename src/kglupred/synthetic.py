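"""Synthetic peptide datasets with planted positional motifs.

The generator emits what the real-data path consumes — proteins (FASTA),
K-centered site annotations (TSV), per-protein PSSM files and secondary
structure strings — with the statistical structure the pipeline assumes:
position-specific residue enrichment/depletion around positive sites, a
roughly 1:6 positive:negative imbalance, PSSM values in the PSI-BLAST
log-odds range, and sticky (run-forming) secondary-structure states.

Windows are embedded in host proteins with randomized flank context, and a
fraction of sites sit close to a protein terminus so the placeholder
padding paths are exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import ProteinRecord, SiteAnnotation, write_fasta, write_sites
from .encoders import (
    PSIBLAST_RESIDUE_ORDER,
    PSSM_VALUE_RANGE,
    PssmProfile,
    SecondaryStructureAnnotation,
    write_pssm,
    write_ss,
)
from .residues import STANDARD20, STANDARD20_INDEX

WINDOW_LENGTH = 33
CENTER = 17  # 1-based center position of the window (the lysine)

#: negatives per positive in the emulated corpus (4369/707)
DEFAULT_IMBALANCE = 6.18


@dataclass
class MotifSpec:
    """Positional residue biases distinguishing positive from negative sites.

    ``enriched`` entries (position, residue, boost) add probability mass to a
    residue at a window position before renormalization; ``depleted`` entries
    (position, residue, damp) multiply its mass by (1 - damp). Positions are
    1..33 excluding the invariant center 17.
    """

    background: np.ndarray | None = None
    enriched: list[tuple[int, str, float]] = field(default_factory=list)
    depleted: list[tuple[int, str, float]] = field(default_factory=list)
    imbalance_ratio: float = DEFAULT_IMBALANCE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background is None:
            self.background = np.full(20, 1 / 20)
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (20,) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be a 20-vector summing to 1")
        if np.any(self.background < 0):
            raise ValueError("background probabilities must be non-negative")
        for pos, res, value in self.enriched + self.depleted:
            if not 1 <= pos <= WINDOW_LENGTH or pos == CENTER:
                raise ValueError(f"motif position {pos} outside [1, 33] \\ {{17}}")
            if res not in STANDARD20_INDEX:
                raise ValueError(f"unknown residue {res!r}")
            if value < 0:
                raise ValueError("boost/damp must be non-negative")
        if any(d > 1 for _, _, d in self.depleted):
            raise ValueError("damp must be <= 1")
        if self.imbalance_ratio <= 0:
            raise ValueError("imbalance_ratio must be positive")

    def position_distributions(self) -> np.ndarray:
        """(33, 20) per-position residue distributions for POSITIVE windows."""
        dists = np.tile(self.background, (WINDOW_LENGTH, 1))
        for pos, res, boost in self.enriched:
            dists[pos - 1, STANDARD20_INDEX[res]] += boost
        for pos, res, damp in self.depleted:
            dists[pos - 1, STANDARD20_INDEX[res]] *= 1 - damp
        return dists / dists.sum(axis=1, keepdims=True)


def default_motif_spec(seed: int = 0) -> MotifSpec:
    """A strong, clearly separable motif around the central lysine.

    Lysine is enriched at several flank positions; leucine, aspartate and
    glutamate are enriched at scattered positions; phenylalanine,
    asparagine, proline and methionine are depleted downstream of the
    center. Effect sizes are deliberately large — this is a recoverable
    planted signal, not a claim about the effect sizes of real data.
    """
    k_positions = [2, 7, 8, 10, 22, 23, 24, 26, 33]
    enriched = [(p, "K", 0.60) for p in k_positions]
    enriched += [(12, "L", 0.40), (14, "L", 0.40), (5, "D", 0.40), (30, "D", 0.40),
                 (13, "E", 0.40), (29, "E", 0.40)]
    depleted = [(19, "F", 0.95), (21, "N", 0.95), (25, "P", 0.95), (28, "M", 0.95)]
    return MotifSpec(enriched=enriched, depleted=depleted, seed=seed)


def null_motif_spec(seed: int = 0) -> MotifSpec:
    """No positional signal: positives and negatives share one distribution."""
    return MotifSpec(seed=seed)


@dataclass
class SyntheticDataset:
    proteins: list[ProteinRecord]
    annotations: list[SiteAnnotation]
    pssms: dict[str, PssmProfile]
    ss: dict[str, SecondaryStructureAnnotation]


def _draw_window(rng: np.random.Generator, dists: np.ndarray) -> str:
    chars = [
        STANDARD20[rng.choice(20, p=dists[i])] if i != CENTER - 1 else "K"
        for i in range(WINDOW_LENGTH)
    ]
    return "".join(chars)


def _embed(
    rng: np.random.Generator, window: str, background: np.ndarray
) -> tuple[str, int]:
    """Place a window inside a host protein; returns (sequence, K position).

    With probability 0.15 per side the flank is truncated (the site sits
    near a terminus and extraction will pad with 'X'); otherwise extra
    background residues extend the protein beyond the window.
    """
    flank = WINDOW_LENGTH // 2

    def extra(n: int) -> str:
        return "".join(STANDARD20[j] for j in rng.choice(20, size=n, p=background))

    if rng.random() < 0.15:
        keep_left = int(rng.integers(0, flank))
        left = window[flank - keep_left : flank]
        prefix = ""
    else:
        left = window[:flank]
        prefix = extra(int(rng.integers(0, 26)))
    if rng.random() < 0.15:
        keep_right = int(rng.integers(0, flank))
        right = window[flank + 1 : flank + 1 + keep_right]
        suffix = ""
    else:
        right = window[flank + 1 :]
        suffix = extra(int(rng.integers(0, 26)))
    sequence = prefix + left + "K" + right + suffix
    return sequence, len(prefix) + len(left) + 1


def generate_pssm(
    protein: ProteinRecord, signal_strength: float = 6.0, seed: int = 0
) -> PssmProfile:
    """Integer L x 20 profile in [-15, 13], biased toward each row's residue.

    ``signal_strength`` is added to the column of the row's own residue on
    top of uniform integer noise; 0 gives pure noise.
    """
    rng = np.random.default_rng(seed)
    L = len(protein)
    matrix = rng.integers(-5, 6, size=(L, 20)).astype(float)
    for i, c in enumerate(protein.sequence):
        j = PSIBLAST_RESIDUE_ORDER.find(c)
        if j >= 0:
            matrix[i, j] += round(signal_strength)
    matrix = np.clip(matrix, *PSSM_VALUE_RANGE)
    return PssmProfile(protein.id, matrix, PSIBLAST_RESIDUE_ORDER, protein.sequence)


def generate_ss(
    protein: ProteinRecord, seed: int = 0, stickiness: float = 0.8
) -> SecondaryStructureAnnotation:
    """Markov secondary-structure string over {C, H, E} with sticky states."""
    rng = np.random.default_rng(seed)
    states = "CHE"
    chars = [states[int(rng.integers(0, 3))]]
    for _ in range(len(protein) - 1):
        if rng.random() < stickiness:
            chars.append(chars[-1])
        else:
            others = [s for s in states if s != chars[-1]]
            chars.append(others[int(rng.integers(0, 2))])
    return SecondaryStructureAnnotation(protein.id, "".join(chars))


def generate_peptolome(
    n_pos: int,
    n_neg: int,
    spec: MotifSpec | None = None,
    pssm_signal: float = 6.0,
) -> SyntheticDataset:
    """Generate a labeled corpus of one K-centered site per host protein.

    Positive windows are drawn from the motif-adjusted per-position
    distributions, negatives from the background; every protein gets a
    matching PSSM and secondary-structure annotation. Fully deterministic
    given ``spec.seed``.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    spec = spec or default_motif_spec()
    rng = np.random.default_rng(spec.seed)
    pos_dists = spec.position_distributions()
    neg_dists = np.tile(spec.background, (WINDOW_LENGTH, 1))

    proteins: list[ProteinRecord] = []
    annotations: list[SiteAnnotation] = []
    pssms: dict[str, PssmProfile] = {}
    ss: dict[str, SecondaryStructureAnnotation] = {}
    labels = [1] * n_pos + [0] * n_neg
    for i, label in enumerate(labels):
        window = _draw_window(rng, pos_dists if label else neg_dists)
        sequence, k_position = _embed(rng, window, spec.background)
        pid = f"p{i:05d}"
        protein = ProteinRecord(pid, sequence)
        proteins.append(protein)
        annotations.append(SiteAnnotation(pid, k_position, label))
        pssms[pid] = generate_pssm(protein, pssm_signal, int(rng.integers(2**31)))
        ss[pid] = generate_ss(protein, int(rng.integers(2**31)))
    return SyntheticDataset(proteins, annotations, pssms, ss)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write FASTA + sites.tsv + per-protein .pssm files + ss.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.proteins, outdir / "proteins.fasta")
    write_sites(dataset.annotations, outdir / "sites.tsv")
    pssm_dir = outdir / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    for pid, profile in dataset.pssms.items():
        write_pssm(profile, pssm_dir / f"{pid}.pssm")
    write_ss(dataset.ss, outdir / "ss.tsv")
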