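"""Two-sample-logo statistics: per-position residue enrichment/depletion.

For every (window position, standard residue) pair, per-sequence presence
indicators (1 if the sequence carries that residue at that position) are
compared between the positive and negative sets with a pooled-variance
two-sample t-test. Entries with p <= alpha are flagged significant and
partitioned into enriched (delta > 0) and depleted (delta < 0), which is
what a two-sample logo draws. No multiple-testing correction is applied to
the display threshold (matching the raw p <= 0.05 convention of two-sample
logos); a Bonferroni-adjusted column is exported for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import PeptideWindow
from .residues import STANDARD20, STANDARD20_INDEX


@dataclass(frozen=True)
class PositionResidueStat:
    position: int  # 1-based window position
    residue: str
    freq_pos: float
    freq_neg: float
    delta: float
    p_value: float
    significant: bool


def _to_sequences(windows: Sequence[PeptideWindow | str]) -> list[str]:
    return [w.sequence if isinstance(w, PeptideWindow) else w for w in windows]


def _indicator_counts(seqs: list[str], length: int) -> np.ndarray:
    """counts[i, j] = number of sequences with STANDARD20[j] at position i."""
    counts = np.zeros((length, 20))
    for s in seqs:
        for i, c in enumerate(s):
            j = STANDARD20_INDEX.get(c)
            if j is not None:
                counts[i, j] += 1
    return counts


def _pooled_t_pvalues(c1: np.ndarray, n1: int, c2: np.ndarray, n2: int) -> np.ndarray:
    """Vectorized pooled two-sample t-test on Bernoulli indicator counts."""
    m1, m2 = c1 / n1, c2 / n2
    # sample variances with ddof=1 for 0/1 data
    s1 = n1 * m1 * (1 - m1) / (n1 - 1) if n1 > 1 else np.zeros_like(m1)
    s2 = n2 * m2 * (1 - m2) / (n2 - 1) if n2 > 1 else np.zeros_like(m2)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / df
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
        p = 2 * stats.t.sf(np.abs(t), df)
    # zero pooled variance: both groups constant -> p = 1 if equal else 0
    degenerate = se == 0
    p = np.where(degenerate, np.where(m1 == m2, 1.0, 0.0), p)
    return p


def two_sample_logo(
    pos_windows: Sequence[PeptideWindow | str],
    neg_windows: Sequence[PeptideWindow | str],
    alpha: float = 0.05,
) -> list[PositionResidueStat]:
    """Per-(position, residue) frequencies, deltas and t-test p-values.

    Placeholder 'X' and 'U' are excluded from frequencies, so per-position
    class frequencies sum to at most 1. The invariant center lysine is
    reported like any other cell (it is non-significant by construction).
    """
    pos = _to_sequences(pos_windows)
    neg = _to_sequences(neg_windows)
    if not pos or not neg:
        raise ValueError("both window sets must be non-empty")
    length = len(pos[0])
    if any(len(s) != length for s in pos + neg):
        raise ValueError("all windows must share one length")
    n1, n2 = len(pos), len(neg)
    c1 = _indicator_counts(pos, length)
    c2 = _indicator_counts(neg, length)
    p = _pooled_t_pvalues(c1, n1, c2, n2)
    f1, f2 = c1 / n1, c2 / n2
    stats_out = []
    for i in range(length):
        for j, aa in enumerate(STANDARD20):
            stats_out.append(
                PositionResidueStat(
                    position=i + 1,
                    residue=aa,
                    freq_pos=float(f1[i, j]),
                    freq_neg=float(f2[i, j]),
                    delta=float(f1[i, j] - f2[i, j]),
                    p_value=float(p[i, j]),
                    significant=bool(p[i, j] <= alpha),
                )
            )
    return stats_out


def stats_frame(stats_list: Sequence[PositionResidueStat]) -> pd.DataFrame:
    df = pd.DataFrame([s.__dict__ for s in stats_list])
    df["p_bonferroni"] = np.minimum(df["p_value"] * len(df), 1.0)
    return df


# conventional amino-acid colour classes for logo rendering
_COLORS = {
    **{aa: "#109648" for aa in "STYCQN"},  # polar
    **{aa: "#255c99" for aa in "KRH"},  # basic
    **{aa: "#d62839" for aa in "DE"},  # acidic
    **{aa: "#221e22" for aa in "AVLIPWFMG"},  # hydrophobic
}


def logo_export(
    stats_list: Sequence[PositionResidueStat],
    figure_path: str | Path,
    tsv_path: str | Path | None = None,
) -> pd.DataFrame:
    """Render the two-sample logo and write the full statistics table.

    Upper panel stacks residues significantly enriched in the positive set
    (glyph height proportional to |delta|), lower panel the depleted ones.
    Returns the exported DataFrame.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = stats_frame(stats_list)
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)

    length = int(df["position"].max())
    fig, ax = plt.subplots(figsize=(max(6, length * 0.35), 4))
    max_h = 0.0
    for pos_val, sign in ((1, "enriched"), (-1, "depleted")):
        for position in range(1, length + 1):
            rows = df[
                (df["position"] == position)
                & df["significant"]
                & (np.sign(df["delta"]) == pos_val)
            ].sort_values("delta", key=np.abs, ascending=False)
            offset = 0.0
            for _, r in rows.iterrows():
                h = abs(r["delta"])
                y = offset + h / 2 if pos_val > 0 else -(offset + h / 2)
                ax.text(
                    position,
                    y,
                    r["residue"],
                    ha="center",
                    va="center",
                    fontsize=6 + 60 * h,
                    color=_COLORS.get(r["residue"], "black"),
                    fontweight="bold",
                )
                offset += h
            max_h = max(max_h, offset)
    lim = max(max_h * 1.15, 0.05)
    ax.set_xlim(0.5, length + 0.5)
    ax.set_ylim(-lim, lim)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel("window position")
    ax.set_ylabel("frequency difference (pos − neg)")
    ax.set_title("enriched (top) / depleted (bottom) residues, t-test p ≤ 0.05")
    fig.tight_layout()
    fig.savefig(figure_path)
    plt.close(fig)
    return df
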