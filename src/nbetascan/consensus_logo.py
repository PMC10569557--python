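"""Per-position residue frequencies, information content and consensus.

Aligned equal-length motif windows (as extracted by the scanner) are
summarised column by column: relative residue frequencies, Shannon
information content in bits (log2(20) minus the column entropy, no
small-sample correction — the logos are descriptive), and a consensus
string using A/B bracket notation for genuinely split positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ALPHABET

MAX_BITS = math.log2(20)


@dataclass(frozen=True)
class LogoColumn:
    position: int  # 1-based
    frequencies: dict[str, float]
    information_bits: float

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"column {self.position}: frequencies sum to {total}")
        if not -1e-12 <= self.information_bits <= MAX_BITS + 1e-12:
            raise ValueError(
                f"column {self.position}: information {self.information_bits} "
                f"outside [0, log2(20)]"
            )


def information_content(frequencies: dict[str, float]) -> float:
    """log2(20) − Shannon entropy of the column, in bits."""
    freqs = np.asarray([f for f in frequencies.values() if f > 0], dtype=float)
    entropy = float(-(freqs * np.log2(freqs)).sum())
    return max(MAX_BITS - entropy, 0.0)


def column_frequencies(motifs: list[str]) -> list[LogoColumn]:
    """Per-position residue frequencies of aligned equal-length motifs.

    'X' residues are ignored with renormalisation over the remaining
    observations; a column consisting only of X has no frequency
    information and raises.
    """
    if not motifs:
        raise ValueError("need at least one motif")
    length = len(motifs[0])
    if any(len(m) != length for m in motifs):
        raise ValueError("motifs must all have the same length")
    for m in motifs:
        bad = set(m) - ALPHABET
        if bad:
            raise ValueError(f"illegal residue(s) {sorted(bad)} in motif {m!r}")

    columns: list[LogoColumn] = []
    for pos in range(length):
        residues = [m[pos] for m in motifs if m[pos] != "X"]
        if not residues:
            raise ValueError(f"column {pos + 1} contains only X")
        n = len(residues)
        freqs = {r: residues.count(r) / n for r in sorted(set(residues))}
        columns.append(
            LogoColumn(
                position=pos + 1,
                frequencies=freqs,
                information_bits=information_content(freqs),
            )
        )
    return columns


def consensus_string(
    columns: list[LogoColumn], wildcard_threshold: float = 0.5
) -> str:
    """Render a consensus with bracket notation for split positions.

    Per column: the modal residue alone when it reaches the threshold and
    no runner-up reaches 0.2; "A/B" when the top two jointly reach the
    threshold and each reaches 0.2 (most frequent first; exact ties break
    alphabetically); otherwise "X".
    """
    parts: list[str] = []
    for col in columns:
        ranked = sorted(col.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
        top_res, top_f = ranked[0]
        second_f = ranked[1][1] if len(ranked) > 1 else 0.0
        if top_f >= wildcard_threshold and second_f < 0.2:
            parts.append(top_res)
        elif (
            len(ranked) > 1
            and top_f + second_f >= wildcard_threshold
            and top_f >= 0.2
            and second_f >= 0.2
        ):
            parts.append(f"{top_res}/{ranked[1][0]}")
        else:
            parts.append("X")
    return "".join(p if len(p) == 1 else p for p in parts) if all(
        len(p) == 1 for p in parts
    ) else "-".join(parts)


def logo_frame(columns: list[LogoColumn]) -> pd.DataFrame:
    """Tidy table (position, residue, frequency, bits) for reports/plots."""
    rows = [
        {
            "position": col.position,
            "residue": residue,
            "frequency": freq,
            "bits": col.information_bits,
        }
        for col in columns
        for residue, freq in sorted(col.frequencies.items())
    ]
    return pd.DataFrame(rows, columns=["position", "residue", "frequency", "bits"])


def plot_logo(columns: list[LogoColumn], path: str) -> None:
    """Stacked-bar logo (height = per-residue information share), cosmetic."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, len(columns)), 3))
    for col in columns:
        bottom = 0.0
        for residue, freq in sorted(
            col.frequencies.items(), key=lambda kv: kv[1]
        ):
            height = freq * col.information_bits
            ax.bar(col.position, height, bottom=bottom, width=0.8)
            if height > 0.15:
                ax.text(
                    col.position, bottom + height / 2, residue,
                    ha="center", va="center", fontsize=8,
                )
            bottom += height
    ax.set_xlabel("motif position")
    ax.set_ylabel("bits")
    ax.set_xticks([c.position for c in columns])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
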