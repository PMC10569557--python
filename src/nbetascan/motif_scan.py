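"""Sliding-window scanner for the 11-residue hydrophilic secretion motif.

The motif model is a position-specific allowed-residue profile:
positions 1-3 are wildcards (the dispensable prefix), positions 4-11 are
the functional core E-S/G-G-S-S/E-S-E-P. A window scores one point per
core position whose residue lies in the allowed set, so scores run 0-8
and a strict match requires all eight.

Windows are evaluated in forward orientation and, optionally, after
reversal (the inverted motif was shown to remain functional), and at full
length 11 or core-only length 8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .io_core import ALPHABET, ProteinRecord, SequenceRegion

FULL_LENGTH = 11
CORE_LENGTH = 8
CORE_OFFSET = FULL_LENGTH - CORE_LENGTH  # prefix positions 1-3 are dispensable

QUARTERS = ("P1", "P2", "P3", "P4")


@dataclass(frozen=True)
class NbetaProfile:
    """Position-specific allowed-residue sets for the 11-position motif.

    ``allowed`` maps 1-based motif position to the residues observed to be
    compatible with secretion (or tolerated variants); positions 1-3 admit
    any residue. ``canonical`` instantiates the wildcard prefix with 'A'
    placeholders, which cannot affect any downstream rule.
    """

    allowed: dict[int, frozenset[str]]
    canonical: str = "AAAESGSSSEP"
    length: int = FULL_LENGTH
    core_span: tuple[int, int] = (4, 11)  # 1-based inclusive positions

    def __post_init__(self) -> None:
        if set(self.allowed) != set(range(1, self.length + 1)):
            raise ValueError("profile must define positions 1..11")
        for pos in range(1, CORE_OFFSET + 1):
            if self.allowed[pos] < (ALPHABET - {"X"}):
                raise ValueError(f"prefix position {pos} must be a wildcard")
        for pos, residue in enumerate(self.canonical, start=1):
            if residue not in self.allowed[pos]:
                raise ValueError(f"canonical residue at position {pos} not allowed")
        if self.core_span[1] - self.core_span[0] + 1 != CORE_LENGTH:
            raise ValueError("core span must cover 8 positions")

    @property
    def core(self) -> str:
        return self.canonical[CORE_OFFSET:]


def default_profile() -> NbetaProfile:
    """The motif profile assembled from the experimentally tested variants.

    Core positions (1-based within the motif):
      4: E (charge anchor)      8: S, E, D, A (S/A secretory in plants)
      5: S, G, A (neutral)      9: S, A (only S retains secretion)
      6: G                     10: E, D (second charge anchor)
      7: S, A                  11: P, D
    """
    wildcard = frozenset(ALPHABET - {"X"})
    allowed = {
        1: wildcard,
        2: wildcard,
        3: wildcard,
        4: frozenset("E"),
        5: frozenset("SGA"),
        6: frozenset("G"),
        7: frozenset("SA"),
        8: frozenset("SEDA"),
        9: frozenset("SA"),
        10: frozenset("ED"),
        11: frozenset("PD"),
    }
    return NbetaProfile(allowed=allowed)


@dataclass(frozen=True)
class MotifMatch:
    """One window hit with placement flags used by the localisation rules."""

    protein_id: str
    region: SequenceRegion
    orientation: str  # "forward" | "inverted"
    window: str
    score: int
    is_core_only: bool
    quarter: str
    n_terminal_quarter: bool
    at_c_terminus: bool

    @property
    def oriented_window(self) -> str:
        """The window in motif reading order (reversed for inverted hits)."""
        return self.window[::-1] if self.orientation == "inverted" else self.window

    def core_residues(self) -> str:
        """Residues at motif core positions 4-11, in motif reading order."""
        w = self.oriented_window
        return w if len(w) == CORE_LENGTH else w[CORE_OFFSET:]


def score_window(window: str, profile: NbetaProfile) -> int:
    """Count core positions (4-11) whose residue is in the allowed set.

    Accepts a full 11-mer or a bare 8-mer core; the wildcard prefix never
    contributes. 'X' matches nothing.
    """
    if len(window) == FULL_LENGTH:
        core = window[CORE_OFFSET:]
    elif len(window) == CORE_LENGTH:
        core = window
    else:
        raise ValueError(f"window must be {CORE_LENGTH} or {FULL_LENGTH} residues, got {len(window)}")
    return sum(
        1
        for pos, residue in zip(range(4, 12), core)
        if residue in profile.allowed[pos]
    )


def quarter_of(start: int, seq_len: int) -> str:
    """Quarter of the primary structure containing a match start.

    P1 is the N-terminal 25%, P4 the C-terminal 25%; the quarter index is
    floor(4*start/len) clamped to P4.
    """
    if seq_len <= 0:
        raise ValueError("sequence length must be positive")
    if not 0 <= start < seq_len:
        raise ValueError(f"start {start} outside sequence of length {seq_len}")
    return QUARTERS[min(4 * start // seq_len, 3)]


def _windows(seq_len: int, allow_core_only: bool) -> Iterator[tuple[int, int]]:
    for start in range(seq_len - FULL_LENGTH + 1):
        yield start, start + FULL_LENGTH
    if allow_core_only:
        for start in range(seq_len - CORE_LENGTH + 1):
            yield start, start + CORE_LENGTH


def scan_sequence(
    record: ProteinRecord,
    profile: NbetaProfile | None = None,
    min_score: int = 8,
    allow_inverted: bool = True,
    allow_core_only: bool = False,
) -> list[MotifMatch]:
    """Scan one protein for motif-like windows.

    Every window of length 11 (and, with ``allow_core_only``, length 8) is
    scored in forward orientation and, with ``allow_inverted``, on the
    reversed window. All hits with ``score >= min_score`` are reported,
    sorted by start; overlapping hits are not suppressed. Sequences
    shorter than 8 residues yield an empty list.
    """
    if profile is None:
        profile = default_profile()
    if not 0 <= min_score <= CORE_LENGTH:
        raise ValueError("min_score must be within 0-8")
    seq = record.sequence
    n = len(seq)
    matches: list[MotifMatch] = []
    for start, end in _windows(n, allow_core_only):
        window = seq[start:end]
        orientations = [("forward", window)]
        if allow_inverted:
            orientations.append(("inverted", window[::-1]))
        for orientation, oriented in orientations:
            score = score_window(oriented, profile)
            if score < min_score:
                continue
            q = quarter_of(start, n)
            matches.append(
                MotifMatch(
                    protein_id=record.id,
                    region=SequenceRegion(start, end),
                    orientation=orientation,
                    window=window,
                    score=score,
                    is_core_only=(end - start == CORE_LENGTH),
                    quarter=q,
                    n_terminal_quarter=(q == "P1"),
                    at_c_terminus=(end == n),
                )
            )
    matches.sort(key=lambda m: (m.region.start, m.region.end, m.orientation))
    return matches


def scan_records(
    records: list[ProteinRecord],
    profile: NbetaProfile | None = None,
    **params,
) -> list[MotifMatch]:
    out: list[MotifMatch] = []
    for rec in records:
        out.extend(scan_sequence(rec, profile, **params))
    return out


def matches_to_frame(matches: list[MotifMatch]) -> "pd.DataFrame":
    """Tabulate matches with 1-based inclusive coordinates for reporting."""
    import pandas as pd

    rows = []
    for m in matches:
        first, last = m.region.to_one_based()
        rows.append(
            {
                "id": m.protein_id,
                "start": first,
                "end": last,
                "orientation": m.orientation,
                "window": m.window,
                "score": m.score,
                "quarter": m.quarter,
                "at_c_terminus": m.at_c_terminus,
            }
        )
    columns = [
        "id", "start", "end", "orientation", "window",
        "score", "quarter", "at_c_terminus",
    ]
    return pd.DataFrame(rows, columns=columns)
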