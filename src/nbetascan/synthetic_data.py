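"""Synthetic proteomes with planted motifs, and the fusion-construct fixture.

Two jobs live here:

* ``make_reference_constructs`` encodes the 15 GFP-fusion constructs whose
  subcellular fate was determined experimentally (deletion series, point
  variants at positions 5/8/9, interior/C-terminal/inverted placements,
  and the ER-retention control). Segments that stand in for folded
  domains (the thioredoxin core / GFP barrel) are seeded random sequences
  verified to be motif-free — the rules depend only on motif placement,
  so domain identity is irrelevant.
* ``simulate_proteome`` generates a proteome of motif-free background
  sequences with chosen motif variants planted at controlled quarters,
  together with a truth table, standing in for a homology-search-derived
  dataset when exercising the scanner and the dataset-level statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ProteinRecord
from .motif_scan import default_profile, quarter_of, scan_sequence

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Average amino-acid composition of UniProtKB/Swiss-Prot (fractions).
SWISSPROT_BACKGROUND = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}

#: N-terminal extension placeholder: 16 neutral residues (Met + glycines),
#: matching the extension's length without inventing its sequence.
NALPHA_PLACEHOLDER = "M" + "G" * 15

_CANONICAL = "AAAESGSSSEP"

VARIANTS = (
    "canonical", "S5G", "S8A", "S8D", "S8E", "S9A",
    "A5E8_mito", "minus3", "minus6", "inverted",
)


def canonical_nbeta() -> str:
    """The canonical 11-mer motif.

    Positions 4-11 are the attested functional core ESGSSSEP; positions
    1-3 are wildcard placeholders instantiated as 'A' (position 1 is an
    Ala in the reference protein; 2-3 are never printed and cannot affect
    any rule because the prefix is dispensable).
    """
    return _CANONICAL


def make_variant(name: str) -> str:
    """Build a named motif variant: substitution, prefix deletion or reversal."""
    c = _CANONICAL
    table = {
        "canonical": c,
        "S5G": c[:4] + "G" + c[5:],
        "S8A": c[:7] + "A" + c[8:],
        "S8D": c[:7] + "D" + c[8:],
        "S8E": c[:7] + "E" + c[8:],
        "S9A": c[:8] + "A" + c[9:],
        "A5E8_mito": c[:4] + "A" + c[5:7] + "E" + c[8:],
        "minus3": c[3:],
        "minus6": c[6:],
        "inverted": c[::-1],
    }
    if name not in table:
        raise ValueError(f"unknown variant {name!r}; choose from {VARIANTS}")
    return table[name]


def _is_motif_free(seq: str, margin_score: int = 7) -> bool:
    """True when no window reaches ``margin_score`` in any orientation/length."""
    rec = ProteinRecord(id="bg", sequence=seq)
    hits = scan_sequence(
        rec, default_profile(), min_score=margin_score,
        allow_inverted=True, allow_core_only=True,
    )
    return not hits


def _random_background(
    rng: np.random.Generator,
    length: int,
    composition: dict[str, float] | None = None,
    max_attempts: int = 50,
) -> str:
    """Draw a motif-free random sequence from the residue composition."""
    if composition is None:
        residues, probs = list(AA20), None
    else:
        residues = list(composition)
        probs = np.asarray([composition[r] for r in residues], dtype=float)
        # allow rounded published composition tables; renormalise below
        if not math.isclose(probs.sum(), 1.0, abs_tol=1e-2):
            raise ValueError("background composition must sum to 1")
        probs = probs / probs.sum()
    for _ in range(max_attempts):
        seq = "".join(rng.choice(residues, size=length, p=probs))
        # no retention tetrapeptide may sit at a segment boundary either
        if _is_motif_free(seq) and seq[-4:] not in ("KDEL", "HDEL"):
            return seq
    raise RuntimeError("could not generate a motif-free background segment")


# -- fusion-construct fixture -------------------------------------------------


@dataclass(frozen=True)
class ConstructFixture:
    """One fusion construct with its experimentally observed fate."""

    name: str
    segments: tuple[tuple[str, str], ...]
    expected: str
    provenance: str

    def sequence(self) -> str:
        return "".join(seq for _, seq in self.segments)

    def to_record(self) -> ProteinRecord:
        return ProteinRecord(
            id=self.name, sequence=self.sequence(), taxon="plant"
        )


_STANDIN_SEED = 20230717  # fixed: the stand-in domain is part of the fixture
_STANDIN_LENGTH = 120


def standin_domain(length: int = _STANDIN_LENGTH, seed: int = _STANDIN_SEED) -> str:
    """Seeded motif-free segment standing in for a folded domain (core/GFP)."""
    return _random_background(np.random.default_rng(seed), length)


def natrxh_like_sequence() -> str:
    """A 152-residue reference-protein stand-in: extension, motif, then a
    motif-free body — the motif occupies residues 17-27 as in the real
    protein."""
    body = _random_background(np.random.default_rng(_STANDIN_SEED + 1), 125)
    return NALPHA_PLACEHOLDER + _CANONICAL + body


def make_reference_constructs() -> list[ConstructFixture]:
    """The 15 fusion constructs with their observed localisations."""
    gfp = standin_domain()
    met = ("met", "M")
    nb = ("Nbeta", _CANONICAL)
    core = ("core_gfp", gfp)

    def fx(name, segments, expected, provenance):
        return ConstructFixture(name, tuple(segments), expected, provenance)

    constructs = [
        fx("NaTrxh-GFP", [("Nalpha", NALPHA_PLACEHOLDER), nb, core],
           "secreted", "full-length fusion control"),
        fx("Nbeta-GFP", [met, nb, core], "secreted", "motif alone suffices"),
        fx("NaTrxhdNa+3-GFP", [met, ("Nbeta-3", make_variant("minus3")), core],
           "secreted", "deletion series: -3 keeps function"),
        fx("Nbeta(-3)-GFP", [met, ("Nbeta-3", make_variant("minus3")), core],
           "secreted", "deletion series: -3 keeps function"),
        fx("NaTrxhdNa+6-GFP", [met, ("Nbeta-6", make_variant("minus6")), core],
           "cytoplasmic", "deletion series: -6 abolishes function"),
        fx("Nbeta(-6)-GFP", [met, ("Nbeta-6", make_variant("minus6")), core],
           "cytoplasmic", "deletion series: -6 abolishes function"),
        fx("Nbeta(S5G)-GFP", [met, ("Nbeta_S5G", make_variant("S5G")), core],
           "secreted", "position-5 variant"),
        fx("Nbeta(S9A)-GFP", [met, ("Nbeta_S9A", make_variant("S9A")), core],
           "cytoplasmic", "position-9 variant"),
        fx("Nbeta(S8A)-GFP", [met, ("Nbeta_S8A", make_variant("S8A")), core],
           "secreted", "position-8 variant"),
        fx("Nbeta(S8D)-GFP", [met, ("Nbeta_S8D", make_variant("S8D")), core],
           "cytoplasmic", "position-8 variant"),
        fx("Nbeta(S8E)-GFP", [met, ("Nbeta_S8E", make_variant("S8E")), core],
           "cytoplasmic", "position-8 variant"),
        fx("NaTrxhdNab-Nbeta-GFP", [("core", gfp), nb, ("gfp", gfp)],
           "cytoplasmic", "interior placement"),
        fx("GFP-Nbeta", [("gfp", gfp), nb], "secreted", "exact C-terminal placement"),
        fx("Nbetainv-GFP", [met, ("Nbeta_inv", make_variant("inverted")), core],
           "secreted", "inverted motif"),
        fx("GFP-Nbeta(KDEL)", [("gfp", gfp), nb, ("kdel", "KDEL")],
           "er_retained", "ER-retention control"),
    ]
    return constructs


# -- proteome simulation ------------------------------------------------------


@dataclass(frozen=True)
class PlantSpec:
    """One block of planted motifs: which variant, where, how many, and the
    annotation category (A-D) recorded in the truth table / metadata."""

    variant: str
    quarter: str  # P1..P4
    count: int
    category: str = "D"


@dataclass(frozen=True)
class SimSpec:
    n_sequences: int = 500
    length_range: tuple[int, int] = (80, 300)
    residue_background: dict[str, float] | None = None  # None = uniform over 20
    plant_fraction: float = 0.5
    planted: tuple[PlantSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences <= 0:
            raise ValueError("n_sequences must be positive")
        lo, hi = self.length_range
        if not (44 <= lo <= hi):
            # 44 = smallest length where an 11-mer fits in every quarter
            raise ValueError("length_range must satisfy 44 <= min <= max")
        if sum(p.count for p in self.planted) > self.n_sequences:
            raise ValueError("planted counts exceed n_sequences")
        if not 0.0 <= self.plant_fraction <= 1.0:
            raise ValueError("plant_fraction must be in [0,1]")


_CATEGORY_ANNOTATION = {
    "A": ("secreted", 5),
    "B": ("secreted", 2),
    "C": ("cytoplasmic", 5),
    "D": ("none", 0),
}


def _plant_start(rng: np.random.Generator, quarter: str, seq_len: int, motif_len: int) -> int:
    q = "P1 P2 P3 P4".split().index(quarter)
    lo = math.ceil(q * seq_len / 4)
    hi = min(math.ceil((q + 1) * seq_len / 4) - 1, seq_len - motif_len)
    if hi < lo:
        raise ValueError(
            f"motif of length {motif_len} does not fit in quarter {quarter} "
            f"of a {seq_len}-residue sequence"
        )
    start = int(rng.integers(lo, hi + 1))
    assert quarter_of(start, seq_len) == quarter
    return start


def simulate_proteome(spec: SimSpec) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate a seeded proteome with planted motif variants plus truth table.

    Background residues are drawn from ``residue_background`` (uniform by
    default) and each background is verified motif-free before a motif is
    written over it at a start drawn uniformly within the target quarter,
    so the truth table is sound by construction. The run is reproducible:
    the same spec (including seed) yields byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range

    jobs: list[PlantSpec | None] = []
    for p in spec.planted:
        if p.variant not in VARIANTS:
            raise ValueError(f"unknown variant {p.variant!r}")
        jobs.extend([p] * p.count)
    jobs.extend([None] * (spec.n_sequences - len(jobs)))

    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    for i, job in enumerate(jobs):
        length = int(rng.integers(lo, hi + 1))
        taxon = "plant" if rng.random() < spec.plant_fraction else "animal"
        background = _random_background(rng, length, spec.residue_background)
        if job is None:
            seq, variant, start_1b, quarter, category = background, "none", 0, "", "D"
        else:
            motif = make_variant(job.variant)
            if len(motif) > length:
                raise ValueError("motif longer than sequence")
            start = _plant_start(rng, job.quarter, length, len(motif))
            seq = background[:start] + motif + background[start + len(motif):]
            variant, start_1b, quarter, category = (
                job.variant, start + 1, job.quarter, job.category
            )
        localisation, score = _CATEGORY_ANNOTATION[category]
        records.append(
            ProteinRecord(
                id=f"sim{i:05d}",
                sequence=seq,
                description=f"synthetic {variant}",
                taxon=taxon,
                annotated_localisation=localisation,
                annotation_score=score,
            )
        )
        truth_rows.append(
            {
                "id": f"sim{i:05d}",
                "variant": variant,
                "start": start_1b,
                "quarter": quarter,
                "taxon": taxon,
                "category": category,
                "localisation": localisation,
                "score": score,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["id", "variant", "start", "quarter", "taxon",
                 "category", "localisation", "score"],
    )
    return records, truth
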