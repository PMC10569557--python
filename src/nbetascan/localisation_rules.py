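"""Rule engine predicting subcellular fate from the best motif hit.

The experimental evidence behind each rule:

* an ER-retention tetrapeptide (KDEL) at the C-terminus overrides the
  secretion signal — the retained fusion stayed intracellular;
* the motif only works at the N-terminal quarter or at the very
  C-terminus (solvent exposure proxy) — an interior copy is ignored;
* the core (positions 4-11) is the minimal functional unit — deleting
  into it abolishes secretion while deleting the 3-residue prefix does not;
* position 9 must stay polar-neutral (Ser works, Ala does not);
* position 8 is taxon-dependent: plant proteins secrete with Ser or Ala,
  while Asp/Glu there abolish plant secretion; in animals a Glu-8 is
  hypothesised to be the secretory form;
* Ala-5 together with Glu-8 matches the mitochondrially targeted
  thioredoxin cluster, so it is flagged as a mitochondrial candidate;
* the motif must be net-negative at physiological pH.

Rules are applied in a fixed order R1..R7 and every evaluation is written
to an ordered trace, so each call is auditable and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .io_core import ProteinRecord
from .motif_scan import (
    CORE_LENGTH,
    MotifMatch,
    NbetaProfile,
    default_profile,
    scan_sequence,
)

COMPARTMENTS = (
    "secreted",
    "cytoplasmic",
    "mitochondrial_candidate",
    "er_retained",
    "indeterminate",
)

# tie-break preference across calls from multiple matches of equal score
_PREFERENCE = {
    "secreted": 0,
    "mitochondrial_candidate": 1,
    "er_retained": 2,
    "cytoplasmic": 3,
    "indeterminate": 4,
}


@dataclass(frozen=True)
class RuleConfig:
    taxon_mode: str = "plant"  # "plant" | "animal"
    neutral_pos9: frozenset[str] = frozenset("STNQG")
    plant_pos8_secretory: frozenset[str] = frozenset("SA")
    animal_pos8_secretory: frozenset[str] = frozenset("E")
    mito_requires_pos5: frozenset[str] = frozenset("A")
    mito_requires_pos8: frozenset[str] = frozenset("E")
    charge_must_be_negative: bool = True
    kdel_variants: frozenset[str] = frozenset({"KDEL", "HDEL"})

    def __post_init__(self) -> None:
        if self.taxon_mode not in ("plant", "animal"):
            raise ValueError(f"taxon_mode must be plant or animal, got {self.taxon_mode!r}")
        if "KDEL" not in self.kdel_variants:
            raise ValueError("kdel_variants must include KDEL")
        for name in ("neutral_pos9", "plant_pos8_secretory", "animal_pos8_secretory",
                     "mito_requires_pos5", "mito_requires_pos8"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")


@dataclass(frozen=True)
class LocalisationCall:
    protein_id: str
    compartment: str
    best_match: MotifMatch | None
    trace: tuple[tuple[str, bool, str], ...]

    def fired_rules(self) -> list[str]:
        return [rule for rule, fired, _ in self.trace if fired]


def net_charge(seq: str) -> int:
    """Net charge at physiological pH: (#K + #R) - (#D + #E), His neutral."""
    return sum(seq.count(r) for r in "KR") - sum(seq.count(r) for r in "DE")


def mean_hydropathy(seq: str) -> float:
    """Mean Kyte-Doolittle hydropathy; 'X' residues are excluded."""
    values = [KYTE_DOOLITTLE[r] for r in seq if r != "X"]
    if not values:
        raise ValueError("mean_hydropathy needs at least one non-X residue")
    return sum(values) / len(values)


def classify_match(
    record: ProteinRecord, match: MotifMatch, config: RuleConfig | None = None
) -> LocalisationCall:
    """Apply the ordered rule cascade R1..R7 to one motif hit.

    Inverted-orientation hits are evaluated on the reversed window so the
    positional rules see the motif in reading order; the charge rule is
    orientation-invariant.
    """
    if config is None:
        config = RuleConfig()
    seq = record.sequence
    start, end = match.region.start, match.region.end
    if not (0 <= start < end <= len(seq)) or seq[start:end] != match.window:
        raise ValueError(
            f"match window does not correspond to record {record.id!r} sequence"
        )

    trace: list[tuple[str, bool, str]] = []

    def call(compartment: str) -> LocalisationCall:
        return LocalisationCall(record.id, compartment, match, tuple(trace))

    # R1 — ER retention tetrapeptide at the protein C-terminus (terminal rule)
    tail = seq[-4:]
    if tail in config.kdel_variants:
        trace.append(("R1_kdel", True, f"C-terminal {tail} retention signal"))
        return call("er_retained")
    trace.append(("R1_kdel", False, f"C-terminal 4-mer {tail} not a retention signal"))

    # R2 — placement: N-terminal quarter or exact C-terminus
    exposed = match.n_terminal_quarter or match.at_c_terminus
    trace.append(
        ("R2_placement", not exposed,
         f"quarter={match.quarter}, at_c_terminus={match.at_c_terminus}")
    )
    if not exposed:
        return call("cytoplasmic")

    # R3 — full core (positions 4-11) must be present
    core = match.core_residues()
    if len(core) < CORE_LENGTH:
        trace.append(("R3_core_length", True, f"core truncated to {len(core)} residues"))
        return call("cytoplasmic")
    trace.append(("R3_core_length", False, "all 8 core positions present"))

    pos5, pos8, pos9 = core[1], core[4], core[5]

    # R4 — position 9 must be polar-neutral
    if pos9 not in config.neutral_pos9:
        trace.append(("R4_pos9", True, f"position 9 {pos9} not polar-neutral"))
        return call("cytoplasmic")
    trace.append(("R4_pos9", False, f"position 9 {pos9} polar-neutral"))

    # R5 — position 8, taxon-dependent
    if config.taxon_mode == "plant":
        secretory8 = pos8 in config.plant_pos8_secretory
        trace.append(
            ("R5_pos8_plant", not secretory8,
             f"position 8 {pos8}; plant secretory set {sorted(config.plant_pos8_secretory)}")
        )
    else:
        secretory8 = pos8 in config.animal_pos8_secretory
        trace.append(
            ("R5_pos8_animal", not secretory8,
             f"position 8 {pos8}; animal secretory set "
             f"{sorted(config.animal_pos8_secretory)} (hypothesis, not validated)")
        )

    # R6 — mitochondrial transit-peptide branch (Ala-5 together with Glu-8);
    # the supporting cluster is plant thioredoxins, so the branch is
    # plant-mode only
    mito = (
        config.taxon_mode == "plant"
        and pos5 in config.mito_requires_pos5
        and pos8 in config.mito_requires_pos8
    )
    trace.append(("R6_mito", mito, f"position 5 {pos5}, position 8 {pos8}"))
    if mito:
        return call("mitochondrial_candidate")
    if not secretory8:
        return call("cytoplasmic")

    # R7 — the motif must carry net negative charge
    charge = net_charge(match.window)
    if config.charge_must_be_negative and charge >= 0:
        trace.append(("R7_charge", True, f"net charge {charge:+d} not negative"))
        return call("cytoplasmic")
    trace.append(("R7_charge", False, f"net charge {charge:+d}"))

    return call("secreted")


def predict_protein(
    record: ProteinRecord,
    profile: NbetaProfile | None = None,
    config: RuleConfig | None = None,
    min_score: int = 8,
) -> LocalisationCall:
    """Scan a protein and return the localisation call of its best motif hit.

    Core-only (8-mer) windows and inverted orientation are both enabled so
    prefix-deleted and reversed motifs are found. Best hit = highest
    score, then compartment preference (secreted first), then smallest
    start. With no hit at all the protein is called cytoplasmic.
    """
    if profile is None:
        profile = default_profile()
    if config is None:
        config = RuleConfig()
    matches = scan_sequence(
        record, profile, min_score=min_score, allow_inverted=True, allow_core_only=True
    )
    if not matches:
        return LocalisationCall(
            record.id,
            "cytoplasmic",
            None,
            (("no_motif", True, "no Nβ-like motif found"),),
        )
    calls = [classify_match(record, m, config) for m in matches]
    calls.sort(
        key=lambda c: (
            -c.best_match.score,
            _PREFERENCE[c.compartment],
            c.best_match.region.start,
        )
    )
    return calls[0]


def predict_records(
    records: list[ProteinRecord],
    profile: NbetaProfile | None = None,
    config: RuleConfig | None = None,
    **kwargs,
) -> list[LocalisationCall]:
    return [predict_protein(r, profile, config, **kwargs) for r in records]


def calls_to_frame(calls: list[LocalisationCall], with_trace: bool = False) -> pd.DataFrame:
    rows = []
    for c in calls:
        if c.best_match is not None:
            first, last = c.best_match.region.to_one_based()
            score = c.best_match.score
        else:
            first = last = score = None
        row = {
            "id": c.protein_id,
            "compartment": c.compartment,
            "start": first,
            "end": last,
            "score": score,
            "fired_rules": ";".join(c.fired_rules()),
        }
        if with_trace:
            row["trace"] = " | ".join(
                f"{rule}[{'fired' if fired else 'pass'}]: {detail}"
                for rule, fired, detail in c.trace
            )
        rows.append(row)
    columns = ["id", "compartment", "start", "end", "score", "fired_rules"]
    if with_trace:
        columns.append("trace")
    return pd.DataFrame(rows, columns=columns)


def evaluate_constructs(
    fixtures: list, config: RuleConfig | None = None
) -> tuple[pd.DataFrame, float | None]:
    """Predict each fusion-construct fixture and compare with its observed fate.

    Returns a per-construct table and the overall concordance fraction
    (None when the fixture list is empty).
    """
    rows = []
    for fx in fixtures:
        record = fx.to_record()
        call = predict_protein(record, config=config)
        rows.append(
            {
                "name": fx.name,
                "expected": fx.expected,
                "predicted": call.compartment,
                "concordant": call.compartment == fx.expected,
                "provenance": fx.provenance,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["name", "expected", "predicted", "concordant", "provenance"]
    )
    concordance = float(frame["concordant"].mean()) if len(frame) else None
    return frame, concordance
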