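# Methods

## Motif model

The Nβ motif is modelled as an 11-position profile of allowed residue
sets rather than a substitution-matrix profile. The functional evidence
behind the motif is residue-identity based — single substitutions (S5G,
S8A/D/E, S9A) either preserve or abolish secretion outright — so
set-membership scoring is the faithful representation; a BLOSUM-style
similarity mode is deliberately out of scope. Positions 1–3 admit any
residue: the deletion series shows they are dispensable, and their
identities in the reference protein are only partially known. The
canonical 11-mer is therefore written `AAAESGSSSEP`, with 'A'
placeholders in the wildcard prefix (position 1 is an alanine in the
reference protein; positions 2–3 are undocumented). Because the prefix
never contributes to a score or a rule, the placeholder choice cannot
affect any result.

A window's score is the count of satisfied core positions (4–11), so it
ranges 0–8. The **strict** threshold is 8 (all core positions — exactly
the variant space with experimental support) and the **relaxed**
threshold is 6, intended for exploratory scans; both are exposed in the
config. `X` is accepted in input sequences and matches no profile
position.

The scanner slides every 11-mer window and, when core-only matching is
enabled, every 8-mer window, scoring each in forward orientation and —
because the inverted motif was experimentally functional — on the
reversed window. All hits above threshold are reported without
non-maximal suppression; downstream logic picks the best-placed hit.
`scan_sequence` defaults to full-length windows only (so the reference
protein yields exactly one strict hit at residues 17–27), while
`predict_protein` enables core-only windows so prefix-deleted motifs at
the very N-terminus are still found; an 8-mer core hit at any interior
start is always contained in an equal-scoring 11-mer hit, so this only
adds information at sequence edges.

## Placement

Each sequence is divided into four equal quarters; a hit's quarter is
`floor(4·start/len)` clamped to P4, anchored at the window **start**.
The anchor choice is a genuinely open point (midpoint anchoring would be
equally defensible); start-anchoring was chosen and is applied
consistently to scanning, statistics and simulation, so internal
comparisons are unaffected. "At the C-terminus" means the window ends
exactly at the last residue: the evidence contrasts a construct whose
motif is terminal (secreted) with dataset proteins whose closest
C-terminal motif is over a hundred residues away (cytoplasmic), and the
cutoff between those extremes is unknown, so v1 requires exact
terminality.

## Rule cascade

Rules run in a fixed order, each appending `(rule_id, fired, detail)` to
the call's trace:

1. **R1 retention.** A C-terminal KDEL or HDEL retains the protein in
   the ER and overrides everything — retention was shown to defeat an
   otherwise secretion-competent motif. HDEL is included as the common
   plant/fungal variant; the set is configurable.
2. **R2 placement.** N-terminal quarter or exact C-terminus; an interior
   motif is ignored (cytoplasmic). Placement precedes composition
   because a perfect interior motif was shown to fail.
3. **R3 core completeness.** All 8 core positions must be present;
   deleting into the core abolishes function while deleting the prefix
   does not.
4. **R4 position 9.** Must be polar-neutral. Only Ser is proven to work
   and Ala proven to fail; the conjectured "neutral polar" reading is
   implemented as the configurable set {S,T,N,Q,G}.
5. **R5 position 8, by taxon.** Plant mode: {S,A} secretory, {D,E} not.
   Animal mode: Glu-8 secretory, Asp-8 not — this is an explicitly
   unvalidated hypothesis, and animal-mode traces carry a "hypothesis"
   marker.
6. **R6 mitochondrial branch (plant mode).** Ala-5 together with Glu-8
   matches the mitochondrially localised thioredoxin cluster and yields
   `mitochondrial_candidate`; Glu-8 alone is cytoplasmic, matching the
   S8E assay.
7. **R7 charge.** The window must be net-negative:
   `(#K + #R) − (#D + #E) < 0`, His counted neutral at physiological pH.

With several hits, the reported call is the best hit's: highest score,
then compartment preference (secreted > mitochondrial candidate >
ER-retained > cytoplasmic), then smallest start. The tie-break is an
implementation choice (the underlying biology gives no ordering for
multi-motif proteins) and is recorded in the trace. A protein with no
hit is called cytoplasmic.

Mean hydropathy uses the Kyte–Doolittle scale from Biopython, excluding
`X`; it is reported descriptively (the motif core averages −1.5, i.e.
clearly hydrophilic) and is not a rule input.

## Statistics

Quartile counts are tested against a uniform null (¼ per quarter) with a
Pearson goodness-of-fit χ², df = 3 (scipy). Uniformity is the natural
null for "four equal parts"; no alternative null is documented for the
original analysis. Notably, the originally reported statistic of 27.974
is **not recoverable** from the reported counts: 101 + 65 + 45 + 88 =
299 gives 24.68 under the uniform null (304 gives 24.36). Either
different counts, a different null, or a subset was used; this package
reports its own computed value, and the χ² routine is validated against
an independent textbook implementation to 1e-9 instead.

Evidence categories: A = secreted with curation score 5, B = secreted
with score strictly between 1 and 3 (i.e. 2), C = cytoplasmic with
score 5, D = everything else. D is the residual bin — it absorbs
secreted proteins with scores 3–4, all other localisations and
unannotated records — which keeps the partition total and exclusive; the
original four bins leave those cases unassigned. Percentages are
reported to two decimals; p-values to full precision, with threshold
styling left to the caller.

## Consensus and logos

Column frequencies ignore `X` with renormalisation; an all-X column is
an error. Information content is log₂(20) − Shannon entropy, with **no
small-sample correction and no pseudocounts** — the logos are
descriptive summaries of aligned windows, not estimators. The consensus
renders a position as the modal residue when it reaches the wildcard
threshold (default 0.5) with no runner-up at ≥ 0.2, as "A/B" (most
frequent first, alphabetical on exact ties) when the top two jointly
reach the threshold and each reaches 0.2, and as `X` otherwise; the
thresholds are invented conventions and configurable. Plotting is a
cosmetic matplotlib stacked-bar rendering; the logo data product is the
TSV.

## Synthetic data

The generator emulates a homology-search-derived protein set: background
sequences of 80–300 residues (uniform residue composition by default,
which maximises the detectability of accidental motif collisions in
tests; a Swiss-Prot-like composition table is available), with chosen
motif variants written over the background at starts drawn uniformly
within a target quarter. Every background is verified to contain no
window scoring ≥ 7 in either orientation or length before planting, so
the truth table is sound by construction, and runs are fully seeded and
byte-reproducible.

What the generator does **not** emulate: real domain composition and
homology structure, length/composition correlations, signal peptides, or
the score distribution of an actual similarity search. Passing tests on
simulated proteomes therefore demonstrate the correctness of the
scanner, rules and statistics machinery — not the biological recall of
the motif model on real proteomes.

The 15-construct fixture stands in for the experimental fusion-protein
panel. Folded domains (the thioredoxin core, GFP) are represented by a
single seeded, motif-free 120-residue random segment — the rules depend
only on motif placement and composition, never on domain identity — and
the N-terminal extension placeholder is Met + 15 Gly, matching the
extension's 16-residue length without inventing its sequence. Both
stand-ins are labelled synthetic in code.

## Problem sizes and numerical choices

The test suite exercises the scanner-versus-enumeration oracle on 100
random sequences up to 500 residues, planted-motif recovery on a
1000-sequence proteome, and χ² agreement on 200 random count vectors;
these sizes give full coverage of the window/orientation/length
combinatorics while keeping the default run fast. Determinism: all
randomness flows through seeded numpy generators; hypothesis suites are
derandomised. Degenerate inputs are errors where the quantity is
undefined (empty percentage lists, zero-total χ², all-X logo columns)
and empty results where the input is merely small (sequences shorter
than 8 residues scan to an empty hit list).

## Known limitations

* Terminal placement is a proxy for solvent exposure; no structural
  accessibility computation is attempted.
* The animal-mode Glu-8 rule encodes an unvalidated hypothesis and is
  marked as such in every trace.
* Strict scanning reproduces the experimentally tested variant space
  exactly; relaxed scanning (score ≥ 6) has no calibrated false-positive
  rate and is for exploration.
* The quarter anchor (start of the hit) is a convention; analyses that
  depend on quarter assignment near boundaries should treat P-labels of
  borderline hits with care.
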