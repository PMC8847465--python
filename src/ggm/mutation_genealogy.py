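"""The GGM core: variant columns, indel collapsing, genealogical classification.

Each locus is represented by a fixed four-role genealogy

::

        Or ----+
               |        +---- indica
        On ----+--(Os)--+
                        +---- japonica

Mutations carried by the crop (Os) lineages are stratified into the branch on
which they arose: *early* (Phase I, shared by indica and japonica, absent from
both wild parents), *lineage-specific* (Phase II, indica or japonica only), or
*parental diagnostic* (polymorphic between the wild parents — these set the
genealogy topology and carry the parental-origin signal used for gene typing,
but are not crop mutations).  The decision table assumes no recurrent
mutation (infinite sites over the shallow history of domestication); columns
where both crop lineages carry different novel states violate it and are
flagged ``recurrent_suspect``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

from .alignment_io import (
    ConsensusResult,
    OrthologSet,
    RegionAnnotation,
    RegionKind,
    ROLE_INDICA,
    ROLE_JAPONICA,
    ROLE_ON,
    ROLE_OR,
    consensus_indica,
)
from .errors import AnnotationError

ROLES = (ROLE_OR, ROLE_ON, ROLE_INDICA, ROLE_JAPONICA)

# temporal categories
CAT_PARENTAL = "parental_diagnostic"
CAT_EARLY = "early_phase1"
CAT_INDICA = "lineage_indica"
CAT_JAPONICA = "lineage_japonica"
CAT_TRANSIENT = "transient_ambiguous"
CAT_RECURRENT = "recurrent_suspect"

# coding effects
EFFECT_NONE = "none"
EFFECT_SYN = "synonymous"
EFFECT_NONSYN = "nonsynonymous"
EFFECT_INFRAME = "inframe_indel"
EFFECT_FRAMESHIFT = "frameshift"
EFFECT_STOP = "stop_gain"

GAP = "-"
PRESENT = "+"  # symbolic non-gap state for indel events


@dataclass
class MutationEvent:
    """One substitution or collapsed indel with its genealogical category."""

    locus_id: str
    region_kind: RegionKind
    span: tuple[int, int]  # 0-based half-open alignment columns
    kind: str  # "substitution" | "indel"
    states: dict[str, str]  # role -> state (base, '-' or '+' for indels)
    multiplicity: int = 1
    category: str = CAT_TRANSIENT
    derived_state: str | None = None
    coding_effect: str = EFFECT_NONE
    aa_change_count: int = 0
    parent_match: dict[str, str] | None = None  # role -> "Or"|"On"|"neither"
    lineage: str | None = None  # for recurrent_suspect bookkeeping

    @property
    def position(self) -> int:
        return self.span[0]

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


@dataclass
class VariantColumn:
    column: int
    states: dict[str, str]  # role -> state; a role may be absent (gapped there)


# ---------------------------------------------------------------------------
# Variant-column calling
# ---------------------------------------------------------------------------


def call_variant_columns(
    oset: OrthologSet, consensus: ConsensusResult | None = None
) -> tuple[list[VariantColumn], list[MutationEvent]]:
    """Scan the alignment column-wise.

    Returns (variant columns, transient records).  A column is variant when
    the four role-states (after indica consensus) are not all identical.  A
    column containing 'N' in any genome, or an ambiguous indica consensus, is
    excluded from calling and reported as a ``transient_ambiguous`` record.
    """
    if consensus is None:
        consensus = consensus_indica(oset)
    or_seq, on_seq, j_seq = oset.or_seq, oset.on_seq, oset.japonica_seq
    i_seq = consensus.sequence
    all_seqs = list(oset.sequences.values())
    variants: list[VariantColumn] = []
    transient: list[MutationEvent] = []
    for col in range(oset.alignment_length):
        states = {
            ROLE_OR: or_seq[col],
            ROLE_ON: on_seq[col],
            ROLE_INDICA: i_seq[col],
            ROLE_JAPONICA: j_seq[col],
        }
        masked = consensus.ambiguous_mask[col] or any(
            s[col] == "N" for s in all_seqs
        )
        if masked:
            if len(set(states.values())) > 1:
                transient.append(
                    MutationEvent(
                        locus_id=oset.locus_id,
                        region_kind=oset.region_kind,
                        span=(col, col + 1),
                        kind="substitution",
                        states=states,
                        category=CAT_TRANSIENT,
                    )
                )
            continue
        if len(set(states.values())) > 1:
            variants.append(VariantColumn(col, states))
    return variants, transient


# ---------------------------------------------------------------------------
# Indel collapsing
# ---------------------------------------------------------------------------


def collapse_indels(
    variant_columns: Sequence[VariantColumn],
    locus_id: str,
    region_kind: RegionKind,
) -> list[MutationEvent]:
    """Turn variant columns into events.

    Maximal runs of adjacent gap columns sharing an identical role-presence
    pattern merge into ONE indel event (a single mutational origin regardless
    of length).  Substitution columns stay separate events; adjacent
    substitution columns with an identical role->state pattern share a
    multiplicity annotation for reporting.  A substitution hiding inside a
    gap column (present roles disagreeing in base) is emitted as its own
    event restricted to the gap-free roles.
    """
    events: list[MutationEvent] = []
    run: list[VariantColumn] = []
    run_pattern: frozenset[str] | None = None

    def flush_run() -> None:
        nonlocal run, run_pattern
        if run:
            cols = [vc.column for vc in run]
            states = {
                role: (GAP if role in run_pattern else PRESENT) for role in ROLES
            }
            events.append(
                MutationEvent(
                    locus_id=locus_id,
                    region_kind=region_kind,
                    span=(cols[0], cols[-1] + 1),
                    kind="indel",
                    states=states,
                )
            )
        run, run_pattern = [], None

    for vc in variant_columns:
        gapped = frozenset(r for r, s in vc.states.items() if s == GAP)
        if gapped:
            contiguous = run and vc.column == run[-1].column + 1
            if contiguous and gapped == run_pattern:
                run.append(vc)
            else:
                flush_run()
                run = [vc]
                run_pattern = gapped
            # substitution variation among the gap-free roles of this column
            present = {r: s for r, s in vc.states.items() if s != GAP}
            if len(set(present.values())) > 1:
                events.append(
                    MutationEvent(
                        locus_id=locus_id,
                        region_kind=region_kind,
                        span=(vc.column, vc.column + 1),
                        kind="substitution",
                        states=present,
                    )
                )
        else:
            flush_run()
            events.append(
                MutationEvent(
                    locus_id=locus_id,
                    region_kind=region_kind,
                    span=(vc.column, vc.column + 1),
                    kind="substitution",
                    states=dict(vc.states),
                )
            )
    flush_run()
    events.sort(key=lambda e: e.span)
    _annotate_multiplicity(events)
    return events


def _annotate_multiplicity(events: list[MutationEvent]) -> None:
    """Shared 'n x' annotation for adjacent identical-pattern substitutions."""
    i = 0
    while i < len(events):
        j = i
        while (
            j + 1 < len(events)
            and events[j + 1].kind == "substitution"
            and events[i].kind == "substitution"
            and events[j + 1].span[0] == events[j].span[1]
            and _pattern(events[j + 1].states) == _pattern(events[i].states)
        ):
            j += 1
        if j > i:
            for k in range(i, j + 1):
                events[k].multiplicity = j - i + 1
        i = j + 1


def _pattern(states: Mapping[str, str]) -> tuple:
    """Category-relevant pattern: the partition of roles by state."""
    groups: dict[str, list[str]] = {}
    for role, s in sorted(states.items()):
        groups.setdefault(s, []).append(role)
    return tuple(sorted(tuple(v) for v in groups.values()))


# ---------------------------------------------------------------------------
# Genealogical classification
# ---------------------------------------------------------------------------


def classify_event(event: MutationEvent) -> list[MutationEvent]:
    """Assign the temporal category; returns one event, or two when both crop
    lineages carry different novel states at one column (each flagged
    ``recurrent_suspect``)."""
    st = event.states
    if any(role not in st for role in ROLES):
        # some role gapped at a substitution-in-gap column: absence in both
        # parents (or the crop state) cannot be established
        event.category = CAT_TRANSIENT
        return [event]
    s_or, s_on, s_i, s_j = (st[r] for r in ROLES)
    parental = {s_or, s_on}

    if s_i == s_j and s_i not in parental:
        event.category = CAT_EARLY
        event.derived_state = s_i
        return [event]

    i_novel = s_i not in parental and s_i != s_j
    j_novel = s_j not in parental and s_j != s_i
    if i_novel and j_novel:
        # two different novel states: violates the no-recurrence assumption
        out = []
        for lineage, state in ((ROLE_INDICA, s_i), (ROLE_JAPONICA, s_j)):
            ev = MutationEvent(
                locus_id=event.locus_id,
                region_kind=event.region_kind,
                span=event.span,
                kind=event.kind,
                states=dict(st),
                multiplicity=event.multiplicity,
                category=CAT_RECURRENT,
                derived_state=state,
                lineage=lineage,
            )
            out.append(ev)
        return out
    if i_novel and s_j in parental:
        event.category = CAT_INDICA
        event.derived_state = s_i
        return [event]
    if j_novel and s_i in parental:
        event.category = CAT_JAPONICA
        event.derived_state = s_j
        return [event]

    if s_or != s_on and s_i in parental and s_j in parental:
        event.category = CAT_PARENTAL
        event.parent_match = {
            ROLE_INDICA: ROLE_OR if s_i == s_or else ROLE_ON,
            ROLE_JAPONICA: ROLE_OR if s_j == s_or else ROLE_ON,
        }
        return [event]

    event.category = CAT_TRANSIENT
    return [event]


def classify_events(events: Iterable[MutationEvent]) -> list[MutationEvent]:
    out: list[MutationEvent] = []
    for ev in events:
        out.extend(classify_event(ev))
    return out


# ---------------------------------------------------------------------------
# Coding effects
# ---------------------------------------------------------------------------

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _translate_codon(codon: str) -> str:
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table.get(codon, "X")


def frame_columns(ann: RegionAnnotation, oset: OrthologSet) -> list[int]:
    """Alignment columns that make up the reading frame: exonic columns where
    the reference role is ungapped, minus the frame offset, trimmed to a
    multiple of 3."""
    ref = oset.sequence_for_role(ann.reference_role)
    cols = [c for c in ann.exon_columns() if ref[c] != GAP]
    cols = cols[ann.frame_offset :]
    return cols[: len(cols) - (len(cols) % 3)]


def _background_state(event: MutationEvent, oset: OrthologSet, col: int) -> str:
    """Pre-mutation state at an alignment column in the event's branch context.

    Phase-I events are polarized against the wild parents (Or's state when the
    parents disagree — the convention here treats wild parent A as the older
    lineage); Phase-II events against the shared crop state, read from the
    sister crop lineage which still carries it.
    """
    s_or, s_on = oset.or_seq[col], oset.on_seq[col]
    if event.category in (CAT_INDICA, CAT_RECURRENT) and event.lineage != ROLE_JAPONICA:
        sister = oset.japonica_seq[col]
        if sister != GAP:
            return sister
    if event.category == CAT_JAPONICA or (
        event.category == CAT_RECURRENT and event.lineage == ROLE_JAPONICA
    ):
        sister = oset.indica_seqs[0][col]
        if sister != GAP:
            return sister
    if s_or not in (GAP, "N"):
        return s_or
    return s_on


def build_branch_cds(
    oset: OrthologSet, ann: RegionAnnotation, phase: str = CAT_EARLY
) -> str:
    """Ancestral (pre-mutation) coding sequence for a branch.

    ``phase=CAT_EARLY`` gives the wild-parent background; the lineage phases
    give the shared-Os background (the sister crop lineage's sequence).
    """
    cols = frame_columns(ann, oset)
    if phase == CAT_INDICA:
        src = oset.japonica_seq
    elif phase == CAT_JAPONICA:
        src = oset.indica_seqs[0]
    else:
        src = oset.or_seq
    ref = oset.sequence_for_role(ann.reference_role)
    out = []
    for c in cols:
        s = src[c]
        out.append(s if s not in (GAP, "N") else ref[c])
    return "".join(out)


def annotate_coding_effect(
    event: MutationEvent, ann: RegionAnnotation, oset: OrthologSet
) -> MutationEvent:
    """Set coding_effect and aa_change_count for an event on a coding/genomic
    alignment.  Intronic and 5' events get effect 'none'."""
    if event.region_kind != RegionKind.CODING_GENOMIC:
        event.coding_effect = EFFECT_NONE
        return event
    span_cols = range(*event.span)
    exonic = [c for c in span_cols if ann.in_exon(c)]
    if not exonic:
        if all(ann.in_intron(c) or ann.in_exon(c) for c in span_cols) or all(
            not ann.in_exon(c) for c in span_cols
        ):
            event.coding_effect = EFFECT_NONE
            return event
        raise AnnotationError(
            f"{event.locus_id}: event at {event.span} outside annotated spans"
        )

    cols = frame_columns(ann, oset)
    col_index = {c: i for i, c in enumerate(cols)}

    if event.kind == "indel":
        n_exonic = len(exonic)
        if n_exonic % 3 == 0:
            event.coding_effect = EFFECT_INFRAME
            event.aa_change_count = n_exonic // 3
        else:
            event.coding_effect = EFFECT_FRAMESHIFT
            event.aa_change_count = _frameshift_aa_count(event, ann, oset, cols)
        return event

    col = event.span[0]
    if col not in col_index:
        # exonic but reference-gapped: no frame position, effect indeterminate
        event.coding_effect = EFFECT_NONE
        return event
    idx = col_index[col]
    codon_start = (idx // 3) * 3
    codon_cols = cols[codon_start : codon_start + 3]
    anc_codon = "".join(_background_state(event, oset, c) for c in codon_cols)
    derived = event.derived_state
    if derived is None or len(anc_codon) != 3 or GAP in anc_codon or "N" in anc_codon:
        event.coding_effect = EFFECT_NONE
        return event
    pos_in_codon = idx - codon_start
    mut_codon = anc_codon[:pos_in_codon] + derived + anc_codon[pos_in_codon + 1 :]
    aa_anc, aa_mut = _translate_codon(anc_codon), _translate_codon(mut_codon)
    if aa_mut == "*" and aa_anc != "*":
        event.coding_effect = EFFECT_STOP
        event.aa_change_count = 1
    elif aa_anc == aa_mut:
        event.coding_effect = EFFECT_SYN
        event.aa_change_count = 0
    else:
        event.coding_effect = EFFECT_NONSYN
        event.aa_change_count = 1
    return event


def _frameshift_aa_count(
    event: MutationEvent,
    ann: RegionAnnotation,
    oset: OrthologSet,
    cols: list[int],
) -> int:
    """Reference codons from the event to the first novel stop in the shifted
    reading (count to the end of the CDS when no stop arises)."""
    background = [_background_state(event, oset, c) for c in cols]
    deleted = set(range(*event.span))
    mutant = [b for c, b in zip(cols, background) if c not in deleted]
    # insertion case: the derived lineages carry bases where the reference is
    # gapped; those columns are not in the frame, so the shift comes from the
    # derived bases themselves
    derived_gapped = event.states.get(ROLE_INDICA) == GAP or event.states.get(
        ROLE_JAPONICA
    ) == GAP
    if not derived_gapped:
        # derived lineages hold sequence; parents gapped -> insertion
        ins = [
            oset.japonica_seq[c]
            for c in range(*event.span)
            if oset.japonica_seq[c] != GAP
        ]
        first_after = next((i for i, c in enumerate(cols) if c >= event.span[0]), len(cols))
        mutant = [b for b in background[:first_after]] + ins + background[first_after:]
    start_idx = next((i for i, c in enumerate(cols) if c >= event.span[0]), 0)
    codon_start = (start_idx // 3) * 3
    seq = "".join(mutant[codon_start:])
    count = 0
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        count += 1
        if GAP not in codon and "N" not in codon and _translate_codon(codon) == "*":
            break
    return count


# ---------------------------------------------------------------------------
# Phase counting
# ---------------------------------------------------------------------------

PHASE_COLUMNS = ["early", "indica", "japonica", "parental", "transient", "recurrent"]

_CAT_TO_COL = {
    CAT_EARLY: "early",
    CAT_INDICA: "indica",
    CAT_JAPONICA: "japonica",
    CAT_PARENTAL: "parental",
    CAT_TRANSIENT: "transient",
    CAT_RECURRENT: "recurrent",
}


def count_by_phase(events: Iterable[MutationEvent]) -> pd.DataFrame:
    """Per locus x region counts of events in each temporal category (each
    collapsed indel counts once).  Totals are conserved: the sum across the
    category columns equals the number of events."""
    rows: dict[tuple[str, str], dict[str, int]] = {}
    for ev in events:
        key = (ev.locus_id, RegionKind(ev.region_kind).value)
        row = rows.setdefault(key, {c: 0 for c in PHASE_COLUMNS})
        row[_CAT_TO_COL[ev.category]] += 1
    if not rows:
        return pd.DataFrame(
            columns=PHASE_COLUMNS,
            index=pd.MultiIndex.from_tuples([], names=["locus_id", "region"]),
        )
    df = pd.DataFrame.from_dict(rows, orient="index")[PHASE_COLUMNS]
    df.index = pd.MultiIndex.from_tuples(df.index, names=["locus_id", "region"])
    return df.sort_index()


def call_locus(
    oset: OrthologSet, ann: RegionAnnotation | None = None
) -> tuple[list[MutationEvent], list[MutationEvent]]:
    """Convenience driver: consensus -> variant columns -> collapse ->
    classify (-> coding effects when an annotation is given).

    Returns (classified events, transient/masked records)."""
    consensus = consensus_indica(oset)
    variants, transient = call_variant_columns(oset, consensus)
    events = collapse_indels(variants, oset.locus_id, oset.region_kind)
    events = classify_events(events)
    if ann is not None and oset.region_kind == RegionKind.CODING_GENOMIC:
        for ev in events:
            if ev.category in (CAT_EARLY, CAT_INDICA, CAT_JAPONICA, CAT_RECURRENT):
                annotate_coding_effect(ev, ann, oset)
    return events, transient
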