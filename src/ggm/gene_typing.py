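"""Eight-way gene typing from parental-diagnostic site patterns.

Sites polymorphic between the two wild parents carry the parental-origin
signal.  Per region (5' and coding) each crop lineage's allele is scored for
the fraction of diagnostic sites matching each parent, and the locus is
classified:

==== =========================================================
Type Meaning
==== =========================================================
1    ancient/conserved — no diagnostic signal, (almost) no crop mutations
2    On-like — both crop lineages match wild parent B
3    Or-like — both crop lineages match wild parent A
4    mixed — bi-specific mosaic of both parents
5    Or-japonica / On-indica association
6    Or-indica / On-japonica association (reversal of 5)
7    separate parental origins between the 5' and coding regions
8    new allele — a lineage accumulated >5 (5') or >2 (coding) mutations
==== =========================================================

Type 8 is an annotation layered on the base affinity type.  A single-crossover
recombinant allele is a mosaic writable with one parent-switch over the
ordered diagnostic sites; a *clean* recombinant additionally accumulated no
private mutations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment_io import RegionKind, ROLE_INDICA, ROLE_JAPONICA, ROLE_ON, ROLE_OR
from .errors import InsufficientSignalError
from .mutation_genealogy import (
    CAT_EARLY,
    CAT_INDICA,
    CAT_JAPONICA,
    CAT_PARENTAL,
    MutationEvent,
)

# region affinity labels
ANCIENT = "ancient"
ON_LIKE = "on_like"
OR_LIKE = "or_like"
MIXED = "mixed"
OR_J_ON_I = "or_j_on_i"
OR_I_ON_J = "or_i_on_j"
INSUFFICIENT = "insufficient"

NEITHER = "neither"

_BASE_TYPE = {
    ANCIENT: 1,
    ON_LIKE: 2,
    OR_LIKE: 3,
    MIXED: 4,
    OR_J_ON_I: 5,
    OR_I_ON_J: 6,
}

# default operationalization of "identical or similar"
DEFAULT_THETA = 0.9
DEFAULT_MIN_SITES = 3
DEFAULT_ANCIENT_MAX = 1
TYPE8_5PRIME_CUTOFF = 5  # new allele when lineage mutations exceed this (5')
TYPE8_CODING_CUTOFF = 2  # ... or this (coding)


@dataclass
class TypingThresholds:
    theta: float = DEFAULT_THETA
    min_sites: int = DEFAULT_MIN_SITES
    ancient_max: int = DEFAULT_ANCIENT_MAX
    type8_five_prime: int = TYPE8_5PRIME_CUTOFF
    type8_coding: int = TYPE8_CODING_CUTOFF


@dataclass
class RegionCall:
    affinity: str
    diagnostic_site_count: int
    match_fractions: dict[str, dict[str, float]]  # lineage -> {Or: f, On: f}


@dataclass
class RecombinantCall:
    lineage: str
    switch_count: int
    breakpoint: tuple[int, int] | None  # alignment interval between flanking sites
    private_mutation_count: int

    @property
    def clean(self) -> bool:
        return self.switch_count == 1 and self.private_mutation_count == 0


@dataclass
class GeneTypeCall:
    locus_id: str
    region_affinity: dict[str, str]  # region -> affinity label
    region_calls: dict[str, RegionCall]
    final_type: int | None
    new_allele: bool = False
    new_allele_detail: list[tuple[str, str, int]] = field(default_factory=list)
    recombinant: RecombinantCall | None = None
    untyped_reason: str | None = None


# ---------------------------------------------------------------------------
# Diagnostic sites
# ---------------------------------------------------------------------------


def diagnostic_sites(
    events: Iterable[MutationEvent],
) -> dict[str, list[MutationEvent]]:
    """Parental-diagnostic events grouped per region, ordered by position.

    Each carries per-lineage parent-match labels set by classification."""
    out: dict[str, list[MutationEvent]] = {}
    for ev in events:
        if ev.category == CAT_PARENTAL:
            out.setdefault(RegionKind(ev.region_kind).value, []).append(ev)
    for sites in out.values():
        sites.sort(key=lambda e: e.span)
    return out


def _labels_for_lineage(
    sites: Sequence[MutationEvent], lineage: str
) -> list[str]:
    return [
        (ev.parent_match or {}).get(lineage, NEITHER) for ev in sites
    ]


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------


def classify_region(
    diag_sites: Sequence[MutationEvent],
    os_mutation_count: int,
    thresholds: TypingThresholds | None = None,
) -> RegionCall:
    """Decision ladder over diagnostic-site match fractions.

    ``os_mutation_count`` is the total crop-mutation count in the region
    (early + both lineages), used only for the 'ancient' rung.  Match
    fractions stored on the call are over *all* diagnostic sites (novel crop
    states match neither parent, so Or + On fractions may sum below 1); the
    ladder's comparisons use fractions over informative (non-neither) sites.
    """
    th = thresholds or TypingThresholds()
    n = len(diag_sites)
    fractions: dict[str, dict[str, float]] = {}
    informative: dict[str, dict[str, float]] = {}
    for lineage in (ROLE_INDICA, ROLE_JAPONICA):
        labels = _labels_for_lineage(diag_sites, lineage)
        counts = Counter(labels)
        fractions[lineage] = {
            ROLE_OR: counts[ROLE_OR] / n if n else 0.0,
            ROLE_ON: counts[ROLE_ON] / n if n else 0.0,
        }
        m = counts[ROLE_OR] + counts[ROLE_ON]
        informative[lineage] = {
            ROLE_OR: counts[ROLE_OR] / m if m else 0.0,
            ROLE_ON: counts[ROLE_ON] / m if m else 0.0,
        }

    if n == 0 and os_mutation_count <= th.ancient_max:
        affinity = ANCIENT
    elif n < th.min_sites:
        affinity = INSUFFICIENT
    else:
        i_or, i_on = informative[ROLE_INDICA][ROLE_OR], informative[ROLE_INDICA][ROLE_ON]
        j_or, j_on = informative[ROLE_JAPONICA][ROLE_OR], informative[ROLE_JAPONICA][ROLE_ON]
        if i_on >= th.theta and j_on >= th.theta:
            affinity = ON_LIKE
        elif i_or >= th.theta and j_or >= th.theta:
            affinity = OR_LIKE
        elif j_or >= th.theta and i_on >= th.theta:
            affinity = OR_J_ON_I
        elif i_or >= th.theta and j_on >= th.theta:
            affinity = OR_I_ON_J
        else:
            affinity = MIXED
    return RegionCall(
        affinity=affinity, diagnostic_site_count=n, match_fractions=fractions
    )


# ---------------------------------------------------------------------------
# Recombinant detection
# ---------------------------------------------------------------------------


def detect_recombinant(
    labels: Sequence[str],
    site_positions: Sequence[int] | None = None,
    lineage: str = "",
) -> RecombinantCall:
    """Minimal parent-switch count for one lineage's allele over the ordered
    diagnostic sites.

    ``labels`` holds 'Or'/'On'/'neither' per site; 'neither' sites carry no
    parental signal and are tallied as private mutations.  The minimal number
    of switches needed to write the allele as a mosaic of Or- and On-source
    blocks equals the number of label changes along the informative sites
    (a linear scan attains the exhaustive minimum).
    """
    informative = [
        (i, lab) for i, lab in enumerate(labels) if lab in (ROLE_OR, ROLE_ON)
    ]
    private = sum(1 for lab in labels if lab == NEITHER)
    if len(informative) < 2:
        raise InsufficientSignalError(
            f"{lineage or 'lineage'}: fewer than 2 informative diagnostic sites"
        )
    switches = 0
    breakpoint = None
    for (i_prev, lab_prev), (i_next, lab_next) in zip(informative, informative[1:]):
        if lab_prev != lab_next:
            switches += 1
            if site_positions is not None:
                breakpoint = (site_positions[i_prev], site_positions[i_next])
            else:
                breakpoint = (i_prev, i_next)
    if switches != 1:
        breakpoint = None
    return RecombinantCall(
        lineage=lineage,
        switch_count=switches,
        breakpoint=breakpoint,
        private_mutation_count=private,
    )


# ---------------------------------------------------------------------------
# Locus classification
# ---------------------------------------------------------------------------

_PARENTAL_AFFINITIES = {ON_LIKE, OR_LIKE, OR_J_ON_I, OR_I_ON_J}


def combine_region_affinities(
    affinities: Mapping[str, str],
) -> tuple[int | None, str | None]:
    """Base type 1-7 from the per-region affinities (Type 8 is layered on top).

    Agreeing regions map straight to their type; a region without signal
    defers to the other; two different parental-origin affinities mean the 5'
    and coding regions were inherited from different parents (Type 7); any
    other disagreement makes the locus bi-specific overall (Type 4).
    Returns (type, untyped-reason).
    """
    effective = [a for a in affinities.values() if a != INSUFFICIENT]
    if not effective:
        return None, "insufficient diagnostic signal in both regions"
    if len(set(effective)) == 1:
        return _BASE_TYPE[effective[0]], None
    non_ancient = set(effective) - {ANCIENT}
    if len(non_ancient) == 1:
        return _BASE_TYPE[non_ancient.pop()], None
    if non_ancient <= _PARENTAL_AFFINITIES:
        return 7, None
    return 4, None


def classify_locus(
    locus_id: str,
    region_calls: Mapping[str, RegionCall],
    new_mutation_counts: Mapping[str, Mapping[str, int]] | None = None,
    thresholds: TypingThresholds | None = None,
    diag_by_region: Mapping[str, Sequence[MutationEvent]] | None = None,
) -> GeneTypeCall:
    """Combine the two region affinities into a final type 1-6/7 and layer the
    Type-8 (new allele) annotation.

    ``new_mutation_counts`` maps region -> lineage -> lineage-specific
    mutation count (Phase-II); the Type-8 cutoffs are *strictly more than* 5
    (5') and 2 (coding) allelic mutations.
    """
    th = thresholds or TypingThresholds()
    affinities = {r: c.affinity for r, c in region_calls.items()}
    final, reason = combine_region_affinities(affinities)

    new_detail: list[tuple[str, str, int]] = []
    if new_mutation_counts:
        for region, per_lineage in new_mutation_counts.items():
            cutoff = (
                th.type8_five_prime
                if region == RegionKind.FIVE_PRIME.value
                else th.type8_coding
            )
            for lineage, count in per_lineage.items():
                if count > cutoff:
                    new_detail.append((region, lineage, int(count)))

    recombinant = None
    if diag_by_region:
        best: RecombinantCall | None = None
        for region, sites in diag_by_region.items():
            positions = [ev.span[0] for ev in sites]
            for lineage in (ROLE_INDICA, ROLE_JAPONICA):
                labels = _labels_for_lineage(sites, lineage)
                try:
                    call = detect_recombinant(labels, positions, lineage=lineage)
                except InsufficientSignalError:
                    continue
                if call.switch_count == 1 and (best is None or call.clean):
                    best = call
        recombinant = best

    return GeneTypeCall(
        locus_id=locus_id,
        region_affinity=affinities,
        region_calls=dict(region_calls),
        final_type=final,
        new_allele=bool(new_detail),
        new_allele_detail=new_detail,
        recombinant=recombinant,
        untyped_reason=reason,
    )


# ---------------------------------------------------------------------------
# Concordance with an extra genome
# ---------------------------------------------------------------------------


def genome_concordance(
    extra_seqs: Mapping[str, str],
    events_by_locus: Mapping[str, Sequence[MutationEvent]],
) -> pd.DataFrame:
    """Check which classified crop mutations an extra genome carries.

    ``extra_seqs`` maps locus -> sequence aligned in the same column frame as
    that locus's alignment.  For early events the extra genome is expected to
    carry the shared derived state; lineage events are checked against their
    own lineage's derived state.  Returns a per-locus-category table with
    agree/total counts; unalignable loci (missing from ``extra_seqs``) are
    skipped.
    """
    rows = []
    for locus, events in events_by_locus.items():
        seq = extra_seqs.get(locus)
        if seq is None:
            continue
        tallies: dict[str, list[int]] = {}
        for ev in events:
            if ev.category not in (CAT_EARLY, CAT_INDICA, CAT_JAPONICA):
                continue
            if ev.kind == "indel":
                observed = set(seq[ev.span[0] : ev.span[1]])
                carries = (
                    observed == {"-"}
                    if _indel_derived_is_gap(ev)
                    else "-" not in observed
                )
            else:
                carries = seq[ev.span[0]] == ev.derived_state
            agree, total = tallies.setdefault(ev.category, [0, 0])
            tallies[ev.category] = [agree + int(carries), total + 1]
        for category, (agree, total) in tallies.items():
            rows.append(
                {
                    "locus_id": locus,
                    "category": category,
                    "agree": agree,
                    "total": total,
                    "concordance": agree / total if total else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["locus_id", "category", "agree", "total", "concordance"])


def _indel_derived_is_gap(ev: MutationEvent) -> bool:
    """True when the derived crop lineage(s) carry the gap (a deletion)."""
    if ev.category == CAT_EARLY:
        return ev.states.get(ROLE_INDICA) == "-"
    lineage = ROLE_INDICA if ev.category == CAT_INDICA else ROLE_JAPONICA
    return ev.states.get(lineage) == "-"


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------

_BIN_OF_TYPE = {1: "ancient", 2: "uni_specific", 3: "uni_specific",
                4: "bi_specific", 5: "bi_specific", 6: "bi_specific",
                7: "bi_specific"}


def type_census(calls: Iterable[GeneTypeCall]) -> dict:
    """Counts and fractions per final type and per summary bin.

    Type-8 (new-allele) loci are binned under 'new' with the base type kept in
    the per-type counts; fractions are over typed loci and sum to 1.
    """
    type_counts: Counter = Counter()
    bin_counts: Counter = Counter()
    n_typed = 0
    for call in calls:
        if call.final_type is None:
            continue
        n_typed += 1
        type_counts[call.final_type] += 1
        if call.new_allele:
            bin_counts["new"] += 1
        else:
            bin_counts[_BIN_OF_TYPE[call.final_type]] += 1
    return {
        "n_typed": n_typed,
        "type_counts": {str(t): int(c) for t, c in sorted(type_counts.items())},
        "bin_counts": {k: int(v) for k, v in sorted(bin_counts.items())},
        "bin_fractions": {
            k: v / n_typed for k, v in sorted(bin_counts.items())
        }
        if n_typed
        else {},
    }
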