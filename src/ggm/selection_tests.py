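"""Intron-calibrated and codon-based positive-selection tests.

Three criteria, applied per locus, region and phase:

1. **5' rate threshold** — the neutral background rate *u* (mutations per kb
   per period) is estimated by pooling mutations over long (>800 bp) introns;
   a 5' region whose per-kb mutation rate strictly exceeds 3u is called
   positively selected.  At the empirical u = 0.56/kb this reduces to >= 2
   mutations over a 1 kb region.  Substitutions and indels count equally.
2. **dN/dS** — Nei-Gojobori (1986) site counting over the pre-mutation coding
   sequence of the branch; positive when dN/dS > 1.  No multiple-hit
   correction (divergence << 1 over a domestication timescale).
3. **amino-acid rate fallback** — when dS = 0 or indels are present, >= 2
   amino-acid changes per kb of coding sequence; frame-disrupting events
   (frameshift, premature stop) satisfy it automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import EstimationError, FrameError
from .mutation_genealogy import (
    CAT_EARLY,
    CAT_INDICA,
    CAT_JAPONICA,
    EFFECT_FRAMESHIFT,
    EFFECT_NONSYN,
    EFFECT_STOP,
    EFFECT_SYN,
    MutationEvent,
    _translate_codon,
)

MIN_INTRON_BP = 800  # introns shorter than this carry too little signal

PHASE1 = "phase1"
PHASE2_INDICA = "phase2_indica"
PHASE2_JAPONICA = "phase2_japonica"
PHASE2_MAX = "phase2_max"

_PHASE_TO_CAT = {
    PHASE1: CAT_EARLY,
    PHASE2_INDICA: CAT_INDICA,
    PHASE2_JAPONICA: CAT_JAPONICA,
}


@dataclass
class BackgroundRate:
    """Pooled intron mutation rate for one phase (mutations / kb / period)."""

    phase: str
    u: float
    total_mutations: int
    total_kb: float
    introns_used: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class SelectionCall:
    locus_id: str
    region: str  # "five_prime" | "coding"
    phase: str
    test: str  # "rate_threshold_5prime" | "dnds" | "aa_rate"
    statistic: float
    threshold: float
    positive: bool


@dataclass
class DnDsResult:
    dn: float
    ds: float
    n_nonsyn: int
    n_syn: int
    nonsyn_sites: float
    syn_sites: float

    @property
    def ratio(self) -> float:
        return self.dn / self.ds if self.ds > 0 else float("inf")


# ---------------------------------------------------------------------------
# Background rate
# ---------------------------------------------------------------------------


def estimate_background_rate(
    intron_mutation_counts: Sequence[int],
    intron_lengths: Sequence[tuple[str, int, int]],
    phase: str,
    min_intron_bp: int = MIN_INTRON_BP,
) -> BackgroundRate:
    """Pool phase-filtered mutation counts over qualifying introns.

    ``intron_lengths`` holds (locus, intron index, ungapped reference length
    in bp) parallel to ``intron_mutation_counts``; introns of length
    <= ``min_intron_bp`` are dropped from the pool.
    """
    used, counts = [], []
    for cnt, meta in zip(intron_mutation_counts, intron_lengths):
        if meta[2] > min_intron_bp:
            used.append(meta)
            counts.append(cnt)
    if not used:
        raise EstimationError(
            f"no introns longer than {min_intron_bp} bp: supply u in the run "
            "configuration instead"
        )
    total_kb = sum(m[2] for m in used) / 1000.0
    total = int(sum(counts))
    return BackgroundRate(
        phase=phase,
        u=total / total_kb,
        total_mutations=total,
        total_kb=total_kb,
        introns_used=used,
    )


def phase2_background(indica: BackgroundRate, japonica: BackgroundRate) -> BackgroundRate:
    """Phase-II background: the higher of the two lineage estimates."""
    best = indica if indica.u >= japonica.u else japonica
    return BackgroundRate(
        phase=PHASE2_MAX,
        u=best.u,
        total_mutations=best.total_mutations,
        total_kb=best.total_kb,
        introns_used=best.introns_used,
    )


# ---------------------------------------------------------------------------
# 5' threshold test
# ---------------------------------------------------------------------------


def test_5prime(
    mutation_count: int,
    region_kb: float,
    u: float,
    locus_id: str = "",
    phase: str = PHASE1,
) -> SelectionCall:
    """Positive when the per-kb 5' mutation rate strictly exceeds 3u.

    For integer counts this is equivalent to requiring at least
    floor(3u * kb) + 1 mutations, which at u = 0.56 and 1 kb is the published
    reduction "two mutations over a 1 kb region".
    """
    if region_kb <= 0:
        raise EstimationError(f"{locus_id}: non-positive 5' region length")
    statistic = mutation_count / region_kb
    threshold = 3.0 * u
    return SelectionCall(
        locus_id=locus_id,
        region="five_prime",
        phase=phase,
        test="rate_threshold_5prime",
        statistic=statistic,
        threshold=threshold,
        positive=statistic > threshold,
    )


# ---------------------------------------------------------------------------
# Nei-Gojobori site counting and dN/dS
# ---------------------------------------------------------------------------


def ng86_site_counts(cds: str) -> tuple[float, float]:
    """Fractional (nonsynonymous, synonymous) site counts, NG86 style.

    Per codon position, the synonymous fraction is the share of the three
    possible single-nucleotide changes that preserve the amino acid; changes
    creating a stop codon count as nonsynonymous.  Codons containing gaps,
    'N', or encoding a stop are skipped.
    """
    if len(cds) % 3 != 0:
        raise FrameError(f"coding length {len(cds)} not divisible by 3")
    n_sites = s_sites = 0.0
    bases = "ACGT"
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if any(b not in bases for b in codon) or _translate_codon(codon) == "*":
            continue
        aa = _translate_codon(codon)
        for pos in range(3):
            syn = 0
            for alt in bases:
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1 :]
                if _translate_codon(mut) == aa:
                    syn += 1
            s_sites += syn / 3.0
            n_sites += (3 - syn) / 3.0
    return n_sites, s_sites


def compute_dnds(
    branch_events: Iterable[MutationEvent], ancestral_coding: str
) -> DnDsResult:
    """dN and dS for one branch from its classified substitution events.

    Under infinite sites each event is a single nucleotide change already
    classified by :func:`annotate_coding_effect`; site counts come from NG86
    enumeration over the pre-mutation coding sequence.  No multiple-hit
    correction is applied.
    """
    n_sites, s_sites = ng86_site_counts(ancestral_coding)
    n_n = n_s = 0
    for ev in branch_events:
        if ev.kind != "substitution":
            continue
        if ev.coding_effect == EFFECT_SYN:
            n_s += 1
        elif ev.coding_effect in (EFFECT_NONSYN, EFFECT_STOP):
            n_n += 1
    dn = n_n / n_sites if n_sites > 0 else 0.0
    ds = n_s / s_sites if s_sites > 0 else 0.0
    return DnDsResult(dn=dn, ds=ds, n_nonsyn=n_n, n_syn=n_s,
                      nonsyn_sites=n_sites, syn_sites=s_sites)


AA_RATE_THRESHOLD = 2.0  # amino-acid changes per kb of coding sequence


def test_coding(
    branch_events: Sequence[MutationEvent],
    ancestral_coding: str,
    coding_kb: float,
    locus_id: str = "",
    phase: str = PHASE1,
) -> SelectionCall:
    """Codon-based positive-selection call for one branch.

    dN/dS > 1 when dS > 0 and no indels are involved; otherwise the
    amino-acid-rate fallback (>= 2 aa changes per kb, automatically satisfied
    by frameshift or premature-stop events).
    """
    events = [ev for ev in branch_events]
    has_indel = any(ev.kind == "indel" for ev in events)
    disruptive = any(
        ev.coding_effect in (EFFECT_FRAMESHIFT, EFFECT_STOP) for ev in events
    )
    res = compute_dnds(events, ancestral_coding)
    if res.n_syn > 0 and not has_indel:
        ratio = res.dn / res.ds
        return SelectionCall(
            locus_id=locus_id,
            region="coding",
            phase=phase,
            test="dnds",
            statistic=ratio,
            threshold=1.0,
            positive=ratio > 1.0,
        )
    if coding_kb <= 0:
        raise EstimationError(f"{locus_id}: non-positive coding length")
    aa_total = sum(ev.aa_change_count for ev in events)
    rate = aa_total / coding_kb
    return SelectionCall(
        locus_id=locus_id,
        region="coding",
        phase=phase,
        test="aa_rate",
        statistic=rate,
        threshold=AA_RATE_THRESHOLD,
        positive=rate >= AA_RATE_THRESHOLD or disruptive,
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def summarize_selection(calls: Iterable[SelectionCall]) -> pd.DataFrame:
    """Locus x phase table of 5'/coding positivity with statistics, one row
    per locus-phase having at least one call (positive or not)."""
    rows: dict[tuple[str, str], dict] = {}
    for c in calls:
        row = rows.setdefault(
            (c.locus_id, c.phase),
            {
                "locus_id": c.locus_id,
                "phase": c.phase,
                "five_prime_positive": False,
                "coding_positive": False,
                "five_prime_statistic": float("nan"),
                "coding_statistic": float("nan"),
                "coding_test": "",
            },
        )
        if c.region == "five_prime":
            row["five_prime_positive"] = c.positive
            row["five_prime_statistic"] = c.statistic
        else:
            row["coding_positive"] = c.positive
            row["coding_statistic"] = c.statistic
            row["coding_test"] = c.test
    df = pd.DataFrame(rows.values())
    if len(df):
        df["any_positive"] = df["five_prime_positive"] | df["coding_positive"]
        df = df.sort_values(["phase", "locus_id"]).reset_index(drop=True)
    else:
        df = pd.DataFrame(
            columns=[
                "locus_id", "phase", "five_prime_positive", "coding_positive",
                "five_prime_statistic", "coding_statistic", "coding_test",
                "any_positive",
            ]
        )
    return df


def selection_counts(summary: pd.DataFrame) -> dict:
    """Per-phase counts of loci positive in 5', coding, both, and the union."""
    out: dict[str, dict[str, int]] = {}
    for phase, grp in summary.groupby("phase") if len(summary) else []:
        out[str(phase)] = {
            "five_prime": int(grp["five_prime_positive"].sum()),
            "coding": int(grp["coding_positive"].sum()),
            "both": int((grp["five_prime_positive"] & grp["coding_positive"]).sum()),
            "union": int(grp["any_positive"].sum()),
        }
    return out
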