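"""Hybrid-origin ortholog simulator with fully known mutation histories.

The generator emulates the data structure of a domesticated selfing crop and
its two wild parents: per locus, a ~1 kb 5' alignment and an exon/intron
genomic alignment over the four genealogical roles.  The two wild parents
diverge at Poisson-planted diagnostic sites; each region of each locus
inherits a parental haplotype under one of seven inheritance modes (ancient,
On copy, Or copy, per-site mixture, the two lineage-parent association
patterns, or a single-crossover recombinant); Phase-I mutations are planted on
the shared proto-crop haplotype and Phase-II mutations on each crop lineage.
The infinite-sites assumption is enforced by sampling columns without
replacement, so a round trip through the classifier must recover every
planted category exactly.

Defaults mirror the study conditions the package targets: 101 loci over 12
chromosomes, 1 kb 5' regions, a neutral rate of 0.56 mutations per kb per
period, indels as ~15% of mutations with geometric length (mean 3), and
in-frame exonic indels with probability 0.7.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment_io import (
    OrthologSet,
    RegionAnnotation,
    RegionKind,
    ROLE_INDICA,
    ROLE_JAPONICA,
    ROLE_ON,
    ROLE_OR,
)
from .errors import ConfigurationError
from .gene_typing import (
    ANCIENT,
    MIXED,
    ON_LIKE,
    OR_I_ON_J,
    OR_J_ON_I,
    OR_LIKE,
    combine_region_affinities,
)

BASES = "ACGT"

MODE_ANCIENT = "ancient"
MODE_ON = "on"
MODE_OR = "or"
MODE_MIXED = "mixed"
MODE_TYPE5 = "type5"
MODE_TYPE6 = "type6"
MODE_RECOMBINANT = "recombinant"

MODES = (
    MODE_ANCIENT,
    MODE_ON,
    MODE_OR,
    MODE_MIXED,
    MODE_TYPE5,
    MODE_TYPE6,
    MODE_RECOMBINANT,
)

#: region affinity each inheritance mode should classify to
MODE_TO_AFFINITY = {
    MODE_ANCIENT: ANCIENT,
    MODE_ON: ON_LIKE,
    MODE_OR: OR_LIKE,
    MODE_MIXED: MIXED,
    MODE_TYPE5: OR_J_ON_I,
    MODE_TYPE6: OR_I_ON_J,
    MODE_RECOMBINANT: MIXED,
}

BRANCH_PARENTAL = "parental"
BRANCH_EARLY = "early"
BRANCH_INDICA = "indica"
BRANCH_JAPONICA = "japonica"


@dataclass
class SimulationConfig:
    """Study-condition parameters of the generator.

    Rates are mutations per kb per period; ``parental_divergence`` is
    substitutions per kb between the two wild parents (~1% divergence by
    default, enough for ~10 diagnostic sites per kb of region).
    """

    seed: int = 0
    n_loci: int = 101
    n_chromosomes: int = 12
    five_prime_len: int = 1000
    n_exons_range: tuple[int, int] = (3, 6)
    exon_len_range: tuple[int, int] = (120, 360)
    intron_len_range: tuple[int, int] = (200, 1600)
    parental_divergence: float = 10.0
    phase1_rate: float = 0.56
    indica_rate: float = 0.56
    japonica_rate: float = 0.56
    indel_fraction: float = 0.15
    indel_mean_len: float = 3.0
    exon_indel_inframe_prob: float = 0.7
    inheritance_weights: dict[str, float] = field(
        default_factory=lambda: {
            MODE_ANCIENT: 0.06,
            MODE_ON: 0.12,
            MODE_OR: 0.18,
            MODE_MIXED: 0.40,
            MODE_TYPE5: 0.19,
            MODE_TYPE6: 0.02,
            MODE_RECOMBINANT: 0.03,
        }
    )
    selected_fraction: float = 0.2
    selection_multiplier: float = 5.0
    new_allele_fraction: float = 0.1
    new_allele_multiplier: float = 15.0
    n_indica_genomes: int = 3
    indica_disagreement_prob: float = 0.0
    recurrence_prob: float = 0.0

    def validate(self) -> None:
        total = sum(self.inheritance_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"inheritance weights sum to {total}, not 1")
        if set(self.inheritance_weights) - set(MODES):
            raise ConfigurationError("unknown inheritance mode in weights")
        for name in ("parental_divergence", "phase1_rate", "indica_rate",
                     "japonica_rate", "indel_fraction"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 1 <= self.n_indica_genomes <= 3:
            raise ConfigurationError("n_indica_genomes must be 1-3")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PlantedMutation:
    """Ground-truth record for one planted event."""

    region: str  # RegionKind value
    span: tuple[int, int]
    kind: str  # substitution | indel
    branch: str  # parental | early | indica | japonica
    carrier: str | None = None  # Or/On for parental events
    inframe: bool | None = None


@dataclass
class LocusTruth:
    locus_id: str
    chromosome: str
    modes: dict[str, str]  # region -> inheritance mode
    breakpoints: dict[str, int]  # region -> crossover column (recombinant only)
    expected_affinity: dict[str, str]
    expected_type: int | None
    selected: bool
    new_allele_target: tuple[str, str] | None  # (region, lineage)
    mutations: list[PlantedMutation] = field(default_factory=list)

    def count(self, branch: str, region: str | None = None) -> int:
        return sum(
            1
            for m in self.mutations
            if m.branch == branch and (region is None or m.region == region)
        )


@dataclass
class SyntheticLocus:
    five_prime: OrthologSet
    coding: OrthologSet
    annotation: RegionAnnotation
    truth: LocusTruth


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    loci: list[SyntheticLocus]

    def truth_totals(self, region: str = "five_prime") -> dict[str, int]:
        return {
            "m_e": sum(l.truth.count(BRANCH_EARLY, region) for l in self.loci),
            "m_i": sum(l.truth.count(BRANCH_INDICA, region) for l in self.loci),
            "m_j": sum(l.truth.count(BRANCH_JAPONICA, region) for l in self.loci),
        }


# ---------------------------------------------------------------------------
# Column bookkeeping (infinite sites)
# ---------------------------------------------------------------------------


class _ColumnLedger:
    """Tracks used columns; indel spans keep a one-column buffer so two indel
    events can never be adjacent (adjacent same-pattern runs would collapse
    into one event downstream, breaking the planted truth)."""

    def __init__(self, length: int) -> None:
        self.length = length
        self.used = np.zeros(length, dtype=bool)

    def draw_column(self, rng: np.random.Generator, max_tries: int = 200) -> int:
        for _ in range(max_tries):
            col = int(rng.integers(self.length))
            if not self.used[col]:
                self.used[col] = True
                return col
        raise ConfigurationError(
            "sequence saturated: lower the mutation/divergence rates"
        )

    def draw_span(
        self,
        rng: np.random.Generator,
        k: int,
        lo: int = 0,
        hi: int | None = None,
        max_tries: int = 200,
    ) -> tuple[int, int]:
        hi = self.length if hi is None else hi
        if hi - lo < k + 2:
            raise ConfigurationError("region too short for requested indel")
        for _ in range(max_tries):
            start = int(rng.integers(lo, hi - k + 1))
            w_lo, w_hi = max(lo, start - 1), min(hi, start + k + 1)
            if not self.used[w_lo:w_hi].any():
                self.used[w_lo:w_hi] = True
                return (start, start + k)
        raise ConfigurationError(
            "sequence saturated: lower the mutation/divergence rates"
        )


def _geometric_len(rng: np.random.Generator, mean: float) -> int:
    return int(rng.geometric(1.0 / max(mean, 1.0)))


# ---------------------------------------------------------------------------
# Per-region construction
# ---------------------------------------------------------------------------


@dataclass
class _RegionPlan:
    region: RegionKind
    length: int
    exon_spans: list[tuple[int, int]]
    intron_spans: list[tuple[int, int]]

    def in_exon(self, col: int) -> bool:
        return any(s <= col < e for s, e in self.exon_spans)

    def exon_containing(self, col: int) -> tuple[int, int] | None:
        for s, e in self.exon_spans:
            if s <= col < e:
                return (s, e)
        return None


def _simulate_region(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    plan: _RegionPlan,
    mode: str,
    rate_multipliers: dict[str, float],
    truth: LocusTruth,
) -> dict[str, list[str]]:
    """Build the four role sequences for one region; append planted mutations
    to ``truth``.  Returns role -> sequence (as mutable char lists joined by
    the caller)."""
    L = plan.length
    region = plan.region.value
    anc = rng.choice(list(BASES), size=L)
    ledger = _ColumnLedger(L)

    or_seq = list(anc)
    on_seq = list(anc)

    # --- wild-parent divergence -------------------------------------------
    div_events: list[PlantedMutation] = []
    if mode != MODE_ANCIENT:
        n_div = rng.poisson(cfg.parental_divergence * L / 1000.0)
        for _ in range(n_div):
            carrier = ROLE_OR if rng.random() < 0.5 else ROLE_ON
            target = or_seq if carrier == ROLE_OR else on_seq
            is_indel = rng.random() < cfg.indel_fraction
            col = ledger.draw_column(rng)
            if is_indel and not plan.in_exon(col):
                ledger.used[col] = False  # re-draw as a span
                k = _geometric_len(rng, cfg.indel_mean_len)
                span = ledger.draw_span(rng, k)
                if any(plan.in_exon(c) for c in range(*span)):
                    # keep the wild reference ungapped in exons
                    for c in range(max(0, span[0] - 1), min(L, span[1] + 1)):
                        ledger.used[c] = False
                    col = ledger.draw_column(rng)
                    target[col] = _other_base(rng, anc[col])
                    ev = PlantedMutation(region, (col, col + 1), "substitution",
                                         BRANCH_PARENTAL, carrier=carrier)
                else:
                    for c in range(*span):
                        target[c] = "-"
                    ev = PlantedMutation(region, span, "indel",
                                         BRANCH_PARENTAL, carrier=carrier)
            else:
                target[col] = _other_base(rng, anc[col])
                ev = PlantedMutation(region, (col, col + 1), "substitution",
                                     BRANCH_PARENTAL, carrier=carrier)
            div_events.append(ev)
            truth.mutations.append(ev)
    div_events.sort(key=lambda e: e.span)

    # --- proto-crop haplotype(s) ------------------------------------------
    sources_i, sources_j = _draw_sources(cfg, rng, mode, div_events, plan, truth)
    i_hap = list(anc)
    j_hap = list(anc)
    for ev, src_i, src_j in zip(div_events, sources_i, sources_j):
        donor = {ROLE_OR: or_seq, ROLE_ON: on_seq}
        for hap, src in ((i_hap, src_i), (j_hap, src_j)):
            for c in range(*ev.span):
                hap[c] = donor[src][c]

    # --- crop mutations ----------------------------------------------------
    if mode != MODE_ANCIENT:
        _plant_crop_mutations(
            cfg, rng, plan, ledger, anc, i_hap, j_hap, rate_multipliers, truth
        )

    return {ROLE_OR: or_seq, ROLE_ON: on_seq,
            ROLE_INDICA: i_hap, ROLE_JAPONICA: j_hap}


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in BASES if b != base]
    return choices[int(rng.integers(3))]


def _draw_sources(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    mode: str,
    div_events: Sequence[PlantedMutation],
    plan: _RegionPlan,
    truth: LocusTruth,
) -> tuple[list[str], list[str]]:
    """Parental source of each diagnostic event for the two crop lineages."""
    n = len(div_events)
    if mode in (MODE_ANCIENT, MODE_OR):
        src = [ROLE_OR] * n
        return src, list(src)
    if mode == MODE_ON:
        src = [ROLE_ON] * n
        return src, list(src)
    if mode == MODE_TYPE5:  # japonica from Or, indica from On
        return [ROLE_ON] * n, [ROLE_OR] * n
    if mode == MODE_TYPE6:
        return [ROLE_OR] * n, [ROLE_ON] * n
    # the coding genealogy is judged on exonic sites, so mixture/crossover
    # balance must hold on that subset as well
    exonic_idx = [
        i
        for i, ev in enumerate(div_events)
        if any(plan.in_exon(c) for c in range(*ev.span))
    ]
    subsets = [list(range(n))] + ([exonic_idx] if plan.exon_spans else [])

    def balanced(src: list[str]) -> bool:
        for subset in subsets:
            m = len(subset)
            if m < 2:
                continue
            frac = sum(1 for i in subset if src[i] == ROLE_OR) / m
            if not 0.1 < frac < 0.9:
                return False
        return True

    if mode == MODE_MIXED:
        # redraw until both parents genuinely contribute (>10% of sites in
        # every judged subset); tiny site counts pass as drawn
        src = [ROLE_OR if rng.random() < 0.5 else ROLE_ON for _ in range(n)]
        for _ in range(200):
            if balanced(src):
                break
            src = [ROLE_OR if rng.random() < 0.5 else ROLE_ON for _ in range(n)]
        return src, list(src)
    # recombinant: one crossover between two diagnostic sites; the operative
    # site list (exonic for the coding region) keeps a usable share per block
    operative = exonic_idx if (plan.exon_spans and len(exonic_idx) >= 2) else list(range(n))
    if len(operative) >= 2:
        m = len(operative)
        lo = max(1, int(np.ceil(0.15 * m)))
        hi = max(lo, m - lo)
        k = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        bp = (
            div_events[operative[k - 1]].span[1]
            + div_events[operative[k]].span[0]
        ) // 2
        left_parent = ROLE_OR if rng.random() < 0.5 else ROLE_ON
        right_parent = ROLE_ON if left_parent == ROLE_OR else ROLE_OR
        src = [
            left_parent if ev.span[0] < bp else right_parent for ev in div_events
        ]
    else:
        src = [ROLE_OR] * n
        bp = plan.length // 2
    truth.breakpoints[plan.region.value] = int(bp)
    return src, list(src)


def _plant_crop_mutations(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    plan: _RegionPlan,
    ledger: _ColumnLedger,
    anc: np.ndarray,
    i_hap: list[str],
    j_hap: list[str],
    rate_multipliers: dict[str, float],
    truth: LocusTruth,
) -> None:
    L_kb = plan.length / 1000.0
    exon_kb = sum(e - s for s, e in plan.exon_spans) / 1000.0
    region = plan.region.value
    branches = (
        (BRANCH_EARLY, cfg.phase1_rate, (i_hap, j_hap)),
        (BRANCH_INDICA, cfg.indica_rate, (i_hap,)),
        (BRANCH_JAPONICA, cfg.japonica_rate, (j_hap,)),
    )
    for branch, rate, targets in branches:
        mult = rate_multipliers.get(branch, 1.0)
        if plan.exon_spans:
            # introns stay neutral: the multiplier only raises the exon rate
            draws = [(rng.poisson(rate * L_kb), False),
                     (rng.poisson(rate * exon_kb * (mult - 1.0)), True)]
        else:
            draws = [(rng.poisson(rate * L_kb * mult), False)]
        for n, exon_only in draws:
            for _ in range(n):
                if rng.random() < cfg.indel_fraction:
                    _plant_indel(cfg, rng, plan, ledger, targets, branch, region,
                                 truth, exon_only=exon_only)
                else:
                    col = _draw_site(rng, plan, ledger, exon_only)
                    new = _other_base(rng, anc[col])
                    for hap in targets:
                        hap[col] = new
                    truth.mutations.append(
                        PlantedMutation(region, (col, col + 1), "substitution", branch)
                    )
    if cfg.recurrence_prob > 0 and rng.random() < cfg.recurrence_prob:
        col = ledger.draw_column(rng)
        alts = [b for b in BASES if b != anc[col]]
        b_i, b_j = rng.choice(alts, size=2, replace=False)
        i_hap[col], j_hap[col] = str(b_i), str(b_j)
        truth.mutations.append(
            PlantedMutation(region, (col, col + 1), "substitution", "recurrent")
        )


def _draw_site(
    rng: np.random.Generator,
    plan: _RegionPlan,
    ledger: _ColumnLedger,
    exon_only: bool,
    max_tries: int = 200,
) -> int:
    if not exon_only:
        return ledger.draw_column(rng)
    lens = np.array([e - s for s, e in plan.exon_spans], dtype=float)
    for _ in range(max_tries):
        i = int(rng.choice(len(lens), p=lens / lens.sum()))
        s, e = plan.exon_spans[i]
        col = int(rng.integers(s, e))
        if not ledger.used[col]:
            ledger.used[col] = True
            return col
    raise ConfigurationError("exons saturated: lower the mutation rates")


def _plant_indel(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    plan: _RegionPlan,
    ledger: _ColumnLedger,
    targets: Sequence[list[str]],
    branch: str,
    region: str,
    truth: LocusTruth,
    exon_only: bool = False,
) -> None:
    if exon_only and plan.exon_spans:
        lens = np.array([e - s for s, e in plan.exon_spans], dtype=float)
        i = int(rng.choice(len(lens), p=lens / lens.sum()))
        s, e = plan.exon_spans[i]
        anchor = int(rng.integers(s, e))
    else:
        anchor = int(rng.integers(plan.length))
    exon = plan.exon_containing(anchor)
    k = _geometric_len(rng, cfg.indel_mean_len)
    inframe: bool | None = None
    if exon is not None:
        if rng.random() < cfg.exon_indel_inframe_prob:
            k = max(3, 3 * int(np.ceil(k / 3)))
            inframe = True
        else:
            if k % 3 == 0:
                k += 1
            inframe = False
        lo, hi = exon
        if hi - lo < k + 2:  # exon too short; fall back to a substitution-free spot
            return
        span = ledger.draw_span(rng, k, lo=lo, hi=hi)
    else:
        span = ledger.draw_span(rng, k)
        if any(plan.in_exon(c) for c in range(*span)):
            # straddles an exon boundary: release and skip (kept simple)
            for c in range(max(0, span[0] - 1), min(plan.length, span[1] + 1)):
                ledger.used[c] = False
            return
    for hap in targets:
        for c in range(*span):
            hap[c] = "-"
    truth.mutations.append(
        PlantedMutation(region, span, "indel", branch, inframe=inframe)
    )


# ---------------------------------------------------------------------------
# Locus / dataset generation
# ---------------------------------------------------------------------------


def _gene_model(cfg: SimulationConfig, rng: np.random.Generator) -> _RegionPlan:
    n_exons = int(rng.integers(cfg.n_exons_range[0], cfg.n_exons_range[1] + 1))
    exon_lens = [
        int(rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1))
        for _ in range(n_exons)
    ]
    total = sum(exon_lens)
    exon_lens[-1] -= total % 3  # coding length must be a multiple of 3
    intron_lens = [
        int(rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1))
        for _ in range(n_exons - 1)
    ]
    exons, introns = [], []
    pos = 0
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < len(intron_lens):
            introns.append((pos, pos + intron_lens[i]))
            pos += intron_lens[i]
    return _RegionPlan(RegionKind.CODING_GENOMIC, pos, exons, introns)


def generate_locus(
    cfg: SimulationConfig, locus_index: int, rng: np.random.Generator
) -> SyntheticLocus:
    """Generate one locus: 5' and coding alignments, annotation, truth."""
    locus_id = f"L{locus_index + 1:03d}"
    chromosome = f"chr{(locus_index % cfg.n_chromosomes) + 1}"
    weights = cfg.inheritance_weights
    mode_names = list(weights)
    probs = np.array([weights[m] for m in mode_names], dtype=float)
    probs /= probs.sum()
    mode5 = str(rng.choice(mode_names, p=probs))
    modec = str(rng.choice(mode_names, p=probs))

    selected = bool(rng.random() < cfg.selected_fraction)
    new_target: tuple[str, str] | None = None
    if rng.random() < cfg.new_allele_fraction:
        new_target = (
            str(rng.choice([RegionKind.FIVE_PRIME.value, RegionKind.CODING_GENOMIC.value])),
            str(rng.choice([BRANCH_INDICA, BRANCH_JAPONICA])),
        )

    expected_affinity = {
        RegionKind.FIVE_PRIME.value: MODE_TO_AFFINITY[mode5],
        RegionKind.CODING_GENOMIC.value: MODE_TO_AFFINITY[modec],
    }
    expected_type, _ = combine_region_affinities(expected_affinity)
    truth = LocusTruth(
        locus_id=locus_id,
        chromosome=chromosome,
        modes={
            RegionKind.FIVE_PRIME.value: mode5,
            RegionKind.CODING_GENOMIC.value: modec,
        },
        breakpoints={},
        expected_affinity=expected_affinity,
        expected_type=expected_type,
        selected=selected,
        new_allele_target=new_target,
    )

    def multipliers(region: str) -> dict[str, float]:
        mult = {BRANCH_EARLY: 1.0, BRANCH_INDICA: 1.0, BRANCH_JAPONICA: 1.0}
        if selected:
            mult[BRANCH_EARLY] *= cfg.selection_multiplier
        if new_target is not None and new_target[0] == region:
            mult[new_target[1]] *= cfg.new_allele_multiplier
        return mult

    plan5 = _RegionPlan(RegionKind.FIVE_PRIME, cfg.five_prime_len, [], [])
    seqs5 = _simulate_region(
        cfg, rng, plan5, mode5, multipliers(plan5.region.value), truth
    )
    planc = _gene_model(cfg, rng)
    seqsc = _simulate_region(
        cfg, rng, planc, modec, multipliers(planc.region.value), truth
    )

    def to_oset(seqs: dict[str, list[str]], region: RegionKind) -> OrthologSet:
        sequences = {
            "Or": "".join(seqs[ROLE_OR]),
            "On": "".join(seqs[ROLE_ON]),
            "japonica": "".join(seqs[ROLE_JAPONICA]),
        }
        roles = {"Or": ROLE_OR, "On": ROLE_ON, "japonica": ROLE_JAPONICA}
        base_i = "".join(seqs[ROLE_INDICA])
        for k in range(cfg.n_indica_genomes):
            name = f"indica{k + 1}"
            seq = base_i
            if k > 0 and cfg.indica_disagreement_prob > 0:
                chars = list(base_i)
                for c in range(len(chars)):
                    if chars[c] != "-" and rng.random() < cfg.indica_disagreement_prob:
                        chars[c] = _other_base(rng, chars[c])
                seq = "".join(chars)
            sequences[name] = seq
            roles[name] = f"indica{k + 1}"
        return OrthologSet(
            locus_id=locus_id, region_kind=region, sequences=sequences, roles=roles
        )

    annotation = RegionAnnotation(
        locus_id=locus_id,
        chromosome=chromosome,
        five_prime_span=(0, cfg.five_prime_len),
        exon_spans=planc.exon_spans,
        intron_spans=planc.intron_spans,
        frame_offset=0,
        reference_role=ROLE_OR,
    )
    return SyntheticLocus(
        five_prime=to_oset(seqs5, RegionKind.FIVE_PRIME),
        coding=to_oset(seqsc, RegionKind.CODING_GENOMIC),
        annotation=annotation,
        truth=truth,
    )


def generate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    loci = [generate_locus(cfg, i, rng) for i in range(cfg.n_loci)]
    return SyntheticDataset(config=cfg, loci=loci)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------


def write_dataset(
    ds: SyntheticDataset, out_dir: str | Path, overwrite: bool = False
) -> Path:
    """Write per-locus FASTA/GFF3 files, truth tables, and a manifest.

    Output is byte-identical for a fixed config (no timestamps, sorted keys).
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise ConfigurationError(f"{out}: refusing to write into non-empty directory")
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": ds.config.seed,
        "config_hash": ds.config.config_hash(),
        "n_loci": len(ds.loci),
        "loci": [],
    }
    truth_rows = []
    locus_rows = []
    for locus in ds.loci:
        lid = locus.truth.locus_id
        ldir = out / lid
        ldir.mkdir(exist_ok=True)
        _write_fasta(locus.five_prime, ldir / "five_prime.fasta")
        _write_fasta(locus.coding, ldir / "coding.fasta")
        _write_gff(locus, ldir / "annotation.gff3")
        manifest["loci"].append(
            {
                "locus_id": lid,
                "chromosome": locus.truth.chromosome,
                "five_prime_fasta": f"{lid}/five_prime.fasta",
                "coding_fasta": f"{lid}/coding.fasta",
                "annotation": f"{lid}/annotation.gff3",
                "role_map": dict(locus.five_prime.roles),
            }
        )
        for m in locus.truth.mutations:
            truth_rows.append(
                {
                    "locus_id": lid,
                    "region": m.region,
                    "start": m.span[0] + 1,
                    "end": m.span[1],
                    "kind": m.kind,
                    "branch": m.branch,
                    "carrier": m.carrier or "",
                    "inframe": "" if m.inframe is None else str(m.inframe),
                }
            )
        locus_rows.append(
            {
                "locus_id": lid,
                "chromosome": locus.truth.chromosome,
                "mode_five_prime": locus.truth.modes["five_prime"],
                "mode_coding": locus.truth.modes["coding_genomic"],
                "expected_type": locus.truth.expected_type,
                "selected": locus.truth.selected,
                "new_allele_target": "|".join(locus.truth.new_allele_target)
                if locus.truth.new_allele_target
                else "",
            }
        )
    pd.DataFrame(truth_rows).to_csv(out / "truth_events.tsv", sep="\t", index=False)
    pd.DataFrame(locus_rows).to_csv(out / "truth_loci.tsv", sep="\t", index=False)
    agg = {
        "five_prime": ds.truth_totals("five_prime"),
        "coding_genomic": ds.truth_totals("coding_genomic"),
    }
    manifest["truth_totals"] = agg
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return out


def _write_fasta(oset: OrthologSet, path: Path) -> None:
    lines = []
    for name in sorted(oset.sequences):
        lines.append(f">{name}")
        seq = oset.sequences[name]
        lines.extend(seq[i : i + 70] for i in range(0, len(seq), 70))
    path.write_text("\n".join(lines) + "\n")


def _write_gff(locus: SyntheticLocus, path: Path) -> None:
    ann = locus.annotation
    lid = ann.locus_id
    attrs = f"locus_id={lid};chromosome={ann.chromosome};reference_role={ann.reference_role}"
    lines = ["##gff-version 3"]
    if ann.five_prime_span:
        s, e = ann.five_prime_span
        lines.append(
            f"{lid}\tggm\tfive_prime_region\t{s + 1}\t{e}\t.\t+\t.\t{attrs}"
        )
    first = True
    for s, e in ann.exon_spans:
        phase = str(ann.frame_offset) if first else "."
        first = False
        lines.append(f"{lid}\tggm\texon\t{s + 1}\t{e}\t.\t+\t{phase}\t{attrs}")
    for s, e in ann.intron_spans:
        lines.append(f"{lid}\tggm\tintron\t{s + 1}\t{e}\t.\t+\t.\t{attrs}")
    path.write_text("\n".join(lines) + "\n")
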