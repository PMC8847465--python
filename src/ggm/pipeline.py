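"""End-to-end orchestration: call -> select -> type -> duration -> reports.

The pipeline consumes a dataset manifest (JSON listing per-locus FASTA and
GFF3 files with their role maps — the layout ``synthetic_data.write_dataset``
emits) and writes the full set of tabular reports into an output directory:

* ``events.tsv`` — every mutation event with category and coding effect
* ``phase_counts.tsv`` — per locus x region temporal category counts
* ``background_rates.tsv`` — per-intron pooling behind the u estimates
* ``selection.tsv`` — per locus x phase selection calls
* ``gene_types.tsv`` + ``census.json`` — eight-way typing and its census
* ``duration.json`` — relative Phase-I duration on both region bases
* ``manhattan.tsv`` — per-chromosome mutation positions (plot-ready)
* ``summary.json`` — stage counts, config echo/hash, seed, version
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .alignment_io import (
    OrthologSet,
    RegionAnnotation,
    RegionKind,
    ROLE_INDICA,
    ROLE_JAPONICA,
    load_annotation,
    load_ortholog_set,
    write_event_table,
    write_json,
)
from .duration_model import EstimationError, estimate_duration
from .errors import ConfigurationError, GGMError
from .gene_typing import (
    GeneTypeCall,
    TypingThresholds,
    classify_locus,
    classify_region,
    diagnostic_sites,
    type_census,
)
from .mutation_genealogy import (
    CAT_EARLY,
    CAT_INDICA,
    CAT_JAPONICA,
    MutationEvent,
    call_locus,
    count_by_phase,
)
from .selection_tests import (
    PHASE1,
    PHASE2_INDICA,
    PHASE2_JAPONICA,
    BackgroundRate,
    SelectionCall,
    estimate_background_rate,
    phase2_background,
    selection_counts,
    summarize_selection,
    test_5prime,
    test_coding,
)
from .mutation_genealogy import build_branch_cds

logger = logging.getLogger("ggm")

_PHASES = (
    (PHASE1, CAT_EARLY),
    (PHASE2_INDICA, CAT_INDICA),
    (PHASE2_JAPONICA, CAT_JAPONICA),
)


@dataclass
class RunConfig:
    """Run configuration (YAML-loadable); thresholds default to the package's
    documented operating points."""

    manifest: str
    output_dir: str
    u_override: float | None = None
    theta: float = 0.9
    min_sites: int = 3
    ancient_max: int = 1
    type8_five_prime: int = 5
    type8_coding: int = 2
    outlier_iqr: float = 3.0
    exclude_loci: list[str] = field(default_factory=list)
    min_intron_bp: int = 800
    seed: int | None = None
    verbosity: int = 1

    def validate(self) -> None:
        if self.theta <= 0 or self.theta > 1:
            raise ConfigurationError("theta must be in (0, 1]")
        for name in ("min_sites", "ancient_max", "type8_five_prime", "type8_coding"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.u_override is not None and self.u_override < 0:
            raise ConfigurationError("u override must be non-negative")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def typing_thresholds(self) -> TypingThresholds:
        return TypingThresholds(
            theta=self.theta,
            min_sites=self.min_sites,
            ancient_max=self.ancient_max,
            type8_five_prime=self.type8_five_prime,
            type8_coding=self.type8_coding,
        )


def load_run_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


@dataclass
class LocusData:
    locus_id: str
    chromosome: str
    five_prime: OrthologSet
    coding: OrthologSet
    annotation: RegionAnnotation
    events: list[MutationEvent]
    transient: list[MutationEvent]


def load_dataset(manifest_path: str | Path) -> list[LocusData]:
    """Load every locus named in a dataset manifest and call its mutations."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    loci: list[LocusData] = []
    for entry in manifest["loci"]:
        lid = entry["locus_id"]
        role_map = entry["role_map"]
        oset5 = load_ortholog_set(
            base / entry["five_prime_fasta"], role_map, RegionKind.FIVE_PRIME, lid
        )
        osetc = load_ortholog_set(
            base / entry["coding_fasta"], role_map, RegionKind.CODING_GENOMIC, lid
        )
        ann = load_annotation(base / entry["annotation"], lid)
        ann.validate_frame(osetc)
        ev5, tr5 = call_locus(oset5)
        evc, trc = call_locus(osetc, ann)
        loci.append(
            LocusData(
                locus_id=lid,
                chromosome=entry.get("chromosome", ann.chromosome),
                five_prime=oset5,
                coding=osetc,
                annotation=ann,
                events=ev5 + evc,
                transient=tr5 + trc,
            )
        )
    return loci


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------


def _ungapped_kb(oset: OrthologSet, role: str, span: tuple[int, int] | None = None) -> float:
    seq = oset.sequence_for_role(role)
    if span is not None:
        seq = seq[span[0] : span[1]]
    return sum(1 for c in seq if c != "-") / 1000.0


def intron_background(
    loci: Sequence[LocusData], min_intron_bp: int = 800
) -> dict[str, BackgroundRate]:
    """Per-phase background rates pooled over qualifying introns."""
    meta: list[tuple[str, int, int]] = []
    counts = {cat: [] for _, cat in _PHASES}
    for locus in loci:
        ref_role = locus.annotation.reference_role
        ref = locus.coding.sequence_for_role(ref_role)
        for idx, (s, e) in enumerate(locus.annotation.intron_spans):
            length = sum(1 for c in range(s, e) if ref[c] != "-")
            meta.append((locus.locus_id, idx, length))
            for _, cat in _PHASES:
                n = sum(
                    1
                    for ev in locus.events
                    if ev.category == cat
                    and ev.region_kind == RegionKind.CODING_GENOMIC
                    and s <= ev.span[0]
                    and ev.span[1] <= e
                )
                counts[cat].append(n)
    rates = {}
    for phase, cat in _PHASES:
        rates[phase] = estimate_background_rate(
            counts[cat], meta, phase, min_intron_bp=min_intron_bp
        )
    rates["phase2_max"] = phase2_background(rates[PHASE2_INDICA], rates[PHASE2_JAPONICA])
    return rates


def selection_stage(
    loci: Sequence[LocusData],
    u_phase1: float,
    u_phase2: float,
) -> list[SelectionCall]:
    """5' and coding selection calls for the three phases at every locus."""
    calls: list[SelectionCall] = []
    for locus in loci:
        ref_role = locus.annotation.reference_role
        kb5 = _ungapped_kb(locus.five_prime, ref_role)
        for phase, cat in _PHASES:
            u = u_phase1 if phase == PHASE1 else u_phase2
            count = sum(
                1
                for ev in locus.events
                if ev.category == cat and ev.region_kind == RegionKind.FIVE_PRIME
            )
            calls.append(
                test_5prime(count, kb5, u, locus_id=locus.locus_id, phase=phase)
            )
            branch_events = [
                ev
                for ev in locus.events
                if ev.category == cat
                and ev.region_kind == RegionKind.CODING_GENOMIC
                and ev.coding_effect != "none"
            ]
            cds = build_branch_cds(locus.coding, locus.annotation, cat)
            calls.append(
                test_coding(
                    branch_events,
                    cds,
                    len(cds) / 1000.0,
                    locus_id=locus.locus_id,
                    phase=phase,
                )
            )
    return calls


def _in_region_scope(ev: MutationEvent, region: str, ann: RegionAnnotation) -> bool:
    """The 5' genealogy covers its whole alignment; the coding genealogy is
    built on coding sequence, so only exon-overlapping events count there
    (introns calibrate the background rate instead)."""
    if RegionKind(ev.region_kind).value != region:
        return False
    if region == RegionKind.CODING_GENOMIC.value:
        return any(ann.in_exon(c) for c in range(*ev.span))
    return True


def typing_stage(
    loci: Sequence[LocusData], thresholds: TypingThresholds
) -> list[GeneTypeCall]:
    calls = []
    for locus in loci:
        diag = diagnostic_sites(locus.events)
        region_calls = {}
        new_counts: dict[str, dict[str, int]] = {}
        for region in (RegionKind.FIVE_PRIME.value, RegionKind.CODING_GENOMIC.value):
            diag[region] = [
                ev
                for ev in diag.get(region, [])
                if _in_region_scope(ev, region, locus.annotation)
            ]
            os_count = sum(
                1
                for ev in locus.events
                if _in_region_scope(ev, region, locus.annotation)
                and ev.category in (CAT_EARLY, CAT_INDICA, CAT_JAPONICA)
            )
            region_calls[region] = classify_region(
                diag[region], os_count, thresholds
            )
            new_counts[region] = {
                role: sum(
                    1
                    for ev in locus.events
                    if _in_region_scope(ev, region, locus.annotation)
                    and ev.category == cat
                )
                for role, cat in (
                    (ROLE_INDICA, CAT_INDICA),
                    (ROLE_JAPONICA, CAT_JAPONICA),
                )
            }
        calls.append(
            classify_locus(
                locus.locus_id,
                region_calls,
                new_mutation_counts=new_counts,
                thresholds=thresholds,
                diag_by_region=diag,
            )
        )
    return calls


def gene_type_table(calls: Sequence[GeneTypeCall], loci: Sequence[LocusData]) -> pd.DataFrame:
    chrom = {l.locus_id: l.chromosome for l in loci}
    rows = []
    for c in calls:
        rows.append(
            {
                "locus_id": c.locus_id,
                "chromosome": chrom.get(c.locus_id, "."),
                "five_prime_affinity": c.region_affinity.get("five_prime", ""),
                "coding_affinity": c.region_affinity.get("coding_genomic", ""),
                "final_type": c.final_type if c.final_type is not None else "",
                "new_allele": c.new_allele,
                "recombinant": c.recombinant is not None,
                "recombinant_clean": bool(c.recombinant and c.recombinant.clean),
                "untyped_reason": c.untyped_reason or "",
            }
        )
    return pd.DataFrame(rows)


def manhattan_table(loci: Sequence[LocusData]) -> pd.DataFrame:
    """Tabular stand-in for a per-chromosome mutation-position plot."""
    rows = []
    for locus in loci:
        for ev in locus.events:
            if ev.category not in (CAT_EARLY, CAT_INDICA, CAT_JAPONICA):
                continue
            rows.append(
                {
                    "locus_id": locus.locus_id,
                    "chromosome": locus.chromosome,
                    "region": RegionKind(ev.region_kind).value,
                    "position": ev.span[0] + 1,
                    "category": ev.category,
                }
            )
    df = pd.DataFrame(
        rows, columns=["locus_id", "chromosome", "region", "position", "category"]
    )
    if len(df):
        df = df.sort_values(["chromosome", "locus_id", "position"]).reset_index(drop=True)
    return df


def duration_matrix(loci: Sequence[LocusData], region: str) -> pd.DataFrame:
    """Per-locus early/indica/japonica counts on one region basis (exonic
    events only for the coding basis)."""
    cat_col = {CAT_EARLY: "early", CAT_INDICA: "indica", CAT_JAPONICA: "japonica"}
    rows: dict[str, dict[str, int]] = {}
    for locus in loci:
        row = rows.setdefault(
            locus.locus_id, {"early": 0, "indica": 0, "japonica": 0}
        )
        for ev in locus.events:
            if ev.category in cat_col and _in_region_scope(
                ev, region, locus.annotation
            ):
                row[cat_col[ev.category]] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "locus_id"
    return df[["early", "indica", "japonica"]] if len(df) else pd.DataFrame(
        columns=["early", "indica", "japonica"]
    )


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Execute call -> select -> type -> duration and write all reports.

    Returns the run summary (also written to ``summary.json``)."""
    config.validate()
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if config.verbosity else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    logger.info("run config hash %s seed %s", config.config_hash(), config.seed)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }

    stage = "call"
    try:
        loci = load_dataset(config.manifest)
        all_events = [ev for l in loci for ev in l.events] + [
            ev for l in loci for ev in l.transient
        ]
        write_event_table(all_events, out / "events.tsv")
        counts = count_by_phase([ev for l in loci for ev in l.events])
        counts.to_csv(out / "phase_counts.tsv", sep="\t")
        summary["stages"]["call"] = {
            "n_loci": len(loci),
            "n_events": len(all_events),
            "category_totals": {
                c: int(counts[c].sum()) for c in counts.columns
            }
            if len(counts)
            else {},
        }

        stage = "select"
        if config.u_override is not None:
            u1 = u2 = config.u_override
            rate_rows = []
        else:
            rates = intron_background(loci, min_intron_bp=config.min_intron_bp)
            u1 = rates[PHASE1].u
            u2 = rates["phase2_max"].u
            rate_rows = [
                {
                    "phase": r.phase,
                    "u": r.u,
                    "total_mutations": r.total_mutations,
                    "total_kb": r.total_kb,
                    "n_introns": len(r.introns_used),
                }
                for r in rates.values()
            ]
        pd.DataFrame(rate_rows).to_csv(out / "background_rates.tsv", sep="\t", index=False)
        calls = selection_stage(loci, u1, u2)
        sel_summary = summarize_selection(calls)
        sel_summary.to_csv(out / "selection.tsv", sep="\t", index=False)
        summary["stages"]["select"] = {
            "u_phase1": u1,
            "u_phase2": u2,
            "counts": selection_counts(sel_summary),
        }

        stage = "type"
        tcalls = typing_stage(loci, config.typing_thresholds())
        gene_type_table(tcalls, loci).to_csv(out / "gene_types.tsv", sep="\t", index=False)
        census = type_census(tcalls)
        write_json(census, out / "census.json")
        summary["stages"]["type"] = census

        stage = "duration"
        duration: dict = {}
        for region in ("five_prime", "coding_genomic"):
            matrix = duration_matrix(loci, region)
            try:
                est = estimate_duration(
                    matrix,
                    region_basis=region,
                    manual_exclude=config.exclude_loci,
                    iqr_multiplier=config.outlier_iqr,
                )
                duration[region] = est.as_dict()
            except EstimationError as exc:
                duration[region] = {"status": f"insufficient loci: {exc}"}
        write_json(duration, out / "duration.json")
        summary["stages"]["duration"] = duration

        stage = "report"
        manhattan_table(loci).to_csv(out / "manhattan.tsv", sep="\t", index=False)
    except GGMError as exc:
        summary["stages"][stage] = {"error": str(exc)}
        write_json(summary, out / "summary.json")
        raise GGMError(f"stage '{stage}' failed: {exc}") from exc

    write_json(summary, out / "summary.json")
    logger.info("pipeline complete: %d loci", len(loci))
    return summary
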