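"""Read/validate per-locus ortholog alignments and region annotations; tabular I/O.

A locus enters the analysis as one aligned multi-FASTA per region (5' region and
coding/genomic region) whose records are mapped onto four genealogical roles:

* ``Or`` — wild parent A (e.g. *O. rufipogon*), exactly one genome;
* ``On`` — wild parent B (e.g. *O. nivara*), exactly one genome;
* ``indica`` — crop lineage 1, one to three genomes (a consensus is taken);
* ``japonica`` — crop lineage 2, exactly one genome.

Internal coordinates are 0-based half-open; every written table reports 1-based
inclusive positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentError,
    AlphabetError,
    AnnotationError,
    ConfigurationError,
    FrameError,
)

ALPHABET = frozenset("ACGTN-")

ROLE_OR = "Or"
ROLE_ON = "On"
ROLE_INDICA = "indica"
ROLE_JAPONICA = "japonica"


class RegionKind(str, Enum):
    FIVE_PRIME = "five_prime"
    CODING_GENOMIC = "coding_genomic"


def _norm_role(role: str) -> str:
    """Collapse indexed indica roles (indica1..indica3) onto 'indica'."""
    if role.startswith(ROLE_INDICA):
        return ROLE_INDICA
    return role


@dataclass
class OrthologSet:
    """One locus-region alignment with taxa mapped to the four roles.

    ``sequences`` maps genome name -> aligned upper-case sequence; ``roles``
    maps genome name -> role.  Indica genomes keep their input order (the
    first two are the primary genomes for consensus building, a third is a
    tie-breaker only).
    """

    locus_id: str
    region_kind: RegionKind
    sequences: dict[str, str]
    roles: dict[str, str]

    def __post_init__(self) -> None:
        self.region_kind = RegionKind(self.region_kind)
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.locus_id}: unequal sequence lengths {sorted(lengths)}"
            )
        normed = {}
        for name, seq in self.sequences.items():
            seq = seq.upper()
            bad = set(seq) - ALPHABET
            if bad:
                raise AlphabetError(
                    f"{self.locus_id}/{name}: illegal characters {sorted(bad)}"
                )
            normed[name] = seq
        self.sequences = normed
        counts: dict[str, int] = {}
        for name, role in self.roles.items():
            if name not in self.sequences:
                raise ConfigurationError(
                    f"{self.locus_id}: role map names absent record '{name}'"
                )
            counts[_norm_role(role)] = counts.get(_norm_role(role), 0) + 1
        for name in self.sequences:
            if name not in self.roles:
                raise ConfigurationError(
                    f"{self.locus_id}: record '{name}' has no role assigned"
                )
        if counts.get(ROLE_OR, 0) != 1 or counts.get(ROLE_ON, 0) != 1:
            raise ConfigurationError(
                f"{self.locus_id}: need exactly one Or and one On genome, got {counts}"
            )
        if counts.get(ROLE_JAPONICA, 0) != 1:
            raise ConfigurationError(
                f"{self.locus_id}: need exactly one japonica genome, got {counts}"
            )
        k = counts.get(ROLE_INDICA, 0)
        if not 1 <= k <= 3:
            raise ConfigurationError(
                f"{self.locus_id}: need 1-3 indica genomes, got {k}"
            )

    @property
    def alignment_length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def _by_role(self, role: str) -> str:
        for name, r in self.roles.items():
            if _norm_role(r) == role:
                return self.sequences[name]
        raise ConfigurationError(f"{self.locus_id}: no genome with role {role}")

    @property
    def or_seq(self) -> str:
        return self._by_role(ROLE_OR)

    @property
    def on_seq(self) -> str:
        return self._by_role(ROLE_ON)

    @property
    def japonica_seq(self) -> str:
        return self._by_role(ROLE_JAPONICA)

    @property
    def indica_seqs(self) -> list[str]:
        return [
            self.sequences[name]
            for name, r in self.roles.items()
            if _norm_role(r) == ROLE_INDICA
        ]

    def sequence_for_role(self, role: str) -> str:
        """Role -> sequence, indica meaning the FIRST indica genome."""
        if _norm_role(role) == ROLE_INDICA:
            return self.indica_seqs[0]
        return self._by_role(role)


@dataclass
class ConsensusResult:
    """Column-wise indica consensus with ambiguity bookkeeping."""

    sequence: str
    ambiguous_mask: np.ndarray  # bool per column; True -> transient_ambiguous
    tiebroken_mask: np.ndarray  # True where the third genome broke a 2-way tie


def consensus_indica(oset: OrthologSet) -> ConsensusResult:
    """Collapse 1-3 indica genomes into one allele per column.

    All genomes agreeing emit that state.  Otherwise the two primary genomes
    decide when they agree; when they disagree a low-coverage third genome is
    consulted only to break the tie, and a column stays ambiguous when no such
    tie-break is possible.  Ambiguous columns are excluded from fixed-mutation
    calling downstream (classified transient).
    """
    seqs = oset.indica_seqs
    n = oset.alignment_length
    ambiguous = np.zeros(n, dtype=bool)
    tiebroken = np.zeros(n, dtype=bool)
    if len(seqs) == 1:
        return ConsensusResult(seqs[0], ambiguous, tiebroken)
    primary = seqs[:2]
    third = seqs[2] if len(seqs) >= 3 else None
    out = []
    for col in range(n):
        states = [s[col] for s in primary]
        if states[0] == states[1]:
            out.append(states[0])
            continue
        if third is not None and third[col] in states:
            out.append(third[col])
            tiebroken[col] = True
            continue
        out.append("N")
        ambiguous[col] = True
    return ConsensusResult("".join(out), ambiguous, tiebroken)


# ---------------------------------------------------------------------------
# Region annotations
# ---------------------------------------------------------------------------

Span = tuple[int, int]  # 0-based half-open interval in alignment columns


@dataclass
class RegionAnnotation:
    """Feature spans for one locus, in alignment coordinates of the
    coding/genomic alignment (the 5' region normally occupies its own
    alignment and its span covers that whole alignment)."""

    locus_id: str
    chromosome: str
    five_prime_span: Span | None
    exon_spans: list[Span]
    intron_spans: list[Span]
    frame_offset: int = 0
    reference_role: str = ROLE_OR

    def __post_init__(self) -> None:
        if self.frame_offset not in (0, 1, 2):
            raise AnnotationError(f"{self.locus_id}: frame_offset must be 0-2")
        for spans, label in ((self.exon_spans, "exon"), (self.intron_spans, "intron")):
            prev_end = -1
            for start, end in spans:
                if end <= start:
                    raise AnnotationError(
                        f"{self.locus_id}: empty {label} span [{start},{end})"
                    )
                if start < prev_end:
                    raise AnnotationError(
                        f"{self.locus_id}: {label} spans overlap or are unordered"
                    )
                prev_end = end
        if self.five_prime_span is not None:
            s, e = self.five_prime_span
            if e <= s:
                raise AnnotationError(f"{self.locus_id}: empty 5' span")

    def exon_columns(self) -> list[int]:
        return [c for s, e in self.exon_spans for c in range(s, e)]

    def in_exon(self, col: int) -> bool:
        return any(s <= col < e for s, e in self.exon_spans)

    def in_intron(self, col: int) -> bool:
        return any(s <= col < e for s, e in self.intron_spans)

    def validate_frame(self, oset: OrthologSet) -> None:
        """Check that the ungapped reference coding length is a positive
        multiple of 3 after the frame offset (needs the alignment, hence a
        separate call from file loading)."""
        ref = oset.sequence_for_role(self.reference_role)
        n = sum(1 for c in self.exon_columns() if ref[c] != "-")
        n -= self.frame_offset
        if n <= 0 or n % 3 != 0:
            raise FrameError(
                f"{self.locus_id}: ungapped reference coding length {n} "
                "is not a positive multiple of 3"
            )


_GFF_FEATURES = {"five_prime_region", "exon", "intron"}


def _parse_gff_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def load_annotation(path: str | Path, locus_id: str) -> RegionAnnotation:
    """Load a RegionAnnotation from GFF3 or the documented 6-column BED dialect.

    GFF3 dialect: seqid = locus id; type in {five_prime_region, exon, intron};
    attributes carry ``locus_id`` and (on any feature) ``chromosome`` and
    ``reference_role``; the phase column of the first exon is the frame offset.

    BED dialect: chrom = chromosome name, name = ``<locus_id>|<feature_type>``,
    score column = frame offset on exon lines ('.' elsewhere).
    """
    path = Path(path)
    text = path.read_text()
    is_gff = path.suffix.lower() in {".gff", ".gff3"} or text.lstrip().startswith(
        "##gff"
    )
    five_prime = None
    exons: list[Span] = []
    introns: list[Span] = []
    chromosome = "."
    frame_offset = 0
    reference_role = ROLE_OR
    found = False
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if is_gff:
            if len(fields) < 9:
                raise AnnotationError(f"{path}: malformed GFF3 line: {line!r}")
            seqid, _src, ftype, start, end, _score, _strand, phase, attrs = fields[:9]
            a = _parse_gff_attrs(attrs)
            if a.get("locus_id", seqid) != locus_id and seqid != locus_id:
                continue
            span = (int(start) - 1, int(end))  # GFF3 is 1-based inclusive
            chromosome = a.get("chromosome", chromosome)
            reference_role = a.get("reference_role", reference_role)
        else:
            if len(fields) < 4:
                raise AnnotationError(f"{path}: malformed BED line: {line!r}")
            chrom, start, end, name = fields[:4]
            if "|" not in name:
                raise AnnotationError(f"{path}: BED name must be locus|feature")
            lid, ftype = name.split("|", 1)
            if lid != locus_id:
                continue
            span = (int(start), int(end))  # BED is already half-open
            chromosome = chrom
            phase = fields[4] if len(fields) > 4 else "."
        if ftype not in _GFF_FEATURES:
            continue
        found = True
        if ftype == "five_prime_region":
            five_prime = span
        elif ftype == "exon":
            if not exons and phase not in (".", ""):
                frame_offset = int(phase)
            exons.append(span)
        else:
            introns.append(span)
    if not found:
        raise AnnotationError(f"{path}: no features tagged with locus '{locus_id}'")
    exons.sort()
    introns.sort()
    return RegionAnnotation(
        locus_id=locus_id,
        chromosome=chromosome,
        five_prime_span=five_prime,
        exon_spans=exons,
        intron_spans=introns,
        frame_offset=frame_offset,
        reference_role=reference_role,
    )


# ---------------------------------------------------------------------------
# FASTA loading
# ---------------------------------------------------------------------------


def load_ortholog_set(
    fasta_path: str | Path,
    role_map: Mapping[str, str],
    region_kind: RegionKind | str,
    locus_id: str | None = None,
) -> OrthologSet:
    """Read one aligned multi-FASTA and attach roles.

    Every record name must appear in ``role_map``; role multiplicities are
    validated by :class:`OrthologSet`.
    """
    fasta_path = Path(fasta_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"{fasta_path}: no FASTA records")
    sequences: dict[str, str] = {}
    roles: dict[str, str] = {}
    for rec in records:
        if rec.id not in role_map:
            raise ConfigurationError(
                f"{fasta_path}: record '{rec.id}' missing from role map"
            )
        sequences[rec.id] = str(rec.seq)
        roles[rec.id] = role_map[rec.id]
    return OrthologSet(
        locus_id=locus_id or fasta_path.stem,
        region_kind=RegionKind(region_kind),
        sequences=sequences,
        roles=roles,
    )


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

EVENT_COLUMNS = [
    "locus_id",
    "region",
    "start",       # 1-based inclusive
    "end",         # 1-based inclusive
    "kind",
    "category",
    "multiplicity",
    "states",
    "derived_state",
    "coding_effect",
    "aa_change_count",
    "parent_match",
]


def _states_to_str(states: Mapping[str, str]) -> str:
    return ",".join(f"{k}={v}" for k, v in sorted(states.items()))


def _states_from_str(s: str) -> dict[str, str]:
    if not s:
        return {}
    return dict(part.split("=", 1) for part in s.split(","))


def write_event_table(events: Iterable, out_path: str | Path) -> pd.DataFrame:
    """Write the mutation-event TSV (1-based inclusive coordinates), sorted by
    (locus, position).  Returns the DataFrame that was written."""
    rows = []
    for ev in events:
        rows.append(
            {
                "locus_id": ev.locus_id,
                "region": RegionKind(ev.region_kind).value,
                "start": ev.span[0] + 1,
                "end": ev.span[1],
                "kind": ev.kind,
                "category": ev.category,
                "multiplicity": ev.multiplicity,
                "states": _states_to_str(ev.states),
                "derived_state": ev.derived_state or "",
                "coding_effect": ev.coding_effect,
                "aa_change_count": ev.aa_change_count,
                "parent_match": _states_to_str(ev.parent_match or {}),
            }
        )
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if len(df):
        df = df.sort_values(["locus_id", "start", "end"], kind="stable").reset_index(
            drop=True
        )
    df.to_csv(out_path, sep="\t", index=False)
    return df


def read_event_table(path: str | Path) -> list:
    """Parse an event TSV back into MutationEvent objects (round-trip of
    :func:`write_event_table`)."""
    from .mutation_genealogy import MutationEvent  # local import: avoids a cycle

    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    events = []
    for _, row in df.iterrows():
        events.append(
            MutationEvent(
                locus_id=row["locus_id"],
                region_kind=RegionKind(row["region"]),
                span=(int(row["start"]) - 1, int(row["end"])),
                kind=row["kind"],
                multiplicity=int(row["multiplicity"]),
                category=row["category"],
                states=_states_from_str(row["states"]),
                derived_state=row["derived_state"] or None,
                coding_effect=row["coding_effect"],
                aa_change_count=int(row["aa_change_count"]),
                parent_match=_states_from_str(row["parent_match"]) or None,
            )
        )
    return events


def write_json(obj, out_path: str | Path) -> None:
    Path(out_path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
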