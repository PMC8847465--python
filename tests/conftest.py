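"""Shared fixtures: small synthetic datasets and hand-built alignments."""

from __future__ import annotations

import pytest

from ggm.alignment_io import OrthologSet, RegionAnnotation, RegionKind
from ggm.pipeline import LocusData
from ggm.mutation_genealogy import call_locus
from ggm.synthetic_data import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 24-locus synthetic dataset under default study conditions."""
    return generate_dataset(SimulationConfig(seed=42, n_loci=24))


@pytest.fixture(scope="session")
def called_loci(small_dataset):
    """The small dataset with mutations called on every locus."""
    loci = []
    for l in small_dataset.loci:
        ev5, tr5 = call_locus(l.five_prime)
        evc, trc = call_locus(l.coding, l.annotation)
        loci.append(
            LocusData(
                locus_id=l.truth.locus_id,
                chromosome=l.truth.chromosome,
                five_prime=l.five_prime,
                coding=l.coding,
                annotation=l.annotation,
                events=ev5 + evc,
                transient=tr5 + trc,
            )
        )
    return loci


def make_set(or_seq, on_seq, i_seq, j_seq, region=RegionKind.CODING_GENOMIC,
             locus_id="LX", extra_indica=()):
    """Four-role OrthologSet from literal sequences."""
    sequences = {"Or": or_seq, "On": on_seq, "indica1": i_seq, "japonica": j_seq}
    roles = {"Or": "Or", "On": "On", "indica1": "indica1", "japonica": "japonica"}
    for k, seq in enumerate(extra_indica, start=2):
        sequences[f"indica{k}"] = seq
        roles[f"indica{k}"] = f"indica{k}"
    return OrthologSet(locus_id=locus_id, region_kind=region,
                       sequences=sequences, roles=roles)


def single_exon_annotation(length, locus_id="LX"):
    return RegionAnnotation(
        locus_id=locus_id,
        chromosome="chr1",
        five_prime_span=None,
        exon_spans=[(0, length)],
        intron_spans=[],
        frame_offset=0,
        reference_role="Or",
    )
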