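"""Region affinity ladder, recombinant detection, locus typing, census."""

import itertools

import numpy as np
import pytest

from ggm.alignment_io import RegionKind
from ggm.errors import InsufficientSignalError
from ggm.gene_typing import (
    ANCIENT,
    INSUFFICIENT,
    MIXED,
    ON_LIKE,
    OR_I_ON_J,
    OR_J_ON_I,
    OR_LIKE,
    GeneTypeCall,
    TypingThresholds,
    classify_locus,
    classify_region,
    detect_recombinant,
    diagnostic_sites,
    genome_concordance,
    type_census,
)
from ggm.mutation_genealogy import CAT_EARLY, CAT_PARENTAL, MutationEvent, call_locus
from ggm.pipeline import typing_stage

from conftest import make_set


def _diag(pos, i_label, j_label, region=RegionKind.FIVE_PRIME):
    return MutationEvent(
        locus_id="LX",
        region_kind=region,
        span=(pos, pos + 1),
        kind="substitution",
        states={},
        category=CAT_PARENTAL,
        parent_match={"indica": i_label, "japonica": j_label},
    )


def _sites(labels_ij):
    return [_diag(10 * k, i, j) for k, (i, j) in enumerate(labels_ij)]


class TestDiagnosticSites:
    def test_empty_when_no_parental_differences(self):
        assert diagnostic_sites([]) == {}

    def test_sites_ordered_and_labeled(self):
        evs = [_diag(50, "On", "Or"), _diag(10, "Or", "Or")]
        out = diagnostic_sites(evs)["five_prime"]
        assert [e.span[0] for e in out] == [10, 50]
        assert out[1].parent_match == {"indica": "On", "japonica": "Or"}


class TestClassifyRegion:
    def test_no_signal_no_mutations_is_ancient(self):
        call = classify_region([], 0)
        assert call.affinity == ANCIENT

    def test_too_few_sites_is_insufficient(self):
        call = classify_region(_sites([("On", "On")] * 2), 0)
        assert call.affinity == INSUFFICIENT

    def test_unanimous_on_matches(self):
        call = classify_region(_sites([("On", "On")] * 10), 3)
        assert call.affinity == ON_LIKE
        assert call.match_fractions["indica"]["On"] == 1.0

    def test_unanimous_or_matches(self):
        assert classify_region(_sites([("Or", "Or")] * 10), 0).affinity == OR_LIKE

    def test_or_japonica_on_indica_association(self):
        assert classify_region(_sites([("On", "Or")] * 10), 0).affinity == OR_J_ON_I

    def test_reverse_association(self):
        assert classify_region(_sites([("Or", "On")] * 10), 0).affinity == OR_I_ON_J

    def test_alternating_labels_are_mixed(self):
        labels = [("On", "Or"), ("On", "On")] * 5  # japonica alternates 5/5
        assert classify_region(_sites(labels), 0).affinity == MIXED

    def test_neither_sites_lower_stored_fractions(self):
        sites = _sites([("On", "On")] * 9 + [("neither", "neither")])
        call = classify_region(sites, 0)
        assert call.affinity == ON_LIKE  # ladder uses informative sites
        assert call.match_fractions["indica"]["On"] == pytest.approx(0.9)
        f = call.match_fractions["japonica"]
        assert f["Or"] + f["On"] <= 1.0


class TestDetectRecombinant:
    def test_canonical_single_crossover(self):
        labels = ["Or"] * 4 + ["On"] * 3
        call = detect_recombinant(labels, site_positions=list(range(0, 70, 10)))
        assert call.switch_count == 1
        assert call.breakpoint == (30, 40)
        assert call.clean

    def test_uniform_labels_not_recombinant(self):
        assert detect_recombinant(["Or"] * 5).switch_count == 0

    def test_alternating_labels_count_three_switches(self):
        assert detect_recombinant(["Or", "On", "Or", "On"]).switch_count == 3

    def test_neither_sites_become_private_mutations(self):
        labels = ["Or", "neither", "Or", "On"]
        call = detect_recombinant(labels)
        assert call.switch_count == 1 and call.private_mutation_count == 1
        assert not call.clean

    def test_insufficient_sites_raise(self):
        with pytest.raises(InsufficientSignalError):
            detect_recombinant(["Or", "neither"])

    def test_linear_scan_equals_exhaustive_minimum(self):
        """For every input up to 12 sites tested, the scan count equals the
        brute-force minimum over all parental source assignments consistent
        with the labels ('neither' sites may take either source)."""
        rng = np.random.default_rng(99)
        alphabet = ["Or", "On", "neither"]
        for _ in range(120):
            n = int(rng.integers(2, 13))
            labels = [alphabet[i] for i in rng.integers(0, 3, size=n)]
            informative = [l for l in labels if l != "neither"]
            if len(informative) < 2:
                continue
            free = [i for i, l in enumerate(labels) if l == "neither"]
            best = None
            for fill in itertools.product(["Or", "On"], repeat=len(free)):
                src = list(labels)
                for i, v in zip(free, fill):
                    src[i] = v
                switches = sum(1 for a, b in zip(src, src[1:]) if a != b)
                best = switches if best is None else min(best, switches)
            scan = detect_recombinant(labels).switch_count
            assert scan == best


class TestClassifyLocus:
    def _call(self, affinity, n=10):
        labels = {
            ON_LIKE: ("On", "On"), OR_LIKE: ("Or", "Or"),
            OR_J_ON_I: ("On", "Or"), OR_I_ON_J: ("Or", "On"),
        }
        if affinity == ANCIENT:
            return classify_region([], 0)
        if affinity == MIXED:
            return classify_region(
                _sites([("On", "Or"), ("On", "On")] * (n // 2)), 0
            )
        if affinity == INSUFFICIENT:
            return classify_region(_sites([("On", "On")]), 5)
        return classify_region(_sites([labels[affinity]] * n), 0)

    @pytest.mark.parametrize(
        "a5, acod, expected",
        [
            (ANCIENT, ANCIENT, 1),
            (ON_LIKE, ON_LIKE, 2),
            (OR_LIKE, OR_LIKE, 3),
            (MIXED, MIXED, 4),
            (OR_J_ON_I, OR_J_ON_I, 5),
            (OR_I_ON_J, OR_I_ON_J, 6),
            (OR_LIKE, ON_LIKE, 7),   # separate parental origins
            (INSUFFICIENT, ON_LIKE, 2),
            (ANCIENT, MIXED, 4),
            (MIXED, OR_LIKE, 4),
        ],
    )
    def test_region_combination(self, a5, acod, expected):
        call = classify_locus(
            "LX",
            {"five_prime": self._call(a5), "coding_genomic": self._call(acod)},
        )
        assert call.final_type == expected

    def test_untyped_when_both_insufficient(self):
        call = classify_locus(
            "LX",
            {"five_prime": self._call(INSUFFICIENT),
             "coding_genomic": self._call(INSUFFICIENT)},
        )
        assert call.final_type is None and call.untyped_reason

    def test_new_allele_annotation_thresholds(self):
        regions = {"five_prime": self._call(ON_LIKE),
                   "coding_genomic": self._call(ON_LIKE)}
        counts = {"five_prime": {"japonica": 6, "indica": 0},
                  "coding_genomic": {"japonica": 0, "indica": 0}}
        call = classify_locus("LX", regions, new_mutation_counts=counts)
        assert call.new_allele and call.final_type == 2
        assert call.new_allele_detail == [("five_prime", "japonica", 6)]
        # exactly at the cutoff is NOT a new allele (strictly more than 5 / 2)
        counts = {"five_prime": {"japonica": 5, "indica": 0},
                  "coding_genomic": {"japonica": 2, "indica": 0}}
        call = classify_locus("LX", regions, new_mutation_counts=counts)
        assert not call.new_allele

    def test_label_swap_maps_types(self, small_dataset, called_loci):
        """Swapping the wild parents maps types 2<->3 and 5<->6 and fixes 1/4."""
        swap = {1: 1, 2: 3, 3: 2, 4: 4, 5: 6, 6: 5, 7: 7, None: None}
        from ggm.pipeline import LocusData

        swapped = []
        for l in called_loci:
            s5 = make_set(l.five_prime.on_seq, l.five_prime.or_seq,
                          l.five_prime.indica_seqs[0], l.five_prime.japonica_seq,
                          region=RegionKind.FIVE_PRIME, locus_id=l.locus_id)
            sc = make_set(l.coding.on_seq, l.coding.or_seq,
                          l.coding.indica_seqs[0], l.coding.japonica_seq,
                          region=RegionKind.CODING_GENOMIC, locus_id=l.locus_id)
            ev5, _ = call_locus(s5)
            evc, _ = call_locus(sc, l.annotation)
            swapped.append(LocusData(l.locus_id, l.chromosome, s5, sc,
                                     l.annotation, ev5 + evc, []))
        base = {c.locus_id: c.final_type for c in typing_stage(called_loci, TypingThresholds())}
        flip = {c.locus_id: c.final_type for c in typing_stage(swapped, TypingThresholds())}
        for lid, t in base.items():
            assert flip[lid] == swap[t], lid


class TestConcordance:
    def _early_locus(self, small_dataset, called_loci):
        for locus, ld in zip(small_dataset.loci, called_loci):
            early = [e for e in ld.events
                     if e.category == CAT_EARLY
                     and e.region_kind == RegionKind.FIVE_PRIME
                     and e.kind == "substitution"]
            if len(early) >= 2:
                return ld, early
        pytest.skip("no locus with two early 5' substitutions in fixture")

    def test_crop_genome_carries_all_early_states(self, small_dataset, called_loci):
        ld, early = self._early_locus(small_dataset, called_loci)
        table = genome_concordance(
            {ld.locus_id: ld.five_prime.japonica_seq},
            {ld.locus_id: [e for e in ld.events
                           if e.region_kind == RegionKind.FIVE_PRIME]},
        )
        row = table[table["category"] == CAT_EARLY].iloc[0]
        assert row["concordance"] == 1.0

    def test_wild_genome_lacks_all_early_states(self, small_dataset, called_loci):
        ld, early = self._early_locus(small_dataset, called_loci)
        table = genome_concordance(
            {ld.locus_id: ld.five_prime.on_seq},
            {ld.locus_id: early},
        )
        assert table.iloc[0]["concordance"] == 0.0

    def test_planted_single_miss(self, small_dataset, called_loci):
        """An extra genome reverted at one early site scores (k-1)/k."""
        ld, early = self._early_locus(small_dataset, called_loci)
        seq = list(ld.five_prime.japonica_seq)
        col = early[0].span[0]
        seq[col] = ld.five_prime.or_seq[col]  # revert to the wild state
        table = genome_concordance(
            {ld.locus_id: "".join(seq)},
            {ld.locus_id: early},
        )
        k = len(early)
        assert table.iloc[0]["agree"] == k - 1
        assert table.iloc[0]["concordance"] == pytest.approx((k - 1) / k)


class TestCensus:
    def _calls(self, spec):
        out = []
        for i, (ftype, new) in enumerate(spec):
            out.append(GeneTypeCall(
                locus_id=f"L{i}", region_affinity={}, region_calls={},
                final_type=ftype, new_allele=new,
            ))
        return out

    def test_fractions_per_summary_bin(self):
        spec = ([(1, False)] + [(2, False)] * 2 + [(3, False)] * 2
                + [(4, False)] * 4 + [(5, True)])
        census = type_census(self._calls(spec))
        assert census["n_typed"] == 10
        assert census["bin_fractions"] == pytest.approx(
            {"ancient": 0.1, "uni_specific": 0.4, "bi_specific": 0.4, "new": 0.1}
        )
        assert sum(census["bin_fractions"].values()) == pytest.approx(1.0)

    def test_empty_census(self):
        census = type_census([])
        assert census["n_typed"] == 0 and census["bin_counts"] == {}

    def test_untyped_loci_excluded(self):
        calls = self._calls([(1, False)]) + [
            GeneTypeCall(locus_id="LU", region_affinity={}, region_calls={},
                         final_type=None, untyped_reason="x")
        ]
        assert type_census(calls)["n_typed"] == 1
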