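# Methods

## The genealogical model

A locus is a four-taxon alignment with fixed topology: two wild parent
species (roles `Or` and `On`) and two crop lineages (`indica`, `japonica`)
that share a common domesticated ancestor descended from a hybrid of the two
parents. No tree search is performed; the topology is an assumption of the
method, and every inference is a polarization of alignment columns onto its
branches. The model further assumes:

* **Infinite sites / no recurrence.** Domestication is shallow enough that
  two independent hits at one column are negligible. Columns where both crop
  lineages carry *different* novel states violate this and are flagged
  `recurrent_suspect`; they are excluded from phase counts by default.
* **Fixed mutations.** With one genome per role, agreement between the two
  crop genomes at a site gives 75% assurance of a truly monomorphic site
  under an equal-frequency binomial model (1 − (1/2)^n; 94% at n = 4,
  `monomorphic_assurance`). Transient polymorphism therefore contaminates
  end branches at a predictable, low rate.
* **One indel run = one mutation.** Adjacent gap columns with the same
  taxon-presence pattern have a single mutational origin and collapse to one
  event, whatever their length. Adjacent substitution columns with an
  identical pattern remain separate events but carry a shared multiplicity
  annotation for compact reporting.

Classification decision table (states after indica consensus): shared novel
crop state → early (Phase I); novel state in exactly one crop lineage, the
other matching a parent → that lineage (Phase II); all states parental with
Or ≠ On → parental diagnostic (with per-lineage parent-match labels);
anything unresolvable → transient. A column with `N` in any genome, or an
unresolvable indica consensus, is excluded from calling and reported as
transient — conservative, since a fixed call cannot be established there.
With up to three indica genomes, the first two decide the consensus; a third
(low-coverage in the motivating data) is consulted only to break a two-way
tie, and such columns are flagged `tie-broken`.

## Two genealogies per locus

Each locus carries a 5′ genealogy (~1 kb upstream region; can be shorter
when alignment quality demands) and a coding genealogy. The coding genealogy
is computed on coding sequence: typing counts, the Type-8 cutoffs,
diagnostic-site affinities and the coding-basis duration matrix use
exon-overlapping events only. Introns inside the same alignments serve
exactly one purpose — calibrating the neutral background rate.

## Coding effects

Substitutions are translated in their branch context: the pre-mutation codon
of a Phase-I event comes from the wild parents (the `Or` state when the
parents disagree — `On` is treated as the derived parent), and that of a
Phase-II event from the sister crop lineage, which still carries the shared
state. In-frame exonic indels record exonic-length/3 amino-acid changes;
frame-disrupting indels record the codon count to the first novel stop in
the shifted reading. The reading frame is defined on the ungapped reference
(`reference_role`, default `Or`) exon columns after the annotated frame
offset.

## Positive selection

* **Background rate u** (mutations·kb⁻¹·period⁻¹): pooled event count over
  pooled ungapped length of introns longer than 800 bp (shorter introns are
  too small to be comparable to the 5′ and coding regions). Phase II uses
  the higher of the two lineage estimates — conservative for a threshold
  test. When no intron qualifies the run must supply `u` explicitly.
* **5′ test:** positive when the per-kb rate strictly exceeds 3u
  (substitutions and indels equally). At u = 0.56 and a full 1 kb region the
  smallest positive integer count is 2. Regions shorter than 1 kb are
  compared per kb, not by raw count. Note the operating characteristics:
  under neutrality at u = 0.56 the tail P(Poisson(0.56) ≥ 2) ≈ 10.9% — the
  cutoff trades specificity for sensitivity at this shallow timescale, and
  the per-locus calls should be read as a screen, not a hypothesis test.
  No multiple-testing correction is applied across loci (none is defined for
  the screen; noted as a limitation).
* **Coding test:** NG86 fractional site counts (per codon position, the share
  of the three single-nucleotide changes preserving the amino acid; changes
  to stop codons count as nonsynonymous; no multiple-hit correction, as
  divergence ≪ 1). dN/dS > 1 when dS > 0 and no indels; otherwise ≥ 2
  amino-acid changes per kb, with frameshift/premature-stop events passing
  automatically (they alter many residues by construction).

## Gene typing

Affinity per region from parental-diagnostic sites: `ancient` (no diagnostic
signal and at most `ancient_max` = 1 crop mutation), `insufficient`
(< `min_sites` = 3 sites), then On-like / Or-like / the two
lineage–parent association patterns at match fraction θ = 0.9, else `mixed`.
θ and `min_sites` operationalize "identical or similar" — they are declared
package choices, config-exposed. Novel crop states at diagnostic sites match
neither parent: they are excluded from the ladder's fractions (computed over
informative sites) and tallied as private mutations; the stored
`match_fractions` are over all diagnostic sites, so Or + On ≤ 1 per lineage.

Locus type: agreeing regions map to types 1–6; one silent region defers to
the other; two different parental-origin affinities make Type 7; any other
disagreement Type 4. A lineage-region with > 5 (5′) or > 2 (coding)
accumulated mutations adds the Type-8 (new allele) annotation on top of the
base type; the census bins Type-8 loci under "new" and keeps the base type in
the detail table. Recombinants: the minimal number of parent switches needed
to write a lineage's allele as an Or/On mosaic equals the label-change count
over informative sites (a linear scan attains the exhaustive minimum); a
single switch with zero private mutations is a clean single-crossover
recombinant, and the breakpoint is reported as the interval between the
flanking sites.

## Duration model

Kimura's fixation probability P = (1 − e^(−4sqNₑ))/(1 − e^(−4sNₑ)); the
removable singularity at s = 0 returns q analytically, switching at
|4sNₑ| < 1e-8 for numerical stability. In a fully selfing crop Nₑ = N/2 and
q = 1/(2N), giving P ≈ 1 − e^(−s) (within 1e-6 whenever 4sNₑ ≥ 50). Expected
fixed mutations per lineage m = 2vNₑPT; under constant v, Nₑ, P across
phases these cancel in T_e/T_w = m_e/(m_e + m_lineage), which is estimated
by pooling counts over loci that accumulated at least one mutation in each
of the three periods. Loci whose lineage count exceeds Q3 + 3·IQR of the
qualifying distribution are dropped (the rule formalizes an outlier exclusion
that would otherwise be a judgement call); a manual exclusion list is also
honoured so a published locus set can be reproduced exactly. Both lineage
fractions are reported, as are both region bases (5′ and coding); fractions
print to 3 decimals and percentages to 1.

## Synthetic data generator

The generator emulates the hybrid-origin structure the method assumes: per
locus a 1 kb 5′ alignment and a 3–6-exon gene model (exons 120–360 bp,
introns 200–1600 bp so that roughly half qualify for the background pool),
wild-parent divergence at 10 substitutions/kb (~1%, ≈ 10 diagnostic sites
per kb), and per-branch mutation rates of 0.56/kb/period matching the
neutral background the selection test is calibrated against. Indels are 15%
of mutations, geometric length (mean 3), in-frame in exons with probability
0.7. 20% of loci carry a ×5 Phase-I rate multiplier on 5′ regions and exons
("selected" loci) and 10% a ×15 lineage-specific multiplier (new-allele
loci); introns always evolve at the neutral rate, because inflating them
would break the u calibration. Inheritance modes are drawn per region with
weights matching the census the method expects of a hybrid-origin crop
(6% ancient, 12/18% On/Or-like, 40% mixed, 19/2% the two association types,
3% recombinant).

Generator conventions worth knowing:

* Infinite sites is enforced by drawing columns without replacement; indel
  spans keep a one-column buffer so two planted indels can never merge into
  one event. An optional recurrence-injection flag exercises the
  `recurrent_suspect` path.
* All indels are planted as deletions (gap run in the derived carrier);
  under the event-collapsing convention an insertion in one lineage is
  indistinguishable from a deletion in all the others, so no generality is
  lost.
* Parental-divergence indels avoid exons so the reading-frame reference
  stays ungapped there; crop-lineage exonic indels are planted.
* Mixed-mode and recombinant loci re-draw their per-site parental sources
  until both parents contribute > 10% of the judged site subsets (including
  the exonic subset for the coding region); a "mixed" locus that drew all
  its sites from one parent would genuinely *be* uni-specific, which would
  make planted-type bookkeeping meaningless.
* The second and third indica genomes are copies of the first with a
  configurable per-site disagreement probability (default 0) to exercise the
  consensus machinery.

What the generator does **not** emulate: coalescent depth heterogeneity,
migration/introgression, alignment error, sequencing error, and transient
segregating polymorphism. Passing round-trip tests therefore demonstrate the
correctness of the classification algebra under the method's own
assumptions, not robustness of the method to violated assumptions on real
genomes.

## Numerical and reporting conventions

Internal coordinates are 0-based half-open; all written tables are 1-based
inclusive. Event tables sort by (locus, position); JSON output uses sorted
keys; reruns with equal inputs and configuration are byte-identical, and the
generator is byte-identical for a fixed seed. Count-based selection
thresholds use ≥ at the integer count implied by the strict > 3u rule.

## Problem sizes used in the test suite

The suite exercises 100-locus datasets for exact category recovery and
intron-rate recovery, 250 loci for gene-type recovery (≥ 99% at ≥ 5
operative diagnostic sites per region), 200 replicates per planted ratio for
duration-estimator coverage (judged as pooled nominal coverage across the
600 checks, with a 90% per-ratio floor — the exact interval's true coverage
sits at ~95–96%, so a per-ratio 95% assertion at 200 replicates would be a
knife-edge on Monte-Carlo error), 50 random coding sequences against the
brute-force NG86 oracle, and exhaustive switch-count minimization for inputs
up to 12 diagnostic sites. These sizes give stable, seed-pinned results
while keeping the whole suite under ten seconds.

## Known limitations

* The fixed four-role topology cannot express introgression between the
  crop lineages or from a third wild source; the concordance checker flags
  candidate cases instead.
* Phase-II u takes the higher lineage estimate; a strongly asymmetric
  mutation history would make the test conservative for one lineage.
* dN/dS on a branch with very few substitutions is unstable by nature; the
  amino-acid-rate fallback absorbs the dS = 0 cases but small-count noise
  remains.
* The parental polarity convention (Or state used when parents disagree at a
  Phase-I codon position) can mis-reconstruct the odd pre-mutation codon;
  it affects only the synonymous/nonsynonymous label of events at
  parental-polymorphic codons.
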