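# Methods

## The problem and the model

Degraded DNA (ancient bone, processed food, forensic traces) rarely yields
amplifiable fragments above ~150 bp, so standard ~650 bp barcodes fail
exactly where identification matters most. The mitochondrial 16S rRNA gene
offers a way out: its sequence is highly conserved across very broad
taxonomic groups except in short loop regions of the ribosomal structure,
which are variable enough to separate species. A mini-barcode marker is
therefore a pair of primer sites in two conserved blocks flanking one
variable loop, giving a primer-inclusive product of roughly 120–125 bp.

The package operationalises each step of that idea with explicit, testable
definitions; the key choices and their defaults are documented below.

## Conservation profile

For each alignment column the conservation score is the frequency of the
modal unambiguous base (A/C/G/T) among the column's non-gap characters.
Ambiguity codes stay in the denominator but never count towards the mode: an
`N` carries no conservation information and must depress, not inflate, the
score, because the score is read directly as consensus-primer mismatch risk
(a column scoring 0.95 means a consensus base mismatches ~5% of templates).
A normalised Shannon-entropy scorer (1 − H/2 bits) is available behind the
same interface. All-gap columns score 0.

Conserved blocks are maximal runs of columns with score ≥ 0.9 and gap
fraction ≤ 0.1, of length ≥ 18 (one primer length). Loops are the gaps
between adjacent blocks with length in [40, 120]; their mean score must be
strictly below both flanks'. These thresholds are this package's choices:
they make products of ~100–150 bp (two ~20–26 nt primers around a 40–120 nt
loop) discoverable, consistent with the published marker sizes; no
thresholds were published for the original design.

## Primer design

Per column of a candidate interval, the consensus code is the minimal IUPAC
code covering every base at frequency ≥ 0.10 (the minor-allele floor; the
modal base is always covered). Total degeneracy is capped at 8; above the
cap, degenerate positions fall back to their modal base starting with the
least-conserved position. A 0.10 floor balances universality against
degeneracy explosion; published universal primers do carry degenerate
positions (one `N` in the built-in set), so degeneracy is a feature, not an
error. Gap-containing columns are a design error — primers must not span
indels. Primer length bounds default to 18–27 nt, spanning the published
21–26 nt primers. Reverse primers are reported 5′→3′ (reverse complement of
the template consensus), the universal reporting convention.

There is deliberately **no melting-temperature model**: the original
protocol ran both pairs at a single annealing temperature, and flank
conservation plus degeneracy already orders candidates; a Tm model would add
parameters without adding evidence. Screening instead covers the two
failure modes that matter at this scale: primer-dimer potential (longest
contiguous antiparallel complementary run involving a 3′-terminal 10-mer;
flagged at ≥ 5) and alternative binding sites (any record with more than one
approximate site for either primer).

## Blocking oligo

A blocking oligo suppresses a known contaminant (typically human DNA in
ancient-DNA extracts). Computationally the C3 spacer is exactly the boolean
"cannot prime", carried as `blocked_3prime=True`. The designed oligo must
(i) match the contaminant exactly over its full length, (ii) overlap the
primer's binding footprint by ≥ 1 nt and extend 3′ of it into
contaminant-specific sequence (so it outcompetes the primer on the
contaminant and only there), and (iii) carry ≥ 4 mismatches against every
target record at its best ungapped placement on either strand. Among
feasible windows within 25–40 nt, the shortest then leftmost wins.
Infeasibility (e.g. a contaminant indistinguishable from targets) is a
distinct error carrying the best achieved mismatch count. The feasibility
margin (4 mismatches) and the length range are this package's choices; the
published 34-nt blocker sits inside both.

## In-silico PCR

Primer sites are found by sliding-window comparison under IUPAC matching: a
primer code matches a template code when their base sets intersect, except
that a template `N` never matches an informative primer position (an unknown
base is evidence of nothing; `N` vs `N` matches because the primer tolerates
anything there). Defaults allow 2 total mismatches per primer with a
perfect 3-nt 3′ clamp — permissive annealing as used for degraded templates,
but extension still requires a matched 3′ terminus. Products are capped at
2 kb. Every (forward site, downstream reverse site) combination is reported,
including overlapping products and both template orientations; a blocking
oligo matching the template perfectly over either primer footprint flags the
product `blocked` rather than deleting it (transparency over realism —
downstream consumers filter). Product sizes are **primer-inclusive**; this
definition reproduces the published c. 125/120 bp sizes exactly on
constructed templates (24+80+21 and 26+72+22).

## Percent identity and resolution

Identity comes from a global alignment with free end gaps (overlap
alignment): match +1, mismatch −1, linear gap −2, overhangs at either end of
either sequence unpenalised. Identity = 100 × matches / aligned columns over
the overlapping region; internal gap columns count in the denominator, end
overhangs do not. This approximates the "matching region" identity a local
aligner reports while staying fully specified: the DP fill is vectorised
row-wise, the traceback is deterministic (end cell by score, then i+j, then
i; steps prefer diagonal, then gap-in-second, then gap-in-first), and the
symmetric wrapper orders its arguments canonically so identity(a,b) =
identity(b,a) even on degenerate ties.

The resolution report gives, per species, the maximum identity to any other
species' amplicon (resolvable iff strictly below the threshold) and the
minimum identity among its own references — undefined (not 100%) for
single-reference species, to avoid overstating within-species sampling.
`fraction_resolvable` is non-decreasing in the threshold by construction.

## Identification

Replicates of one fragment are pairwise-aligned to the first; positions
where any replicate disagrees (or is deleted) are masked `N` and flagged —
replication is how degradation-induced miscalls are caught — and the
consensus is restricted to the region all replicates cover. Replicates below
80% mutual identity are irreconcilable (that is not sequencing error).

Each consensus is scored against every reference amplicon on both strands
(Sanger reads arrive in either orientation; the better strand is kept), with
query `N` columns excluded from numerator and denominator. Hits are ranked
by identity, then fewer mismatches, then reference id. One guard matters:
an overlap alignment between *unrelated* sequences degenerates to a few
perfectly matching terminal columns — "100% identity" over a meaningless
region. Hits whose aligned region covers less than half of the shorter
sequence are therefore marked uncovered, ranked last, and excluded from
tie-set consideration. This is the deterministic stand-in for the
significance filtering a heuristic local aligner applies before reporting.

A call requires top identity **strictly above 97%**. All covered hits within
0.5 percentage points of the top are considered jointly: one species →
species call; several species in one genus → genus; several genera in one
family → family; broader → unidentified. The tie margin exists because
near-ties must demote honestly rather than arbitrarily pick a species.
Fragment calls per specimen are combined by deepest agreement; a call
supported by a single identified fragment stands but is flagged, and species
disagreement between fragments demotes with a conflict note. Raising the
threshold can only move calls toward unidentified, never the reverse.

The heuristic local-alignment parameters of the original analysis (E = 10,
word size 11, gap open 5, gap extend 2) are recorded in
`minibarcode.config.BLASTN_PROVENANCE` for provenance; no E-value statistics
are computed here.

## Synthetic data

The generator emulates exactly the structure the method assumes: a root
sequence laid out as conserved blocks (40/50/40 nt, between-species
substitution probability 0.01 per column) alternating with variable loops
(80 and 72 nt, probability 0.15), with the published primer sites implanted
verbatim at the block edges and spared from mutation, so in-silico PCR
recovers products of 24+80+21 = 125 and 26+72+22 = 120 bp by construction.
Loop rate 0.15 gives realised between-species loop divergence well above the
3% the 97% threshold needs; block rate 0.01 keeps flanks conserved. Each of
the default 20 species contributes 3 reference individuals with small
within-species variation (0.002 per column) — needed for intraspecific
identities to exist at all. Species are grouped two-per-genus and six-per-
family so genus- and family-level demotion is exercised.

Damaged queries add independent substitutions (default 1% — the residual
error of a replicated, consensus-called sequence, not raw lesion density),
extra C→T transitions in the 5 terminal positions at each end (terminal
cytosine deamination, default rate 0.2), and a uniform 0–15 nt truncation
from one random end. Everything is byte-deterministic under the seed.

What the generator does **not** model: indels (alignments are gap-free, so
degapping is the identity), phylogenetically correlated substitutions (a
tree-based simulator is out of scope), position-dependent damage-rate decay,
or instrument-specific error profiles. Passing tests therefore show the
pipeline's logic is correct under the structural assumptions, not that real
libraries are as cleanly separated; real 16S libraries have indels in loops
and uneven taxon sampling, and the conservation thresholds may need
adjusting per marker.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use 20 species × 3 references
(≈280-column alignments), 50 two-fragment specimens (100 degraded queries),
and ≥ 200 random instances per brute-force oracle comparison — sizes at
which exhaustive exact computation runs in seconds to tens of seconds while
exercising every contract. All randomness flows through explicit seeds; the
CLI exposes `--seed` on stochastic commands and logs the fully resolved
configuration of every run to stderr.

## Known limitations

- Identity is ungapped-friendly but indel-heavy queries pay linear gap
  penalties; for markers with common loop indels the scoring scheme may need
  retuning.
- The dimer screen counts contiguous complementary runs only; it ignores
  bulged or interrupted duplexes and has no thermodynamics.
- The blocking-oligo target check uses best ungapped placement; a target
  with an indel near the blocker site could evade the mismatch count.
- `alternative_binding_scan` treats every approximate site as potentially
  productive; it does not model competition between sites.
- Genus and family calls depend on the taxonomy encoded in reference
  headers; with missing family fields, cross-genus ties fall through to
  unidentified rather than family.
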