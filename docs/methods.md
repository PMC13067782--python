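# Methods

## Guide design

A tiling library contains one guide per NGG PAM whose blunt cut site
(3 bp 5' of the PAM, between protospacer positions 17/18 — standard
SpCas9 geometry) falls inside the CDS, on both strands. Coordinates are
1-based and inclusive on the coding strand throughout the package; the
only exception is the BED-like region export (0-based half-open,
`start0 = start_aa − 1`, `end0 = end_aa`). `pam_pos_nt` is the leftmost
coding-strand base of the PAM window, so plus-strand cuts sit at
`pam − 3` and minus-strand cuts at `pam + 6`. The cut is attributed to
the residue whose codon contains the first nucleotide 3' of the cut; no
half-codon splitting. Protospacers overhanging the CDS ends are filled
from flanking context when provided, otherwise the candidate is dropped
and logged — the saturation accounting (records + drops = exhaustive PAM
count) is enforced by test. No off-target or uniqueness filtering is
applied: a saturating tiling library targets every site by design.
Non-targeting controls are seeded random 20-mers rejected if they occur
anywhere in the CDS-plus-flank context on either strand (a stronger and
cheaper condition than checking NGG adjacency).

## Repair-outcome and selection model

Per allele: frameshift with probability 2/3 (always disabling), in-frame
with probability 1/3 (disabling with probability `d` of the targeted
residue). Alleles are edited and repaired independently; editing
efficiency is exposed as a knob but defaults to 1. A diploid cell is
loss-of-function only when both alleles are disabled, giving
`f(d) = (2/3 + d/3)²` — exactly 4/9 at `d = 0` and 1 at `d = 1`. Cells
with at least one functional allele are treated as fully fit (no
haploinsufficiency). Loss-of-function cells reproduce with weight
`1 − s` per generation; the expected relative abundance after `T`
generations is `f(1−s)^T + (1−f)`, and the log2 of the
screened/reference ratio of these abundances is floored at −10 so that
complete dropout stays finite for smoothing.

## Forward simulator

The generator emulates: transduction at low MOI (exactly one guide per
cell) of `coverage` cells per guide (default 1000×, matching the
coverage floor such screens maintain); 21 generations of in vitro
pre-depletion (three weeks at one division/day — durations are given in
the protocol, generation times are our calibration); a split into a
screened arm (optional Poisson engraftment bottleneck, then `t_scr`
generations at `s_scr`) and a reference arm that stays at `s_ref`; and
one multinomial draw of `depth` reads per sample. Replicates share the
transduced, pre-depleted pool (as mice engrafted from one culture do)
and diverge at the bottleneck and sequencing stages.

By default genotype-class frequencies are propagated deterministically in
expectation between those stochastic stages; this isolates the signal
the scan must detect and makes analytic cross-checks exact. A
per-generation stochastic mode (`wright_fisher=True`) replaces the
deterministic propagation with Poisson branching plus a binomial
genotype split — note a constant-size resampling scheme per guide would
erase the between-guide abundance differences that the screen measures,
which is why branching is used.

What the generator does *not* emulate: immune or microenvironment
compartments, spatial growth, clonal interference, guide-specific
cutting efficiency, sequence-dependent repair-outcome spectra, PCR
jackpotting, or multi-integration cells. Passing recovery tests
therefore show that the analysis recovers implanted signal under the
stated noise model, not that it is robust to every artifact of real
screens.

### The integrin-β1-like fixture

A seeded random 2394-nt ORF (798 residues) stands in for the real CDS;
five intervals — 153–171, 248–254, 280–295, 305–314, 359–363 — are
implanted as ground-truth domains. The first (19-residue) interval is
the designated critical region and gets `d = 1.0`; the other four get
`d = 0.99`. All five are modeled as strongly disruptive because the
fixture represents a screen in which all five regions ranked highly;
near-saturating `d` also keeps every domain in the separation regime of
the permutation test (see below), which is what makes the fixture a
usable positive control at desk-scale permutation counts. Default
screen conditions: `s_scr = 0.3`, `s_ref = 0`, `t_scr = 20`,
coverage 500, depth 10⁶, 99 controls.

## Guide and gene scoring

Frequencies use a pseudocount of 0.5 (`(count + 0.5) / (colsum +
0.5·n_guides)`); replicate pairs are matched by replicate index; each
pair's raw lfc is centered on the median control lfc, and per-guide lfc
is the mean over pairs (replicate-level variance is preserved rather
than pooling counts). The robust z standardizes against the control lfc
distribution via median and MAD (×1.4826). With no controls the
centering falls back to the all-guide median with a warning; with fewer
than 8 controls the MAD falls back to all guides. When the control MAD
is exactly zero (degenerate identical columns) the denominator is
floored at 1e-12, so identical screened/reference columns give z = 0
rather than 0/0. Testing is one-sided for depletion.

Gene scores are the median guide z with a null built from B seeded
draws of same-size control-guide sets, `p = (1 + #{null ≤ obs})/(B+1)`,
BH-adjusted across genes. This is deliberately *not* an α-RRA/MAGeCK
re-implementation — it is a simple, calibrated consumer for simulated
multi-gene screens. Two calibration caveats are inherent to the design
and documented because they shape how uniformity should be checked:
(i) all genes in a run share one empirical null sample, so their
p-values carry a common ECDF distortion of order `1/√B` — marginally
each p is uniform, but a goodness-of-fit test pooled within a single
run will reject spuriously; check calibration across independent runs.
(ii) the control pool is self-standardized, adding an `O(1/n_controls)`
anti-conservative bias that is negligible for control sets of a few
hundred.

## Residue track, permutation null, and region calls

Smoothing is Gaussian-kernel Nadaraya–Watson with default bandwidth
h = 5 residues (chosen to average a handful of guides at typical NGG
density while keeping the shortest implanted domain, 5 residues,
resolvable); residues with kernel support below 0.25 are masked. The
null shuffles the z-vector over the fixed guide positions — preserving
guide spatial density — and the one-sided empirical p at each residue is
`(1 + #{null ≤ obs})/(B+1)`, hence floored at `1/(B+1)`. Adjacent
residues share kernel windows, so p-values are strongly autocorrelated
along the protein with decorrelation length ≈ 3h; any uniformity check
must thin at that spacing.

Region calling BH-adjusts p over supported residues, keeps residues with
adjusted p ≤ α (default 0.05), merges significant residues whose
coordinates differ by at most `max_gap` (default 2: one intervening
non-significant residue is bridged, two are not), and drops regions
shorter than `min_len` (default 3 — the shortest implanted domain is 5
residues, so the default cannot preclude it). Region score is the mean
smoothed signal over the span, region p the minimum member adjusted p,
rank by score ascending.

A structural property worth knowing: with B permutations the smallest
achievable per-residue p is `1/(B+1)`, so BH at level α over m supported
residues can reject **only** when at least `m/(α(B+1))` residues sit at
that floor (≈53 residues for B = 300, α = 0.05, m ≈ 790). Detecting a
single short region at small B is therefore impossible by construction;
either B must scale with `m/α`, or — as in the bundled fixture — enough
truly depleted residues must exist to clear the floor-count threshold.
The neutral false-positive rate is unaffected (BH under the global null
controls family-wise error ≈ α).

Consensus across screens intersects intervals pairwise (strictest
reading; union mode available); recovery against simulation truth uses
inclusive-interval Jaccard, with recall counted at Jaccard ≥ 0.5.

## Reproducibility

All randomness flows from a single integer seed through named
`SeedSequence` substreams (design / sim / score / scan / fixture), so
changing one stage's parameters never perturbs another stage's draws.
Pipeline artifacts (library, counts, truth, scores, track, regions, BED,
metrics, manifest) are written with fixed float formatting and LF
endings; identical config + seed reproduce them byte-identically. Test
and demonstration problem sizes (hundreds of guides, depth 10⁵–10⁶,
B = 200–500, 20-seed neutral batteries) were chosen so the whole suite
runs in seconds on one CPU while keeping every statistical check at
sound effective sample sizes.
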