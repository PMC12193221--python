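# Methods

`hrmid` is a desk-scale reconstruction of a PCR-HRM (high-resolution
melting) workflow for identifying necrophilous fly species from short
mitochondrial DNA barcodes (COXI/COXII fragments). It covers the in-silico
parts of that workflow: scoring aligned barcode panels for conserved primer
flanks, screening primer candidates, predicting amplicons, simulating melt
curves and calling their peaks, and assigning unknown melt signatures to
species against a reference Tm panel. The wet-lab steps (extraction,
amplification, the instrument itself) are represented only by deterministic
bench calculators.

## The identification model

HRM species identification rests on one observation: amplicons that differ
in sequence melt at measurably different temperatures. An unknown sample is
amplified alongside a panel of reference species with the same primer pair,
and its melt-peak temperature is compared with each reference:

* |ΔTm| < 0.15 °C → the sequences are treated as identical (same species);
* |ΔTm| ≥ 0.15 °C → distinct sequences.

The 0.15 °C figure is the scale of an isobond substitution (A·T→T·A or
G·C→C·G), the smallest sequence change that still shifts Tm; the instrument
resolves ±0.02 °C. The boundary case — a separation of exactly 0.15 °C —
is not defined by the rule's two published halves ("exceeds" / "less
than"); we resolve it as *distinct*, which keeps the ten-species COXII
panel's closest fully-resolved pair (76.73 vs 76.88 °C) species-specific.
Comparisons happen after rounding to 0.01 °C (half the instrument
resolution), with a 1e-9 guard against float representation noise.

`TmPanelClassifier` reports *every* reference within the threshold of the
query's principal (highest) peak. One candidate is a `match`; several are
`ambiguous` — deliberately surfaced rather than resolved by panel order or
suppressed, because two references 0.03 °C apart genuinely cannot be
distinguished by this assay. No candidate is `novel`. In `full_signature`
mode a reference must also present the same number of peaks (each matching
within the threshold after sorting); a principal-peak match with a peak-count
mismatch is flagged `partial_signature` — the situation of a single-peak
unknown against a three-peak reference signature.

There is no likelihood model: the published decision rule is a hard
threshold, and the classifier implements exactly that. Inter-run Tm drift
(0.02–0.10 °C between repeat extractions in the bundled panels) is handled
only by a warning (`batch_consistency_guard`) recommending co-amplified
references; no drift correction is attempted.

## Reference panels are data

The bundled panels (`hrmid.panels`) are measured instrument values for ten
necrophilous fly species under two primer sets (a 97 bp COXII target and a
278 bp COXI target), plus a repeat run and a larva-identification run. The
nearest-neighbor thermodynamic predictions in `hrmid.thermo` are *never*
calibrated against them — dye, buffer and ramp-rate effects shift absolute
instrument Tms by amounts this toolkit does not model. Only ranks and Tm
differences of the NN predictions are contractual.

## Nearest-neighbor thermodynamics

`nn_thermo` sums unified nearest-neighbor stack enthalpies/entropies
(`santalucia1998_unified`, 1 M NaCl reference) plus terminal initiation
terms, applies the entropic monovalent-salt correction
0.368·(N−1)·ln[Na⁺], and evaluates the two-state Tm

    Tm(K) = ΔH·1000 / (ΔS_salt + R·ln(C_T/x)),  R = 1.987 cal/(mol·K),

x = 4 for non-self-complementary duplexes, x = 1 with a −1.4 cal/(mol·K)
symmetry entropy for self-complementary ones. Defaults: C_T = 2.5e-7 M,
[Na⁺] = 0.05 M; both, and the table id, are embedded in every result.
Sequences shorter than 8 nt are rejected (outside the two-state regime of
interest). The published HRM rules of thumb (≈6 °C for losing a G-C pair,
≈0.6 °C for G·C→A·T, ≈0.15 °C for an isobond swap) ship as read-only
documentation constants and are exercised only as order-of-magnitude
property checks — for ~100 bp amplicons the NN model predicts much smaller
shifts than the single-pair-loss heuristic, and no reconciliation is
attempted.

## Melt-curve simulation

Each melting transition is a two-state logistic helicity
h(T) = 1/(1+exp((T−Tm)/w)); the curve is a weighted sum of transitions plus
a baseline and optional white Gaussian noise on a 0.01 °C grid over the
65→90 °C ramp window. Multi-peak signatures are simulated as mixtures of
transitions with no claim about the physical origin of the extra
transitions in real amplicons.

The default transition width is w = 0.25 °C. Two considerations fix it:
the van 't Hoff width R·Tm²/|ΔH| of a ~100 bp amplicon (ΔH ≈ −760
kcal/mol) is ≈0.3 °C, and the derivative peak of a logistic has FWHM ≈
3.5w, so components ~1 °C apart — which the instrument distinguishes — are
resolvable at w = 0.25 but physically merge into a single maximum at
w = 0.5. Van 't Hoff mode computes w per component from a supplied ΔH.

## Derivative computation and peak calling

The derivative (−dF/dT) uses Savitzky–Golay smoothing (window 51 points =
0.51 °C, cubic) followed by central finite differences over a ±0.1 °C
stencil. Adjacent-point differences on a 0.01 °C grid are useless under
noise: Savitzky–Golay filters pass high-frequency noise nearly
unattenuated, and differencing amplifies it by 1/Δ. The wide stencil
divides that amplification by 10 while leaving peak positions unbiased
(symmetric error).

Peak calling is two-stage:

1. **Counting.** Local maxima of a further-smoothed copy (window 21,
   quadratic) that reach 5% of the global maximum in either prominence or
   height. Prominence alone under-scores a real transition on the shoulder
   of a larger neighbour (its prominence is measured only down to the
   saddle); height alone would admit offset artifacts. Candidates within
   0.1 °C of a higher one are merged away — the instrument never reports
   peaks that close.
2. **Validation and refinement.** A joint least-squares fit of two-state
   derivative shapes A·sech²((T−Tm)/2w) at the candidate positions, on the
   lightly-smoothed derivative. The fit refines each Tm to well inside the
   ±0.02 °C instrument resolution (raw argmax jitter under noise is an
   order of magnitude worse). Components fitted with amplitude below 5% of
   the largest, or width below 0.08 °C (narrower than any real amplicon
   transition), are pruned as noise. If the smoothed fit residual shows a
   bump above 8% of the largest amplitude and 7 robust sigma — away from
   window edges — a missed transition (a shoulder swallowed by the counting
   smoother) is added and the mixture refit, at most twice.

Measured performance of the full simulate → derivative → call chain at
noise SD 0.002 (about 0.2% of a unit-weight transition): over 900 random
trials with k ∈ {1,2,3} components, pairwise separations ≥ 1 °C and weights
in [0.2, 1], the peak count was exact in all but one trial and the worst Tm
error was 0.011 °C.

**Known limits.** A component outweighed ~5:1 by a neighbour at a
separation near 1 °C can still merge (the one stress failure above). At
noise SD 0.005 the residual-addition step occasionally (≈3%) promotes a
side lobe into a spurious peak; below 0.004 this was not observed. Peak Tms
are reported at grid resolution; heights/prominences refer to the smoothed
counting curve (fitted amplitude for residual-recovered peaks).

## Conservation profiling and primer screening

Column identity is the modal A/C/G/T fraction among non-gap residues;
ambiguity codes count as mismatches and any gap disqualifies a column from
conserved calls (primers cannot span indels — the amplified region shows
length polymorphism between species). Defaults demand perfect identity
(min_identity = 1.0) over ≥ 18 columns, the minimum primer length; the
thresholds are exposed because no numeric definition of "highly variable"
exists in the source protocol. Conserved and variable calls partition the
columns.

Primer screening follows short-amplicon HRM practice: length 20 ± 2 nt, GC
40–60%, product ≤ 300 bp (long products accumulate polymerase errors that
blur melt peaks, and degraded specimens amplify poorly beyond ~300 bp).
Hairpin/self-dimer checks use longest-complementary-run rules (stem ≥ 4
with loop ≥ 3; inter-molecular run ≥ 8; 3′-anchored run ≥ 5) rather than
thermodynamic folding — the screening intent is qualitative exclusion, and
the run rules are transparent and exactly testable. All failures are
reported, not just the first. Degenerate bases are rejected outright.

In-silico PCR allows a per-primer mismatch budget but demands an exact
match over the 3′-terminal 5 bases (a mismatched 3′ end does not extend);
amplicons span the forward 5′ base through the reverse 5′ base, so the
97 bp product length includes both primer footprints. All products of all
site pairs are returned; no product is an empty list, not an error.

Pair enumeration walks all window pairs across two conserved regions whose
product spans at least one variable region, screens both oligos, and sorts
by ascending product length, then by descending summed |GC−0.5| of the two
oligos.

## Synthetic data

`synth_barcodes` emulates the conserved-flank/variable-core structure of
the COXII target: an ancestral sequence drawn uniformly over ACGT, flanks
(default 20 nt) shared verbatim by all species, and each core site mutated
independently per species with probability `core_divergence` to a uniformly
chosen different base. Two species then differ at a core site with
probability q = 2p(1−p) + (2/3)p², which the tests check the generator
against. Defaults (20 + 57 + 20 = 97 nt) mirror the real product size.

What the generator does *not* emulate: phylogenetic correlation between
species (mutations are independent, not tree-structured), indels,
transition/transversion bias, codon structure, and within-species
polymorphism. Passing tests therefore demonstrate the machinery —
conservation calling, primer enumeration, Tm separation, classification —
under a clean null model, not performance on real mitochondrial data. The
bundled COXII-like template used by the in-silico PCR tests is likewise a
labelled synthetic stand-in (random sequence carrying the real primer
footprints at the real 97 bp spacing), not the GenBank record.

## Bench calculators

The 20 µL reaction fixes master mix (10), primers (1+1), dye (1) and a 7 µL
template+water budget. The template rule loads max(2, ⌈10 ng / conc⌉) µL —
the ≥10 ng requirement is read as total nanograms in the reaction, which is
what the published worked example (3.83 ng/µL → 3 µL + 4 µL water)
arithmetically implies — at whole-microlitre pipetting granularity, with
water absorbing the adjustment so every reaction totals exactly 20 µL.
Extracts below ~1.43 ng/µL cannot reach 10 ng within the budget and raise
an infeasibility error suggesting re-extraction. The thermocycler program
is fixed (95 °C 10 min; 35 × [95 °C 30 s, anneal 30 s, 72 °C 45 s]; 72 °C
10 min; HRM stage with the 65→90 °C ramp); only the annealing temperature
varies per primer set (53 °C for the COXII pair, 48 °C for the COXI pair),
validated to 40–72 °C.

## Problem sizes used in the test suite

The suite's statistical checks run at desk scale: 1,000 random sequences
(8–200 nt) for the thermodynamics oracle comparison, 50-seed round-trip
peak-recovery sweeps with k ≤ 3, a 200-trial end-to-end identification run
on a 10-species synthetic panel spaced 0.4 °C apart at noise SD 0.002, and
Monte-Carlo generator checks over 100 seeds. The full suite completes in
well under a minute.
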