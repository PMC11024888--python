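# Methods

This note documents the models, rules and numerical choices behind
`gslprof`, and what its synthetic benchmarks do and do not demonstrate.

## Mass model

All arithmetic is monoisotopic. Atomic masses: H 1.0078250319, C 12
(exact), N 14.0030740052, O 15.9949146221, P 30.97376151, S 31.97207069
Da. Charged species use the electron-corrected proton mass 1.00727646 Da
per charge, so m/z of an adduct is
`(M + mass(added atoms) + z·1.00727646)/z`, where [M+NH₄]⁺ adds NH₃ plus
a proton and [M+2NH₄]²⁺ adds 2 NH₃ plus two protons. At one printed
decimal the proton-mass convention is invisible, but ppm-level precursor
matching requires it, so it is fixed here once. Printed-value
comparisons round half-up, matching how m/z tables are typeset.

Compositions are non-negative element→count maps over {C,H,N,O,P,S};
subtraction below zero is an error rather than a silent negative,
because a composition always denotes a real molecular fragment.

## Structure space

A long-chain base dC:db (2 hydroxyls) or tC:db (3) has free-base
composition C_nH_{2n+3−2db}NO_{oh} — sphingosine d18:1 is C18H37NO2.
The N-acyl is counted as its free fatty acid C_nH_{2n−2db}O_{2+oh}, and
amide condensation removes one water. Headgroups add glycan residues
(Hex 162.0528, HexNAc 203.0794, Fuc 146.0579, Neu5Ac 291.0954 Da as
dehydrated residues) and modification deltas (sulfate +SO₃, phosphate
+HPO₃, phosphocholine +C5H14NO4P−H₂O, O-acetyl +C₂H₂O, lactone −H₂O).

The enumerator applies the human-biosynthesis constraint box to the
combined ceramide: 32–44 total carbons, 2–3 free hydroxyls (the amide
oxygen is not counted), ≤ 3 double bonds, over the five human LCBs.
Hydroxyl/double-bond limits are interpreted on the whole lipid rather
than per chain, which is what makes the printed minor-LCB list (d/t,
0–2 double bonds) come out as a subset. Acyl chains run over even *and*
odd carbon counts: even-chain dominance is a biological prior best
handled by scoring, not by exclusion. This yields 325 ceramides;
crossed with the 18-entry default catalog, 5 850 structures.

Ganglioside nomenclature is composition-based (GM1 = 3Hex·1HexNAc·
1Neu5Ac on ceramide, GD/GT/GQ adding Neu5Ac); a/b-series isomers share a
mass and are represented by `sialic_positions` (Neu5Ac on the terminal
vs the first core galactose), not by duplicate rows. The catalog ships
as an editable CSV. Headgroups whose composition is not established
(e.g. the GA0 retention class) are left to user-supplied rows; the RRT
table still carries their class values.

## CID fragment rules

Fragmentation is modeled at the monosaccharide-composition level — no
linkage topology — because the diagnostic ions of these compounds are
compositional:

* **B ions**: every residue sub-multiset of the glycan up to 4 residues,
  m/z = Σ residues + proton; Neu5Ac-containing B ions get a −H₂O
  companion, and O-acetylated structures an +42.0106 variant.
  Composition-level enumeration over-generates slightly relative to true
  topology (e.g. a {2Hex} ion for a branched glycan); since scoring is a
  matched-weight fraction and the synthetic spectra use the same rules,
  this costs nothing in the benchmarks and is conservative on real data.
* **Y ions**: the protonated precursor minus terminal residues, removed
  fucose-first, then sialic acids, then the core from the nonreducing
  end; successive Y ions differ by exactly one residue mass.
* **Lipid ions**: [Cer+H]⁺ with one and two water losses, and the LCB
  pair. Unsaturated or tri-hydroxy LCBs give [LCB+H−H₂O]⁺/[LCB+H−2H₂O]⁺;
  the saturated dihydroxy base (d18:0) is reported as
  [LCB+H]⁺/[LCB+H−H₂O]⁺ (302.3/284.3) — its dehydration products would
  be isobaric with the sphingosine ions, and the intact protonated base
  is the ion that stays diagnostic.
* **Headgroup diagnostics**: phosphocholine 184.073 for SM, combined
  H₂O+SO₃ loss for sulfatides, and the intact water loss.

Diagnostic weights encode qualitative dominance: ceramide/LCB and
headgroup diagnostics 1.0, B ions 0.8, Y ions 0.6, water losses 0.4,
fucose B ions 0.2 (fucose survives CID poorly as an oxocarbenium but its
neutral loss is prominent). The weights are configurable; only their
ordering matters for the decisions the annotator takes. The O-methyl
Neu5Ac table value in circulation is inconsistent with a +14.0157
methylation and is deliberately not reproduced; `glycan_b_ion` supports
O-acetyl only.

## Retention model

RRT is a compound's retention time divided by the sphingomyelin
anchor's: the SM species with the matching ceramide when one is
identified in the run, else the run's most abundant SM. The class table
(SM 1.000, Hex 0.987, … GQ1 0.700) is shipped as CSV. The RRT tolerance
defaults to ±0.015, half the smallest printed inter-class gap
(GM2 0.833 vs SLac 0.822); the run-to-run variability of RRT is not
quantified in the underlying data, so this is a deliberate judgment
recorded here. Within a (headgroup, LCB) family, retention is linear in
acyl carbon number; the fit is ordinary least squares (`scipy.stats.
linregress`) over ≥ 3 distinct chain lengths, and predictions more than
6 carbons outside the fitted range carry a far-extrapolation flag.
Elution-order rules: more hydroxyls ⇒ earlier, more double bonds ⇒
earlier, and d18:1/FA:1 elutes before d18:2/FA at equal totals.

## Feature finding

EICs take, per centroided MS1 scan, the most intense peak within the ppm
window of each target (dense matrices are processed in chunks of 2 000
targets to bound memory). Peaks are local maxima above 1 000 counts
(the acquisition-threshold default, ≈ 2× baseline noise), with bounds
where the trace falls below 10 % of apex or a valley begins; a 5 %
rise tolerance per scan keeps centroid noise from truncating a flank.
Area is the trapezoidal integral — robust to sampling density, which is
why area rather than apex height is the abundance measure. Adducts of
one compound are grouped greedily by area within a 0.2 min co-elution
window; equivalence to any specific vendor feature-finder is functional
(recovery of synthetic truth), not algorithmic.

## Scoring and disambiguation

The 0–20 composite score is this package's analog of a commercial
library score, calibrated so that complete evidence reaches 20 and the
familiar ≥ 10 acceptance cutoff keeps its meaning: fragments contribute
10 × (matched diagnostic weight / total weight) at 50 ppm, precursor
5 × (1 − |ppm|/25), RRT 5 × (1 − |ΔRRT|/0.015), each floored at zero.

One structure per physical peak: the best-scoring annotation claims all
member features of its group; a lower-scoring annotation whose apex sits
on a claimed peak (same m/z at 25 ppm, within max(0.3 min, co-elution
window)) is dropped. The widened claim radius matters because a
near-isobar window offset by ~20 ppm sees a gap-riddled copy of the same
peak whose apparent apex shifts by a few scans — the characteristic
failure mode of CH₄-vs-O near-isobars (Δ 36.4 mDa), which fall inside
25 ppm for doubly charged gangliosides. Exact score ties are reported
with a `tie` flag, never broken silently.

In-source artifacts are removed when a co-eluting, larger, accepted
parent explains the candidate's mass by SO₃ or single-Neu5Ac loss, the
candidate is off its own expected RRT, and its area is ≤ 1 % of the
parent's (the source-optimization ceiling); a candidate scoring at its
own RRT is never removed. PC/PE contaminants are vetoed by the 184.073
fragment with an even-nominal precursor (integer part of m/z — the
lipid mass defect stays below +1 Da in this range) and by the 141.019
neutral loss. Precursor-only homologs are rescued by the acyl-chain fit
when ≥ 3 confident family members exist and the observed RT is within
0.7 min of prediction — except candidates sitting on peaks already
explained by an accepted identification, which are never rescued.

## Sialidase differencing

The digest rule: α2-3,6,8-neuraminidase removes Neu5Ac from the terminal
galactose; Neu5Ac on the first core galactose is sterically protected
(hence the fully desialylated core is never observed). `digest_product`
applies one such step and is idempotent; lactonized or O-acetylated
sialic acids are conservatively treated as resistant. Series letters
follow core-sialic count (a/b/c = 1/2/3).

Assignment cannot be done one structure at a time when gangliosides
share a ceramide — GT1b feeds the GD1 pool while GD1a drains into GM1 —
so `assign_series` fits all (core, terminal) configuration combinations
of a matched-ceramide group jointly: each combination's predicted
treated pools (single-step digest, cleaved share moved to the product)
are compared with the observed ones by summed squared log-ratio, and a
structure is assigned only when every near-optimal combination agrees.
Admissible configurations keep ≥ 1 core sialic acid (the biosynthetic
root) and ≤ 3 on the core. A global activity gate precedes everything:
if no pool anywhere shifted by the fold-change threshold (default 2.0,
with a +1 count floor against division by small numbers), the digest is
considered uninformative and all assignments are `undetermined`;
conversely, under a demonstrably active enzyme an *unchanged*
multi-sialyl pool is positive evidence of all-core linkage.

## Synthetic runs

The generator emulates the acquisition this workflow targets, with
defaults chosen once as study conditions: a 70 min gradient sampled
every 0.05 min; the SM anchor eluting at 45 min; Gaussian peaks of
σ = 0.15 min; compound retention = class RRT × (anchor + 0.08 min per
acyl carbon from C18) + N(0, 0.04 min) jitter; m/z jitter 2 ppm;
2 % intensity noise; 30 uniform noise peaks per scan at 550–2 000 m/z
below the 1 000-count threshold; adduct splits of 90/10
[M+H]⁺/[M+NH₄]⁺ for SM and small glycolipids, 40/45/15 over 1+/2+ for
GM, and fully doubly charged mixtures for GD/GT/GQ. MS2 spectra are the
predicted fragment lists with weight-proportional log-normal
intensities plus uniform noise peaks. Optional in-source artifacts
place the sulfate- or sialic-loss mass at the parent's retention time
at 0.8 % of its area; the 40-compound benchmark profile is a brain-like
mixture dominated by SM/GM1/GD1 with d18:1/C18–C20 lipids plus minor
LCBs, hydroxylated/long acyls and polysialylated species. Replicate
simulation draws per-compound multiplicative log-normal noise with
σ² = ln(1+cv²) and mean-one correction. Everything is a deterministic
function of the seed; mzML output is centroided, 64-bit, uncompressed,
written (and read back) by the package's own minimal standard-conformant
mzML module.

What passing these benchmarks shows: the arithmetic, rules and decision
logic are internally consistent and recover a known truth under
realistic tolerances, including designed failure modes (decoys at +5 Da,
CH₄/O near-isobars, cross-adduct mass collisions, in-source artifacts).
What it does not show: robustness to profile-mode data, isotopic
envelopes, chimeric MS2, ion suppression, retention drift between runs,
or real chromatographic peak shapes — none of which the generator
models. Problem sizes (40-compound runs, 5 850-structure database, 50
replicates) were chosen as the smallest that exercise every rule with
comfortable statistics.

## Degenerate inputs and tie-breaks

Empty LCB sets, empty databases, all-zero abundance columns, replicate
groups of one, and gangliosides without sialic-position annotations are
errors, not warnings. CSV importers report the offending line; a
formula/mass disagreement beyond 25 ppm warns but loads. Enumeration,
database export and simulation are order-deterministic, so identical
inputs produce byte-identical files.
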