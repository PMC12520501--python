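# Methods

## The observable

Hairpin bisulfite sequencing covalently links the two strands of one DNA
molecule before conversion, so a single read pair reports the methylation
state of both cytosines of a symmetric dyad. Four dyad types are handled:

| context | Watson anchor at `pos` | Crick partner | note |
|---------|------------------------|---------------|------|
| CG      | `pos`                  | `pos+1`       | palindromic |
| CWG     | `pos` (W = A/T)        | `pos+2`       | palindromic CHG |
| CWWG    | `pos` (two W bases)    | `pos+3`       | palindromic CHH pair; CTAG is the modelled subcontext |
| CCG     | `pos`                  | `pos+2`       | reverse complement is CGG (not CHG), tallied apart from CWG |

A CSG site (S = C/G) nests a CG dyad inside a CCG/CGG trinucleotide: C1
(CHG context) and C2 sit consecutively on one strand, C3 on the other,
with C2–C3 forming the CG dyad and C1–C3 the CCG dyad. C3 is shared by
both dyads, which couples the three cytosines' fates.

Coordinates are 0-based, intervals half-open; a dyad's position for
binning is its Watson anchor. Each observed dyad on a molecule is `full`
(M,M), `hemi_watson` (M,U), `hemi_crick` (U,M), `unme` (U,U), or
`unresolved` when either call is missing; unresolved calls never enter
counts. Conflicting duplicate calls at one cytosine of one molecule are
treated as missing.

## Aggregation and the quantities modelled

Per-dyad frequencies are computed only at dyads with resolved coverage
≥ 5; 1-kb bin values are unweighted means of per-dyad frequencies
(a pooled-count mode exists as an option). For a bin,

- `P_full`, `P_hemi`, `P_unme` — mean dyad-status frequencies,
- `P_total = P_full + P_hemi/2` — per-cytosine methylation frequency.
  Because replication hands every methylated cytosine to one daughter as
  a hemi dyad, `P_total` is also the initial hemi-methylation frequency
  right after the fork passes.
- maintenance efficiency `y = P_me / P_total` with `P_me = P_full` — the
  fraction of inherited marks restored to full methylation by observation
  time.

Bins with `P_total < 2.5%` are flagged (not deleted) and excluded from
model fits and curves, as their frequencies are noise-dominated.

## The stochastic null and the Exp/Theo ratio

If every cytosine were methylated independently with its bin's `P_total`,
a dyad would be full with probability `P_total**2`. The Exp/Theo ratio is
the observed `P_full` over that expectation; bins are grouped by
`P_total` (default: 10 equal-width groups over [0.025, 1]) and both sides
are dyad-count-weighted group means, so uneven methylation across bins
does not masquerade as maintenance. `log2` of the ratio is 0 under purely
stochastic deposition and positive when hemi dyads are specifically
converted to full.

## Maintenance-efficiency models

Two models are fitted to (x = `P_total`, y = efficiency) points by
minimising mean squared error:

- saturation (Michaelis–Menten-like): `y = E_max * x / (k_m + x)` —
  H3K9me2-depleted regions, where hemi dyads act as substrate and the
  enzyme is in excess. `E_max` is the maximum maintenance efficiency,
  `k_m` the affinity scale.
- linear: `y = E_base + k_p * x` — H3K9me2-enriched regions, where the
  enzyme is limiting and efficiency rises with methylation density.
- identity `y = x` is the stochastic limit (two independent de novo
  events); `stochastic_limit_check` compares the free linear fit and the
  forced identity model on the same points.

Numerical choices: the saturation objective is non-convex in `k_m`, so
ten Nelder–Mead starts spread over a log grid (`k_m` in [1e-4, 0.5],
two `E_max` starts) with bounds `E_max ∈ [0, 1.05]`, `k_m ∈ (1e-5, 1]`;
the 1.05 cap keeps boundary estimates diagnosable rather than silently
clipped, and estimates above 1 are logged. The linear fit is closed-form
least squares. Efficiency values are never clipped before fitting —
sampling noise legitimately pushes y above 1 and clipping would bias
`E_max` down. Points are unweighted by default (dyad-count weighting is
an option). Fits require ≥ 10 points spanning ≥ 2 distinct x values.

## DMR calling

Per 1-kb bin, per-dyad full (fDMR) or hemi (hDMR) frequencies over dyads
covered ≥ 5× in both samples are compared with a paired two-sided t-test
and a Mann–Whitney U test; Benjamini–Hochberg FDR is applied within one
(context, kind) family; a bin is a DMR when both adjusted p-values are
below alpha = 0.05. The conjunction is the conservative reading of using
both tests; a disjunction mode exists. Bins with fewer than 3 shared
dyads are reported untested. A zero-variance paired difference leaves
the t-test undefined and the decision falls to the U test. Bins where
the second sample is completely unmethylated are additionally called when
they hold > 10 shared dyads and the absolute change exceeds 0.30
("complete loss"). Called DMRs are classified by delta signs: Group 1
both down, 2 full down/hemi up, 3 full up/hemi down, 4 both up; a zero
delta is unassigned. CSG content per DMR counts CCG plus CGG matches on
the Watson strand, overlapping matches individually.

## Strand analyses

`proximal_status` classifies, for every hemi focal dyad on a molecule,
the nearest resolved neighbour dyad of the requested context on the same
molecule (ties resolve to the left; the default search range is the whole
molecule, as hpBS fragments are ≤ 200 bp): hemi with 5mC on the same
strand as the focal mark (`hemi_same`), on the opposite strand
(`hemi_oppo`), `full`, or `unme`. Pairs are pooled over (site ×
molecule), not averaged per site.

`conditional_pearson` codes CSG triplet states M=1/U=0 and, for each
pair of cytosines, computes Pearson r within the subset where the third
cytosine is fixed U or M; subsets smaller than 30 observations or with a
constant vector are undefined (NaN), never coerced to 0.

## Nucleosome profiles

`center_profile` averages a sparse per-position signal by offset from
nucleosome centers (default window ±1000 bp, step 10 bp; offsets are
step-width buckets so sparse dyads are not discarded), with optional
max-to-1 normalisation. The full/hemi ratio per offset and its Pearson r
against occupancy (computed across offsets of the averaged profiles; a
per-nucleosome mode is the documented alternative) quantify whether
nucleosomes impede the hemi→full conversion. Context density profiles
count dyad anchors per offset, normalised to mean 1. Stratified
correlations assign each center to the low/high stratum of its containing
1-kb bin (H3K9me2 thresholds: low ≤ 0.1, high ≥ 5; other marks high ≥ 2).

ChIP tracks are averaged into 1-kb bins by length-weighted means; when an
input/control track is supplied, bins above 2× its genome-wide mean are
blacklisted and drop out of all downstream statistics.

## The synthetic methylome generator

The generator emulates what the analyses assume about the biology, at the
point where the real pipeline's alignment ends (it emits aligned call
tables; FASTQ and alignment are out of scope):

1. **Genome** — i.i.d. weighted base sampling (default A/T 0.3, C/G 0.2
   over 200 kb), so expected motif densities follow in closed form from
   the weights; an always-unmethylated spike-in chromosome (lambda
   analog) is appended for conversion-rate estimation and excluded from
   dyad discovery.
2. **Chromatin** — contiguous heterochromatic blocks (default 40% of
   bins, 50-kb blocks) with H3K9me2 drawn high (5 + Exp(4)) versus low
   (Exp(0.06)); nucleosome centers at 180-bp spacing with ±10 bp jitter.
3. **Methylation (replication mode)** — per molecule a template strand is
   chosen uniformly; template cytosines carry 5mC with probability
   `q(context, region)`; each dyad whose template member is methylated
   has its nascent member methylated with probability
   `E(context, region) × s` where `s` (default 0.7) applies when the
   nascent cytosine lies within 73 bp of a nucleosome center — shielding
   multiplies maintenance only, not de novo; remaining unmethylated
   cytosines gain de novo 5mC with probability `d`. A single
   replication + maintenance + de novo pass per molecule approximates
   the population snapshot the experiment takes. Independent mode
   methylates every cytosine i.i.d. with `q` — the stochastic null.
4. **Observation** — unmethylated cytosines read converted with
   probability `conversion_rate` (default 0.995, a conventional library
   value, configurable), methylated cytosines read converted with
   `overconversion_rate` (0.002), and calls go missing with `miss_rate`.
   `emit_unlinked_fragments` instead splits each molecule into two
   strand records sharing coordinates but no molecule id — the iSA input.

Default parameters (per context, euchromatic/heterochromatic): q =
0.15/0.85 (CG), 0.04/0.50 (CWG), 0.01/0.10 (CWWG), 0.04/0.50 (CCG);
E = 0.93/0.88 (CG), 0.87/0.80 (CWG), 0.05 (CWWG), 0.20/0.30 (CCG);
d = 0.005 except CWWG 0.02. These reproduce the field's qualitative
facts: CG most methylated with full > hemi, CWG intermediate, CWWG
dominated by hemi marks from essentially de novo deposition, and CSG
maintenance through the CHG pathway inefficient. Heterochromatic E
values sit where the linear efficiency model puts them at high
`P_total`; CWWG maintenance is near zero so CTAG full methylation
requires two independent events. Fragment lengths are uniform in
[100, 200] bp (sonication range).

Because C3 belongs to two dyads, maintenance can reach it through either
the CG or the CCG pathway (probabilities combine as a union). This
coupling is deliberate — it generates the conditional correlation
structure among C1/C2/C3 — and it means "every hemi 5mC lies on the
template strand" holds exactly for CG/CWG/CWWG dyads (and for all dyads
when the CCG pathway is off), while CSG-nested dyads can acquire
nascent-strand marks through the sibling pathway.

`lineage_spread` (default 0, i.e. off) scales the template strand's q by
1 ± spread per molecule, a one-parameter stand-in for replication
history: a parental strand inherited its marks as a unit, so same-strand
cytosines are correlated beyond what region-level parameters induce.
Without it a single-pass simulation cannot show the same-strand C1–C2
correlation exceeding the cross-strand C1–C3 one.

A count-level sampler (`simulate_binned_dyads`) draws per-dyad status
counts directly from (`p_full = y·P_total`, `p_hemi = 2(P_total −
p_full)`, `p_unme`) at the 1-kb-bin scale. Calibration studies over
thousands of bins (stochastic-null calibration, model parameter
recovery, DMR error rates) use it; molecule-level structure is
irrelevant there and simulating it would add nothing but runtime. The
sampler requires `y ≥ max(0, 2 − 1/P_total)` for a consistent status
distribution, which bounds the usable `P_total` range for low-efficiency
configurations (the recovery study draws `P_total` from [0.03, 0.65],
valid for all its configurations).

### What the generator does not emulate

No sequencing errors beyond the conversion model, no PCR duplicates, no
multi-generation lineage simulation (the lineage factor summarises it),
no real genome sequence composition (motif densities are i.i.d., real
genomes cluster CpG content), no RdDM targeting structure, and no
coupling between H3K9me2 level and nucleosome density. Passing tests
therefore show the estimators and models are correct and calibrated
under the stated generative assumptions — not that those assumptions
exhaust real hpBS-seq data.

## Benchmark study sizes

The desk-scale studies in `hemimeth.benchmarks` use: caller equivalence
on a 100-kb genome with 5,000 molecules; stochastic-null calibration on
5,000 bins × 45 dyads (the Arabidopsis CG-dyad density per kb) at 15×;
saturation recovery over E_max ∈ {0.6, 0.8, 0.93} × k_m ∈ {0.007, 0.05}
with 20 replicate fits of 5,000 bins × 20 dyads at 15×; DMR calibration
on 1,000-bin samples (5 null replicates, one 30-point-drop power run);
strand/CSG studies on 100-kb C/G-balanced genomes with 20,000 molecules;
iSA on 5,000 molecules; shielding on 300 kb × 30,000 molecules × 4
replicate populations, correlating over a ±90-bp window (half the
nucleosome spacing, so offsets are independent) at 2-bp steps. The
shielding correlation is reported as the mean over replicates because a
single averaged profile's null Pearson r has standard deviation
~1/sqrt(n_offsets) regardless of sequencing depth.

## Known limitations

- The complete-loss DMR rule interprets "> 30% change" as an absolute
  frequency difference, the natural reading when the mutant is at zero.
- iSA pairs coordinate-duplicate fragments arbitrarily (min(#W, #C)
  pairs per coordinate group); real collisions can thus produce chimeric
  pseudo-molecules, exactly as in the real procedure.
- The Exp/Theo theoretical value uses each bin's estimated `P_total`
  squared; at very low methylation the estimator's variance biases the
  theory up slightly, which is why the 2.5% filter and grouped averaging
  matter.
- Fits pool all molecules of a sample (merged counts); replicate-level
  fitting would need per-replicate call tables and is not implemented.
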