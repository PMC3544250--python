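# Methods

## The breeding model

The package models a marker-assisted backcross (MABC) programme that moves a
single target QTL (*Saltol*, rice chromosome 1) from a donor line into a
recipient elite cultivar while recovering the recipient genome everywhere
else.  A diploid genome is a pair of haplotypes per chromosome, each an
ordered list of maximal ancestry segments (recipient or donor) on 0-based
half-open bp intervals.  Published marker coordinates are 1-based inclusive,
as SSR tables print them; conversion between the two conventions happens in
exactly one place, at genotyping.

**Meiosis.**  Per chromosome, the crossover count is Poisson with mean equal
to the map length in Morgans and crossover positions are uniform in physical
coordinates; the gamete starts from a fair-coin parental haplotype and
alternates at each crossover.  This is the Haldane (no-interference) model:
the recombination fraction between two loci d Morgans apart is
r = ½(1 − e^(−2d)).  Haldane was chosen over Kosambi because it is the
simplest defensible model with a closed form that unit tests can check
directly; crossover interference would slightly reduce double-crossover
rates but does not change the genome-fraction expectations the tests rely
on.

**Genetic map.**  No genetic map accompanies the marker table, so the map is
linear in physical position at a global rate of 4.0 cM/Mb, the order of the
rice genome-wide average (~1500 cM over ~380 Mb); the rate is configurable
globally or per chromosome.  Chromosome lengths are likewise not published;
the shipped default is a 12-chromosome table of rice-like pseudo-chromosome
lengths (chr1 = 45 Mb, total 379 Mb).  All tests pin these defaults.

**Genotyping.**  A plant is scored at a marker as A (both haplotypes
recipient), B (both donor) or H (heterozygous); calls can be independently
dropped to missing with probability `missing_rate` (default 0 — the source
programme reports no missing data; the knob exists for robustness tests).

## Selection tiers

Each backcross generation crosses every advanced parent to the recipient
(`pop_size` progeny per parent, default 300 — the programme reports selecting
from populations of 300–478 plants without per-generation sizes, so 300 is a
configuration default, not a reported value) and applies:

1. **Foreground**: keep plants heterozygous at *every* foreground marker
   (defaults RM493 and RM3412b, both tightly linked to the target).  Missing
   disqualifies (conservative).
2. **Recombinant**: keep plants homozygous recipient (A) at the generation's
   flanking marker — RM10825 (distal) in BC1, RM10694 (nearest proximal) in
   BC2/BC3.  The published recombinant-marker lists differ between sections
   of the source description; the defaults follow the explicit
   RM10825/RM10694 rule, and the schedule is configurable per generation.
3. **Background**: rank candidates by %R over the background panel (missing
   calls excluded per plant), ties broken by %A descending then plant id
   ascending (the tie-break is this package's choice — no rule is published
   — and makes the ranking deterministic), and advance the top
   `n_parents_advanced` (default 2).

**Fixed-marker dropping.**  Background markers whose call is A in all
advanced plants of a generation are dropped from later screening and carried
in a *fixed ledger*; ledger markers count as A in all later %A/%R.  Counting
the ledger keeps BC2/BC3 percentages comparable to BC1 (otherwise dropping
recipient-fixed markers would deflate later estimates); missing calls are
uninformative, never evidence of fixation.

**Halting.**  A generation in which any tier leaves zero survivors halts the
campaign with a diagnostic naming the generation and tier, rather than
silently resampling: an empty tier signals a configuration pathology (or,
for recombinant selection at small population sizes, genuine bad luck — at
the defaults the chance is ≈0.3% per campaign) that the caller should see.
The acceptance script logs and excludes any halted seed from its median.

## Recovery statistics

For n_A, n_B, n_H non-missing calls of each class,

    %A = 100 · n_A / (n_A + n_B + n_H)
    %R = 100 · (n_A + ½ n_H) / (n_A + n_B + n_H)

%R is the standard allele-counting recovery ("percent recipient alleles,
heterozygotes at half weight"); the source names but never writes the
formula, so the allele-counting definition is stated here prominently.  The
bp-weighted ground truth `true_rpg` (recipient allele-bp over 2× genome
size) is the simulator-side oracle; marker %R converges to it as marker
density grows, which a test checks at 48 vs 480 markers.

The %R histogram uses right-open bins (last bin closed at 100) of default
width 2.5 percentage points (the published frequency figure does not state
its bin width).

## Graphical genotypes

Inter-marker intervals are coloured from their two flanking calls: both A →
recipient; any B → donor; otherwise any H → heterozygous introgression;
chromosome ends take their single nearest marker's class, missing calls drop
out of the flanking logic, and a chromosome with no informative marker
renders as unknown.  This interval rule is a package design choice (the
graphical-genotyping software used in the field does not document its exact
rule).  The text rendering (`.` recipient, `#` donor, `+` heterozygous, `|`
marker tick) keeps at least one glyph per interval so it parses back to the
exact classification.

## Duncan's multiple-range test

A one-way ANOVA error mean square feeds Duncan's least significant ranges
R_p = q(1 − α_p; p, df)·√(MSE/n_h) with protection level
α_p = 1 − (1 − α)^(p−1) over the span p of each ordered-means comparison
(n_h = harmonic mean group size; critical values from scipy's studentized
range).  Groups inside a non-significant stretch share a letter; letters are
then named in order of first appearance over the input group order, the
convention of agronomic tables where the first row is 'a'.  With two groups
the decision reduces to a comparison against R_2 (= the LSD).  Zero error
variance separates all unequal means and merges equal ones.

The packaged agronomic comparison fixture uses 3 replicates per line
(analyses "performed at least thrice") with symmetric offsets ±0.637 about
the published plant-height means (107.5, 101.2, 110.3, 106.5 cm), giving
LSD(0.05) ≈ 1.2 cm.  That spread is chosen so the letter display — the
published qualitative outcome, a/b/c/a: the two introgression lines
indistinguishable from the recipient except IL-30's taller stature, the
donor clearly shorter — is internally consistent; the replicate-level field
data themselves are not published, so the means are inputs, not reproduced
outputs.

## Synthetic data vs real data

The simulator reproduces the *statistical* structure of a backcross
programme: segregation, linkage under a linear genetic map, the three-tier
selection funnel, and the resulting recovery distributions (unselected
BC_nF_1 mean %R of 75 / 87.5 / 93.75; selected best plants ≥99.2–100%).  It
does not emulate: real marker informativeness (every shipped background
marker is polymorphic by construction — it models the 89 polymorphic of 477
screened, an 18.7% polymorphism rate, as a fixed panel), genotyping error,
segregation distortion, crossover interference, or any phenotype.  Passing
tests therefore certify the pipeline's arithmetic and selection logic, not
field performance of any real line.

The 89-marker background panel is synthetic and deterministic: allocation
proportional to chromosome length with at least four markers per chromosome
(the published coverage guideline), even spacing, and the 10.5–16.5 Mb
target window on chromosome 1 excluded so background markers stay unlinked
to the target.  A fixed panel (rather than re-thinning at 18.7% per run)
keeps panel composition out of the Monte-Carlo variance.

## Numerics, determinism, problem sizes

All randomness flows from one `numpy` Generator seeded in the campaign
configuration; the draw order is documented in `simulate_gamete` (per
chromosome: starting haplotype, crossover count, positions).  Identical seed
and configuration reproduce byte-identical outputs, which a test asserts.
Percentages printed to one decimal round half-up, matching how such tables
are typically printed.  The SSR-span audit uses exact rational arithmetic
(`Fraction`), so inconsistent rows — e.g. RM562, whose printed 45-bp span
of a 3-bp motif implies 15 repeats, not the printed 13 — are flagged, never
silently corrected.

Default analysis sizes — 300 progeny per parent per generation, 20 seeds for
the headline median, 1000 plants for neutral-expectation checks — run the
whole suite in well under a minute of simulation time while keeping
Monte-Carlo standard errors small relative to every tolerance tested.

## Known limitations

- The linear cM/Mb map ignores recombination suppression near centromeres;
  local recovery estimates around such regions would be optimistic.
- Selfed generations (BC_nF_2 and beyond) are out of scope; all statistics
  are on BC_nF_1 plants, where donor-homozygous calls are impossible.
- The salinity yield-loss utility implements only the linear threshold rule
  (no loss below 3 dS/m, 12% per dS/m above); at 6 dS/m this gives 36%,
  whereas a separate literature figure of "up to 50%" at the same salinity
  circulates — the linear rule is the one implemented.
- Duncan's test assumes a completely randomized design with (near-)balanced
  replication; unequal group sizes are handled via the harmonic mean, an
  approximation.
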