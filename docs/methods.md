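# Methods

## Model and assumptions

`homesite` analyses two-donor microbiota competition experiments: a native
and a non-native donor fecal community are mixed and inoculated into
germ-free recipient mice, and recipient communities are profiled by 16S
amplicon sequencing (ASV tables) at one or more weeks post-inoculation.

The core quantity is the Local Adaptation Index of a recipient profile *A*:

    LAI(A) = sim(A, D_nat) − sim(A, D_non),   LAI ∈ [−1, 1]

`sim` is Jaccard similarity on presence/absence sets (default; presence =
count ≥ `detection_min`, default 1) or Bray-Curtis similarity on relative
abundances. The sign convention is fixed so that *positive LAI means the
recipient is more similar to its native donor*; equivalently LAI is the
similarity difference, not the distance difference — the distance-based
form has the opposite sign and would invert every downstream
interpretation, so the similarity form is the one implemented.

The neutral null holds that colonisation outcome is set entirely by
propagule pressure. Each donor contributes `load × mass` total 16S copies
(load in copies per gram from qPCR, mass in grams of feces mixed); the
native donor's share is

    w = L_nat·m_nat / (L_nat·m_nat + L_non·m_non),

and the per-ASV assembly probabilities are the load-weighted blend of the
donors' relative-abundance profiles, `p_i = w·p_i^nat + (1−w)·p_i^non`.
A simulated neutral recipient is a multinomial draw of the observed read
depth from *p* — sampling **with** replacement, because donor pellet cell
numbers (~10^8–10^11 copies) vastly exceed read depths, making the
inoculum an effectively infinite pool. Loads are treated as point
estimates (technical qPCR replicates averaged upstream); load uncertainty
is not propagated, and per-taxon 16S copy-number variation is ignored
(load is total copies, not cells).

Assumptions worth stating plainly:

* donor profiles are taken as the sequenced compositions — the null is
  conditional on the observed donor tables, with no measurement-error
  model for the donors themselves;
* mice are exchangeable replicates within a group; cage structure is
  handled only where the tests use per-cage means;
* weeks are analysed independently and never pooled within a mouse
  (pseudoreplication guard).

## Statistical procedures

**Group tests.** Per inoculum × genotype × week, a two-sided one-sample
Wilcoxon signed-rank test asks whether LAI (and separately, observed −
expected LAI) is centred away from zero. Zeros are dropped before ranking
(classical procedure); the exact null distribution is used for n ≤ 25 with
untied absolute values, otherwise the normal approximation with continuity
correction. Benjamini-Hochberg correction is applied across groups within
one statistic family (all LAI tests together, all deviation tests
together), mirroring per-figure correction granularity.

**Per-ASV selection.** For each ASV with mixture probability > 0, each
evaluable mouse is a Bernoulli trial: success iff its observed relative
abundance exceeds (positive direction) or falls below (negative direction)
the neutral expectation. The one-sided exact binomial test uses null
success probability p0 = 0.5 — the sign-test null: under neutrality and a
continuous abundance distribution a mouse is equally likely to land on
either side of its expectation. p0 is exposed as a parameter. Ties
(typically observed = expected = 0) count as failures, which is
conservative for selection calls. ASVs absent from a recipient are
evaluable with observed abundance 0, and at least 3 evaluable mice
(configurable) are required. BH correction runs across ASVs within each
direction; `selected` means q < 0.05 by default. By default the final
collection week enters these tests (configurable).

**Genotype dependence** is a two-stage screen reproducing the two
significance modes of the selection analysis: stage one flags ASVs with
discordant unadjusted binomial evidence (p < 0.05 in one genotype, ≥ 0.05
in the other); stage two compares per-cage mean deviations (observed −
expected relative abundance averaged within cage — the cage, not the
mouse, is the experimental unit, since cage mates share environment and
coprophagy) between genotypes by a two-sample Wilcoxon rank-sum test,
BH-corrected across flagged ASVs. At least 2 cages per genotype are
required; exact rank-sum null for small untied samples.

**Enrichment** of selection calls between two ASV classes (native-only vs
non-native-only origin, or taxon A vs B) uses Pearson's chi-square on the
2×2 table without Yates correction, switching to Fisher's exact test when
any expected cell is below 5 (mode `auto`). Shared and unassigned-origin
ASVs are excluded from native-vs-non-native enrichment but retained in
per-ASV testing with origin recorded.

**Distance decay.** All unordered sample pairs (within-line pairs at
t = 0) are fit to `S = a·exp(−b·t)` by nonlinear least squares on the
similarity scale, initialised from the OLS regression of log S on t. R² is
1 − SS_res/SS_tot on the similarity scale; the p-value is an F-test of the
two-parameter model against the constant mean. Pairwise distances share
samples and are not independent; like the conventional presentation, the
default fit ignores this, and a permutation p-value (pair-level label
permutation — an approximation, not a full sample-level Mantel scheme) is
available as an alternative. No asymptote term is fitted (a `+c` term is
not identifiable from the short divergence range typical of these
designs); residual diagnostics are left to the caller. A negative fitted
decay rate triggers a warning rather than an error.

**Rarefaction** subsamples without replacement (multivariate
hypergeometric), the standard choice for presence/absence comparability.
Whether LAI inputs are rarefied to a common depth is exposed as a pipeline
flag (`rarefy_depth`) rather than hard-coded, since presence-based
measures are depth-sensitive but the appropriate depth is study-specific;
the neutral expectation is instead depth-matched per recipient, which
addresses the same artifact from the null-model side.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `detection_min` | 1 | reads | an ASV is present iff ≥ 1 read (after any rarefaction) |
| `n_reps` (expected LAI) | 1000 | simulations | SE of the mean LAI ≈ sd/√n; stable to < 0.01 at typical depths |
| `p0` | 0.5 | — | sign-test null for the binomial caller |
| `min_mice` | 3 | mice | smallest cohort with a non-trivial binomial tail |
| `q_threshold` | 0.05 | — | BH FDR level for `selected` / genotype dependence |
| `alpha_flag` | 0.05 | — | unadjusted screen level of the genotype two-stage procedure |
| depth policy | per-recipient | reads | each recipient's null is simulated at its own observed depth; a fixed common depth is configurable |

Expected-LAI simulations default to one simulation set per
inoculum × depth × metric, shared by recipients sequenced to the same
depth (equivalent to per-recipient depth matching, cheaper when depths
coincide).

## The synthetic-data generator

`synthetic_data` generates complete studies: two donors with partially
overlapping ASV sets (default 150 ASVs per donor, 10% shared), log-normal
relative abundances (σ = 2.0, a standard steep rank-abundance shape),
loads log-uniform over 10^8–10^10 copies/g, 25 mg of feces per donor,
and cohorts of recipients (default 20 mice in 5 cages per genotype, read
depth 5 000, sampled at week 4). Recipient assembly probabilities are

    q_i ∝ [w·p_i^nat + (1−w)·p_i^non] · s_i(genotype) · c_i(cage)

with s a per-ASV multiplicative selection factor (s = 1 neutral; selection
acts multiplicatively on assembly probabilities, the simplest model
consistent with per-lineage fitness advantages — a logit-additive
alternative was considered and left out of scope) and c a per-cage
log-normal effect shared by cage mates. Cage effects default to off
(σ_cage = 0): the default configuration is the exact null of the pipeline's
tests, and cage effects are opt-in structure for cage-structured designs
(the genotype-dependence analyses in this package's own validation use
σ_cage = 0.3, a mild shared-cage perturbation). All randomness flows from
one seed through spawned, never-reused child streams, so recipients are
independent and studies are reproducible bit-for-bit.

**What the generator deliberately does not emulate.** Donors are defined
by their sequenced profiles: recipients assemble from the donors' observed
compositions, so there is no donor measurement-error layer between truth
and the pipeline's neutral expectation. Real data carry that extra layer —
the donor table is itself one multinomial realisation of the pellet — and
shared error in the expectation makes the per-ASV binomial trials
positively dependent across mice, inflating its false-positive rate above
nominal. Calibration results on synthetic data therefore certify the
inference given the donor profiles, not robustness to donor-profile noise
(deep donor sequencing is the practical mitigation). Also not simulated:
read-level sequencing error, chimeras, PCR bias, and longitudinal
within-mouse dynamics (weeks are independent draws).

**LAI is propagule-pressure-bounded.** With loads drawn independently over
two decades, a sizeable minority of generated studies give one donor a
≥ 5:1 copy-number majority. In such studies even a strong (s = 5) native
fitness advantage cannot make presence/absence LAI positive — the
recipient still contains mostly non-native ASVs — although the
observed-minus-expected deviation recovers the effect essentially always.
This is the behaviour that motivates the neutral correction in the first
place, and it is why directional expectations about raw LAI hold reliably
only for load-balanced mixtures (w ≈ 0.5).

## Validation scales

The test suite and `scripts/acceptance.py` validate at these problem
sizes, chosen to give tight Monte-Carlo error at interactive runtimes:
exact-oracle checks on 1 000 random profiles and all binomial (k, n ≤ 30);
exhaustive multinomial enumeration on universes ≤ 6 ASVs at depth ≤ 5
against 10 000-replicate Monte-Carlo; neutral calibration on 100–200
generated studies of 20 recipients at depth 5 000; effect recovery on
50–100 studies with s = 5 and a 3 × 3 power grid over
s ∈ {1, 2, 5} × cohort size ∈ {6, 12, 20}; genotype-dependence recovery on
40–100 two-genotype studies (6 cages × 4 mice per genotype); decay-fit
recovery over 100 noisy datasets of 100 pairs.

## Known limitations

* No load-uncertainty propagation and no donor measurement-error model
  (see above); both are natural extensions.
* Jaccard LAI is sensitive to sequencing depth through the presence rule;
  use the rarefaction flag or the Bray-Curtis metric when depths vary
  widely.
* The decay fit does not correct for pseudoreplication of shared samples
  in pairwise distances; its default p-value is anti-conservative to an
  unknown degree and the permutation alternative is approximate.
* Source attribution itself (Bayesian source tracking) is out of scope;
  `source_log_ratio` only summarises externally supplied source fractions.
* The binomial caller's p0 = 0.5 null is exact only when observed
  abundances are continuous; at very low expected counts discreteness
  makes both directions conservative (ties count as failures).
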