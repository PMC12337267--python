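# Methods

## Pedigree model

A pedigree is a directed acyclic graph of parent–offspring links with
per-individual metadata (sex; origin local / translocated / natural
migrant; donor population and release year for translocated birds; birth
and last years). *Founders* are individuals without recorded parents:
residents present when monitoring began, occasional natural migrants, and
all translocated birds (their source pedigrees are unobserved). All genetic
computation assumes founders are non-inbred and mutually unrelated; every
quantity is therefore conditional on the observed pedigree and understates
any inbreeding or coancestry that predates monitoring.

Individuals must carry 0 or 2 parents. A *half-founder* (one recorded
parent) is completed with a synthetic unknown founder (`SYN-` id prefix,
pooled with nontranslocated founders). This preserves the recorded parent's
transmission path rather than discarding the individual; the count of
completions is reported after every build. Sire/dam sex inconsistencies
warn rather than fail, since sex is sometimes unrecorded. Processing order
is a deterministic topological sort (Kahn's algorithm, ties broken by id),
so all recursions and simulations are reproducible given the input.

Founders are partitioned into *founder groups*: one group per donor
population plus a pooled `nontranslocated` group holding original residents
and natural migrants (a switch promotes migrants to their own group).
Translocation *cohorts* are the founders sharing a release year and donor.

## Exact pedigree algebra

The additive relationship matrix A is built by the tabular method in
topological order: `A[i,j] = (A[j,s] + A[j,d])/2` for previously placed j,
`A[i,i] = 1 + A[s,d]/2` with s, d the parents. Pedigree inbreeding is
`F_P(i) = A[i,i] − 1`, the expected proportion of the genome identical by
descent (IBD) given the pedigree. The matrix is dense, O(n²) memory —
adequate into the tens of thousands of individuals; founder contributions
below avoid the full matrix when only founder rows are needed.

Expected founder contributions use the genome-proportion recursion
`g[f,f] = 1`, `g[f,i] = (g[f,s] + g[f,d])/2`, which equals `A[f,i]` for
founders (asserted in tests). `Σ_f g[f,i] = 1` for every individual to
1e-9. A founder's contribution to year t is the mean of `g[f,·]` over the
year-t census (equivalently the summed proportions divided by N_t), so
per-year contributions over all founders sum to 1; the published approach
cites a standardization by each year's population size without printing the
formula, and this N_t-normalized mean satisfies that description. Cohort
series are sums of member series. A founder's series is zero before it (or
any descendant) first appears in a census, and missing in empty census
years.

## Gene drop

Each founder receives two unique alleles; each replicate transmits one
uniformly random allele per parent per offspring, in topological order from
a single seeded NumPy generator, vectorized across replicates (an
n × R × 2 int32 array). Tallies retained per individual: allele copies from
each founder (exactly 2R in total — an integer identity), replicates in
which both alleles are the identical copy from a founder (IBD via that
founder), and replicates in which both alleles originate within each
founder group. From these:

* ancestry proportion from group G = copies from G / 2R (rows sum to 1
  exactly); translocation ancestry = 1 − nontranslocated ancestry;
* P(homozygous for G) = both-allele-in-G replicates / R. This is *not* the
  squared ancestry in general: allele origins are correlated through shared
  ancestors (e.g. for an offspring of a sire–daughter mating with a
  translocated sire, ancestry is 0.75 but the homozygosity probability is
  0.5);
* founder-attributed inbreeding for year t: mean over replicates of the
  count of census individuals IBD via founder f, divided by N_t — the
  probability that a random individual's two alleles at a random locus are
  identical copies from f. Summed over founders this estimates the year's
  mean F_P. IBD is tallied per founder (either of its two alleles), not per
  allele.

Default R = 50,000. Every Monte Carlo estimate is emitted with its binomial
standard error. The default is simulation; ancestry (and F_P) can instead
be computed by the exact recursion (`--exact-only`), while homozygous-group
probability and founder attribution have no simple closed form and always
use simulation.

`enumerate_transmissions` replaces the random draws with all 2^k meiosis
outcomes (k = 2 × non-founders, capped at 20) and yields exact versions of
every tally. It is the oracle for the Monte Carlo engine and an independent
cross-check of the tabular method; the test suite verifies exact agreement
of F_P across all three routes on random small pedigrees, and 4-SE
agreement for the stochastic estimates.

## Ancestry metrics

With individual ancestry vectors q_i and population mean Q over the groups
present (Q_g > 0),

    m_d = 1 − [Σ_i Σ_g |q_ig − Q_g|] / [2 N Σ_g Q_g(1 − Q_g)].

This normalized mean-absolute-deviation form reproduces the defining
boundary behavior — 0 when every individual's ancestry is confined to one
group (any group shares), 1 when all individuals carry the mean vector —
and is undefined (None) when fewer than two groups are present. It is
deliberately isolated in one function so an alternative definition can be
swapped in; interior values of other definitions may differ. Founder-group
counts per individual use threshold 0 by default: any group with nonzero
estimated ancestry counts (in simulation mode, any group from which an
allele copy was ever inherited). Per-year composition is the census mean of
ancestry rows; donor shares divide each donor column by total translocation
ancestry.

## Demography

Census size N_t counts distinct censused individuals; interyear change is
100·(N_t − N_{t−1})/N_{t−1}. A *potential breeding group* is a cluster
occupied (breeder/helper/juvenile roles — floaters are unattached by
definition) by at least one adult male and one adult female, where adult
means hatched or released strictly before the census year (unrecorded years
⇒ treated as adult, i.e. pre-monitoring residents); unknown-sex birds never
satisfy the requirement. PBGs are classified by whether their adults are
only translocated, only nontranslocated, or combined. A released bird is
*established* if censused in any year strictly after its release year
(fall releases follow the post-breeding census); persistence counts census
years (the calendar span is also reported, so gaps are visible), and
nesting years count distinct years a nest names the bird as breeder. Pair
identity is the unordered breeder pair — re-pairings are new pairs — and
pair classes split by whether 2, 1, or 0 partners are translocated.
Spearman's rank correlation (average ranks on ties, via scipy) compares the
size and PBG series; constant series give a missing value.

## Synthetic populations

The simulator emulates the monitored study system: clusters with one
monogamous breeding pair and up to four helpers; an annual cycle of
survival → vacancy filling (oldest same-cluster helper, then oldest
floater) and colonization of empty clusters by floater pairs → nesting
(zero-inflated Poisson fledglings) → post-breeding census → juvenile
dispersal (helper retention vs floating) → fall releases. Translocated
birds are subadult founders with ancestry 1; establishment is a configured
Bernoulli draw at release, and birds that establish are guaranteed their
first post-release census (establishment probability is thus interpreted
as the probability of ever being censused, matching how establishment is
scored). Survival is sex-specific on the logit scale with an additive
effect of translocation ancestry (`ancestry_survival_logit`); fecundity
takes an optional log-scale ancestry effect. Offspring ancestry is the
parental mean, so truth ancestry equals the exact pedigree recursion by
construction.

Defaults mirror the study's shape: 29 monitoring years (1994–2022), 40
clusters (20 initially occupied), female/male survival 0.71/0.80, mean 1.6
fledglings per successful nest with 25% total failures, helper retention
0.4, establishment 0.7, a ~2%-per-year migrant arrival, and a release
schedule of 11 events (sizes 1–10, six donor labels, 54 birds,
1998–2016). Under these defaults populations run roughly 70–220 birds —
the scale of the real program. Effect-recovery experiments use a ~150-bird,
40-year configuration; with a logit effect of 0.65 (≈ +10 percentage points
of annual survival at full translocation ancestry) the naive survival
difference between high- and zero-ancestry birds is positive in ≥95 of 100
replicates, and with zero effect the sign is near 50/50 (both checked in
the acceptance tests).

What the simulator does *not* reproduce: spatial territory structure,
age-dependent vital rates beyond the adult/juvenile split, environmental
stochasticity, mate choice or inbreeding avoidance (so simulated pedigrees
accumulate more inbreeding than a choosy wild population would), and
detection failure (censuses are perfect, which is why naive survival
comparisons are meaningful in simulation while real data need
capture–mark–recapture models, out of scope here). Passing tests therefore
validate the estimators' algebra and convergence, not the ecological
realism of any particular parameter set.

## Numerical conventions

Conservation and symmetry assertions use 1e-9 absolute tolerance; gene-drop
stochastic checks use 4 binomial standard errors. Dyadic quantities
(relationship entries, enumeration probabilities) are exact in double
precision, so small-fixture tests assert equality. Calendar years are
integers, intervals closed. Missing values are empty fields on write;
empty/NA/na/NaN on read. Tie-breaks everywhere are id-sorted; all
randomness flows from explicit seeds recorded in outputs and manifests.
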