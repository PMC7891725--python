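# Methods

This note documents the models, estimators, numerical choices and known
limitations of `sumoquant`.

## SILAC peptide-to-protein quantification

### Measurement model

A two-channel SILAC experiment grows one strain on light lysine/arginine
and the other on heavy (¹³C/¹⁵N) lysine/arginine (mass shifts +8.014199 Da
per Lys and +10.00827 Da per Arg; carbamidomethylated Cys carries a static
+57.021464 Da). After mixing, enrichment, digestion and LC-MS/MS, a search
engine identifies peptides and an isotope-pair quantifier reports a light
area, a heavy area and a validity flag per identification. This package
starts from that table; it never touches raw spectra.

### Filtering rules

Applied in order, each idempotent:

1. **Quality**: keep a record iff its combined area l+h strictly exceeds the
   intensity threshold (default 1e-3 in the quantifier's normalized units)
   *and* its ratio is flagged valid. The printed form of such thresholds is
   ambiguous about absolute scale across quantifier versions, so the value
   is a config field, not a constant.
2. **Uniqueness**: within a protein, redundant identifications of one
   sequence collapse to the single most abundant record (largest combined
   area; ties break to the lexicographically smallest spectrum id — the tie
   rule is arbitrary but makes reruns byte-identical). Across proteins,
   sequences observed under two or more accessions are dropped entirely by
   default, since their evidence is ambiguous; `drop_shared_peptides=False`
   retains them for sensitivity analyses. The redundancy key is
   (protein, sequence) — charge states of one sequence are treated as
   redundant identifications of the same peptide; a config switch makes the
   key charge-sensitive.

A dropped record is charged to the first rule it fails, so the filter
report's per-rule counts always sum to the input row count.

### Rollup and dispersion

Per protein, R = Σh/Σl and log2 R. The summed-area form weights peptides by
signal and is invariant under peptide reordering and uniform rescaling of
all areas. The dispersion is the n−1 sample SD of per-peptide log2(h/l)
over the three peptides with the largest combined area; computing it on the
log2 scale matches the symmetric error bars of ratio figures. Selection is
by intensity, not by ratio, so an outlier ratio on a weak peptide cannot
enter the SD. Proteins with fewer than three unique peptides (the default
gate, configurable) carry no SD and are written to a separate low-evidence
table rather than discarded — the gate is auditable. A protein whose summed
light or heavy channel is zero has no defined log ratio; it is excluded
with an explicit flag instead of being assigned ±∞.

### Orientation

Raw ratios are heavy/light. Which biological condition each channel carries
is metadata (`ComparisonLabel`); figure-facing summaries can request either
orientation, and a flip negates every log2 value while leaving SDs
unchanged. Every output embeds the orientation string so a table can never
be misread.

## Synthetic SILAC data

Each protein draws a true log2 ratio from Normal(group mean, group SD);
each peptide draws a combined area from a log-normal (log10 mean 6, SD 1 —
a typical orbitrap dynamic range), perturbs the protein ratio with
multiplicative noise (Gaussian on log2, default σ = 0.2, a typical
peptide-level SILAC scatter), and splits the combined area as
l = c/(1+R), h = c − l. Corruption knobs inject, per record: invalid-ratio
flags, sub-threshold intensities, sequences shared verbatim between two
proteins, and duplicate identifications re-emitted under a fresh spectrum
id with areas scaled by Uniform(0.3, 0.9). Default group means (septins
+1.5; nuclear-pore 0; nucleolar/RNA-Pol-I, SMC and replication/repair −1.5;
chromosome segregation −0.3 log2 units) mirror the qualitative structure of
a SUMO-ligase-pathway mutant vs wild type. All randomness flows from one
seeded `numpy.random.Generator`.

What it does **not** emulate: missing channels, retention-time or
mass-accuracy artifacts, interference between co-eluting pairs, nonlinear
detector saturation, or between-experiment normalization drift. Passing
tests therefore certify the *analysis* logic, not robustness to every
failure mode of real acquisitions.

With σ = 0 and no corruption, the pipeline returns each true log2 ratio to
double precision (each sum and quotient rounds once; asserted at 1e-9,
far below any scientific signal) and SDs ~0. With σ = 0.2 and five
peptides per protein the estimate's spread is slightly above σ/√5 because
the rollup weights peptides by their log-normal intensities (effective
n < 5); the recovery test bounds it within a factor of two.

## Fluctuation analysis

### Model

Cultures grow from small inocula to N_t cells; mutations arise at rate μ
per cell per generation. Under deterministic doubling the expected number
of mutational events per culture is m = μ·N_t, and an event at the time
when the culture had fraction u of its final size founds a clone of ~1/u
cells — hence the simulator's M ~ Poisson(m) events per culture with clone
sizes ⌊1/U⌋, U ~ Uniform(0,1], capped at N_t. This yields the classic
heavy-tailed count distribution (P(clone ≥ k) = 1/k), which is why means
are useless and the median is the summary of choice. Plating efficiency is
1: rates are per cell plated, with no dilution correction.

### Estimator

The Lea–Coulson method of the median solves r̃/m − ln m = 1.24 for m. The
left side is strictly decreasing in m (−r̃/m² − 1/m < 0), so the root is
unique for any r̃ > 0 and is found by bracketed Brent iteration to
machine tolerance (residual < 1e-9 asserted). A zero median falls back to
the p0 method m = −ln P₀ and the estimate records which method produced it,
so alternative estimators (e.g. MSS maximum likelihood) can be added
without breaking the output contract. μ̂ = m/N̄_t uses the mean viable
count; per-culture N_t spreading beyond 10× triggers a warning rather than
an error, since the protocol tolerates modest titer variation but the mean
then summarizes poorly.

### Confidence intervals

The 95% CI of the *median count* uses symmetric order-statistic ranks
(a, n+1−a), the narrowest pair whose exact Binomial(n, ½) coverage reaches
the nominal level (n = 16 → ranks (4, 13), coverage 97.9%; below n = 6 the
nominal 95% is unattainable and the widest pair is returned with an
achieved-coverage warning). Both bounds pass through the same m(·)/N̄_t map
as the point estimate. A bound of zero counts maps to rate 0 — the p0
method needs a whole assay, not a single order statistic — and the interval
is clipped to bracket the estimate for the rare p0-fallback case where the
fallback estimate sits outside the transformed ranks. Simulated coverage at
the generator's default conditions (μ = 2×10⁻⁸, N_t = 10⁸, 16 cultures)
runs ~97%, i.e. conservatively above nominal.

Fold changes are point-estimate ratios vs a named reference strain; the
CI-derived interval (lower bound over upper, upper over lower) is available
from the written table. A zero-rate reference makes the ratio undefined and
the error reports the ">x" lower bound implied by the reference CI.

### Problem sizes

Stochastic checks run at: 10⁵ cultures for the Poisson zero-class check,
10³ assays of 16 cultures per m ∈ {1, 2, 5, 20} for estimator recovery,
500 replicates for CI coverage, and 100 replicates of 20 proteins for
SILAC recovery — sizes at which every Monte-Carlo margin is several times
its standard error while a full run stays in seconds.

## Design choices that were genuinely open

- **Estimator choice**: median-based protocols rarely restate their
  estimator; the Lea–Coulson median equation is the standard
  operationalization of "median rate" and is declared in output metadata
  rather than hard-coded into the semantics.
- **SD scale**: dispersion on log2 ratios, not raw ratios, matching
  symmetric error bars on log2 axes.
- **Shared-peptide handling**: dropped by default (toggleable) — the
  conservative reading of "unique peptides of each protein".
- **Orientation**: both H/L and L/H producible; nothing is hard-coded
  because condition-to-channel assignment varies between experiments.

## Limitations

- No identification-level FDR control, normalization across experiments,
  missing-channel imputation, or significance testing of ratio differences
  — the pipeline reports ratios and dispersions.
- The fluctuation model assumes equal growth of mutants and non-mutants, no
  phenotypic lag, and full plating; rates from assays violating these are
  biased in known directions and this package does not correct for them.
- The xlsx reader expects the package's column contract; supplementary
  spreadsheets from publications generally need a one-time column mapping
  to TSV before ingestion.
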