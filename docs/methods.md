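# Methods

## Carbon-transition model

The network covers trehalose cleavage, upper/lower glycolysis and both PPP
branches as thirteen reactions over thirteen metabolites, each reaction with
an explicit bijective atom map (CO₂ is a one-carbon product, so ¹³C count is
conserved identically). Carbon numbering is the biochemical convention (C1 =
most oxidized end). The mechanistically load-bearing maps:

* **oxidative branch (lumped G6P→Ru5P + CO₂)** — C1 → CO₂, C2–C6 → Ru5P C1–C5;
* **transketolase** — the donor ketose's C1–C2 glycolaldehyde unit moves onto
  the acceptor's C1 end (TKT1: Xu5P+R5P→S7P+GAP; TKT2: Xu5P+E4P→F6P+GAP);
* **transaldolase** — the donor's C1–C3 dihydroxyacetone unit moves
  (S7P+GAP→E4P+F6P);
* **aldolase/TPI lump** — F6P C4–C6 → one GAP unchanged; C1–C3 → the second
  GAP with inverted order (the DHAP half passes through TPI). Order only
  matters for positional states, not mass shifts;
* PGI, RPI, RPE, hexokinase, trehalase and lower glycolysis keep identity
  skeletons. PGI, RPI, RPE, TKT1, TKT2 and TAL are reversible; the oxidative
  decarboxylation, trehalase/hexokinase and lower glycolysis are not.

These maps reproduce the scheme-level checks exactly: forward TKT1 on
unlabeled Xu5P + fully labeled R5P gives S7P m+5; reversed TKT2 then reversed
TAL on fully labeled F6P + unlabeled GAP gives S7P m+4 (via Xu5P m+2 and E4P
m+4); forward TAL with a fully labeled triose gives a hexose labeled at
C4–C6 (m+3). One recycling round consumes six pentoses as two (Xu5P, R5P,
Xu5P) sets and returns four hexoses and two trioses; enumerating each set's
three pentose inputs as fully labeled/unlabeled (minus the all-unlabeled
case) yields seven combinations, three of which regenerate an m+2 hexose.

The transaldolase triose partner in the recycling round is a policy:
`internal` consumes the TKT1-produced GAP (the closed-loop reading),
`pool_unlabeled` draws an unlabeled triose from the cytosolic pool and emits
the TKT1 GAP into it. The first-round enumeration uses `pool_unlabeled`
(the tracer-minority assumption under which the 3-of-7 count holds); the
result object records consumed/emitted pool trioses so label balance is
auditable under either policy.

## Regime templates

Template MIDs for four labeling regimes are computed by exact enumeration of
positional pattern distributions ("pools"), never Monte Carlo. Two modeling
assumptions apply throughout:

* **well-mixed pools** — each reaction event draws its substrates
  independently from the current pool distributions (product–product
  correlations within one event are not tracked across later events);
* **exchangeable entry patterns** — a tracer MID is spread uniformly over
  positional patterns at each mass shift. This is exact for the cases it is
  used on (pure m+6/m+0 mixtures, i.i.d. per-carbon tracer impurity); the
  half-labeled trehalose option is block-labeled at one glucosyl unit and is
  special-cased accordingly.

The entry hexose pool is `enrichment · tracer + (1 − enrichment) · unlabeled`;
trehalose enters through the trehalase map as two glucosyl units.

* **direct_glycolysis** — identity transport to G6P/F6P; trioses from the
  aldolase split; pentose and heptose pools stay at the unlabeled background.
* **oxppp_single_pass** — one oxidative decarboxylation, one TKT1/TAL/TKT2
  recombination pass with the internal triose as transaldolase partner.
* **cyclic_ppp** — pentoses from oxidation of the entry pool; recombination
  with the transaldolase partner drawn from the **glycolytic GAP pool at
  tracer enrichment**, which creates the early-phase hexose labeled at C4–C6
  (m+3) alongside the pentose-recombination products (m+1–m+4, m+6). With
  `rounds > 1`, product hexoses are diluted by unlabeled influx (the same
  enrichment scalar — the minimal mixing model) and re-enter the
  recombination step; the reported G6P/F6P template is the accumulated
  mixture over the entry pool and all rounds.
* **nonox_ppp** — reversed TKT2, TAL and TKT1 on the F6P and glycolytic GAP
  pools; the reported pentose peak is the stoichiometric 1:1:1 mixture of the
  two Xu5P products and R5P (RPE/RPI equilibrate the skeletons).

**Truncation choice.** Reported Ru5P and S7P templates come from the *first
oxidative generation* (oxidation of the entry pool; round-1 TKT1), while
hexose templates accumulate over rounds. Re-oxidizing recombination hexoses
(labeled at C1–C3) would feed m+2 pentoses into the cyclic template and blur
the marker identities that make the regimes separable — m+2 ribulose-5P and
m+4 sedoheptulose-7P are diagnostic of the nonoxidative route, m+5 species of
the oxidative routes. Truncating at the first generation keeps those markers
exactly zero where the scheme predicts no first-order production, at the cost
of ignoring second-order recycling contributions to the pentose pool. This is
a deliberate identifiability-over-completeness trade-off for template
construction; it does not affect the single-molecule engine, which applies
any reaction sequence the user requests.

Reported species follow the instrument: ribulose-5P/ribose-5P and
fructose-6P/glucose-1P are each one combined peak (declared as aliases in the
atlas); lactate inherits the GAP pool through identity skeletons.

## Natural-abundance correction

With natural ¹³C abundance `p13` (default 0.0107, configurable), a molecule
with `j` tracer carbons is observed at shift `i ≥ j` with binomial probability
`C(n−j, i−j) p13^(i−j) (1−p13)^(n−i)`; columns of the resulting
lower-triangular matrix sum to 1. Correction solves `M x ≈ measured` with
`x ≥ 0` by NNLS and renormalizes, reporting the residual norm. NNLS reduces
to exact sequential stripping on noise-free data but cannot produce negative
fractions on noisy data; if the deposited sheets used plain stripping, small
numeric differences on noisy vectors are expected. Only carbon satellites are
corrected (at 70k resolving power the extracted series is the ¹³C one);
tracer impurity (purity ≥ 99 atom % is typical) enters the forward model as
an i.i.d. per-carbon labeling probability on the tracer MID, not as a
correction-matrix term.

## Normalization and fractions

The normalization factor of a sample is the arithmetic mean, over all
metabolites shared with the chosen reference sample, of the m+0 peak-area
ratios sample/reference; labeled satellites never enter the factor, zero or
missing reference areas are excluded and counted, and the internal standard
(4-fluorophenylalanine) is excluded by default. All areas of the sample are
divided by its factor. The procedure is idempotent and removes per-sample
global scales exactly when samples share true MIDs; between groups with
different m+0 fractions the factor deliberately tracks total unlabeled
content, as published. Isotopologue fractions are within-(sample, metabolite)
area ratios and are therefore scale-invariant; missing shifts count as zero.

## Statistics

Welch's *t* (closed-form statistic and Satterthwaite df, p from the *t*
distribution; one- or two-tailed) and the paired *t* test are implemented
directly so the df and tail conventions are explicit; both are cross-checked
against scipy in the tests. Holm–Šidák is the step-down rule
`1 − (1 − p_(i))^(m−i)` with a running maximum; the default family is one
metabolite's mass shifts (per-panel style), configurable to global or none.
Fractions are tested on the raw simplex — no logit/arcsine transform —
matching how such data are plotted and compared.

Mixture deconvolution stacks the corrected mean fractions over all reported
(metabolite, mass shift) pairs and solves NNLS with an appended sum-to-one
row (weight 10³) followed by exact renormalization; the residual and a
rank-deficiency (collinearity) flag are returned. Recovery on the noise-free
0.1-step simplex grid is exact to ≤ 1e-3 by construction of the shared
forward model.

## Synthetic data

The generator emulates the ex vivo tracing design: two groups (uninfected /
infected) × 5 biological replicates, tracer media of 0.5 mM glucose-¹³C₆ or
5 mM trehalose-¹³C₁₂ (concentrations are carried as metadata; labeling enters
through the enrichment parameter), infected shifted toward cyclic PPP
(default mixtures 0.55/0.20/0.10/0.15 vs 0.35/0.20/0.30/0.15 at enrichments
0.4 vs 0.6 — direction-of-change choices, not published magnitudes). True
MIDs are the convex mixture of regime templates; the forward model applies
natural-abundance convolution, a per-sample log-normal global scale
(σ = 0.25) and per-peak log-normal noise (CV = 10%, unit mean), the latter two
chosen as realistic LC-HRMS orders of magnitude. Baseline pool areas are
order-of-magnitude placeholders per metabolite (10⁵–2·10⁶ area units), not
measured values. All randomness comes from one `numpy.random.default_rng`
(PCG64) seed recorded in the output metadata; equal seeds give byte-identical
tables.

What passing recovery tests show: the pipeline inverts its own forward model
— consistent normalization, correction and deconvolution — under realistic
multiplicative noise. What they do not show: robustness to chromatographic
artifacts, retention-time misassignment, matrix effects, compartmentation, or
regime structures outside the four templates; real tissue mixes oxidation
generations that the template truncation deliberately omits.

## Problem sizes and numerics

Exact enumeration is cheap: the largest species has 12 carbons (4096
patterns) and template construction runs in milliseconds with caching per
(tracer, enrichment, rounds). The recovery suite uses 20 seeded synthetic
experiments at CV 10%, n = 5 (median max weight error ≤ 0.1; observed ≈
0.03–0.05), and the noise-free limit is checked to 1e-3. MIDs are validated
to sum to 1 within 1e-9; the natural-abundance round trip holds to 1e-6 for
n ≤ 12. Degenerate inputs fail loudly: zero-variance t tests, all-zero peak
vectors, missing reference samples and malformed table records raise errors
naming the offending quantity.
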