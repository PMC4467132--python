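# Methods

## Kinetic model and units

Species concentrations are in nM and time in seconds throughout; rate
constants follow the convention 1/s (unimolecular), 1/(nM·s) (bimolecular
and mass-action catalysis), and 1/s with K_m in nM for Michaelis–Menten.
Reversible reactions are limited to at most two reactants/products;
catalytic reactions convert a substrate form into a product form of
identical moiety composition with the enzyme unchanged. Mass action is the
default catalytic law; Michaelis–Menten is available per reaction. Each
reversible reaction expands to two directed rate processes and each
catalytic reaction to one, so a network with R reversible and C catalytic
reactions carries 2R + C directed processes.

Moiety compositions make two checks possible: per-reaction moiety balance
at validation time, and conservation of each basic protein's total
(summed over all forms and complexes, with multiplicity) along any
trajectory of a closed model. mRNA species carry an empty composition, so
transcription/degradation does not break protein-moiety conservation.

## Model exchange

Two formats round-trip losslessly: a native tabular form (a directory with
`species.csv` + `reactions.csv`, compositions as `A+2*B` strings, plus
`annotations.json`) and an SBML Level 3 subset written and parsed with
lxml. The SBML writer emits explicit kinetic-law MathML with local
parameters (`kon`/`koff` for reversible reactions, `kcat`/`Km` for
enzyme-modifier reactions) and stores roles/compositions in a custom
annotation namespace, since SBML core has no vocabulary for them. The
reader accepts our own files and any SBML following those local-parameter
conventions; it does not attempt general MathML interpretation. The
promoter configuration is not part of SBML output (it is not a reaction
process); it travels with the in-memory model and the YAML/JSON side
files.

## Integration and equilibration

Signaling networks mix second-scale binding with hour-scale
transcription, so the system is stiff; SciPy's implicit BDF method is used
for all integration (default rtol 1e-8, atol 1e-9 nM). Trajectories are
clipped to zero at output only; solver state is untouched, and rate
evaluation clamps negative underflow so the right-hand side is robust.

"Quasi-stationary equilibrium" is operationalized as the first time the
scaled derivative norm max_i |dx_i/dt| / (atol + |x_i|) falls below 1e-10/s,
checked at the end of doubling time chunks (100 s, 200 s, …) up to a
2×10⁷ s ceiling; hitting the ceiling returns the state with a warning
flag, and a growing norm with a diverging state raises an error. The slow
pole of the system is CCND1 mRNA (k_deg = 5.7×10⁻⁶/s), which sets the
~10⁶ s equilibration horizon. Equilibration runs with mRNA dynamics live
(a flag can freeze them), so the baseline includes the steady-state mRNA
levels.

## Promoter model

Site occupancy is treated in the thermodynamic limit with single occupancy
per site and competitive binding: F_site = (1 + Σ ω_a·[a]/Kd_a) /
(1 + Σ [a]/Kd_a + Σ [r]/Kd_r). An unoccupied site contributes 1;
repressor occupancy excludes RNA polymerase recruitment (weight 0 in the
numerator), which a brute-force enumeration over joint occupancy states
confirms is exactly equivalent to the product-of-sites form under site
independence. k_RNAP is multiplicative (association-constant convention);
a config toggle reinterprets it as a dissociation constant. The two genes
share one promoter architecture and synthesis constant (k_synth =
5×10⁻⁵/s) and differ only in degradation (MYC 2.7×10⁻⁴/s, CCND1
5.7×10⁻⁶/s) — a ~47-fold stability asymmetry that drives the fast-MYC /
slow-CCND1 response difference.

The MEK-inhibition CCND1 destabilization multiplies k_deg,CCND1 by
[ppERK_control]/[ppERK_treated]. The treated ppERK level is read
dynamically from the current state during integration (the control level
is the equilibrated baseline scalar), since nothing fixes whether the
ratio should be static; a dynamic ratio lets partial ERK recovery feed
back into mRNA stability. The treated level is floored at 10⁻⁶ of control
(with a warning) so near-total ERK inhibition cannot produce an unbounded
degradation rate. Because the destabilization is experimentally known to
act through the transcription of an intermediary gene, the term is
conditional on active transcription: under Actinomycin D (k_synth = 0) it
switches off by default (`actd_blocks_destabilization`), reproducing the
rescue of CCND1 by co-treatment; disabling the flag keeps it active.

## Genotypes and inhibitors

Constitutive activation zeroes the catalytic constants of every
inactivation process acting on the target's annotated active form, rather
than clamping a concentration — this preserves moiety conservation and
makes the active form's steady state independent of upstream drive (any
nonzero activation flux eventually converts the whole pool). Null /
partial-loss / over-expression rescale the moiety's total pool (0×,
fraction, fold). Directives record themselves in the model annotations and
are skipped on re-application, so applying a genotype is idempotent and
rescalings never compound. Presets: HCT116 (constitutive KRAS, β-Catenin,
PI3K; PTEN at 60%; E-Cadherin and TGFβRII null) and HT29 (constitutive
BRAF, PI3K; APC and SMAD4 null; ErbB2 2×).

Activity-scaling inhibitors multiply by (1−f) the catalytic constants of
every reaction whose enzyme is the target species or whose enzyme
composition contains the target moiety — the latter is what lets a GSK3β
inhibitor act on the Axin:GSK3β:APC destruction complex. Competitive
binders add an inhibitor species at a fixed dose plus a reversible
sequestration reaction (association rate 10⁻³/(nM·s), K_i = strength);
sequestered target is excluded from the "active" readout numerator but
still counts in the moiety total, mirroring how a bound kinase is inactive
but still detected as protein. The Perifosine presets are competitive
binders at 20/40 nM because scaling the activity of phospho-AKT itself
cannot move the pAKT/AKT readout; the documented 40%/70% inhibition levels
are stoichiometrically reachable only when the dose is commensurate with
the AKT pool, which fixes the toy network's AKT total at 40 nM.

Calibration finds the mechanistic strength (f, or K_i on a log₁₀ grid)
whose 30-min treated readout, normalized to the equilibrated control,
matches a desired fractional inhibition. The dose-response is first
checked to bracket the target (otherwise a calibration error names the
insensitive readout); Brent root finding then converges the readout to
within 10⁻⁴, comfortably inside the 10⁻³ contract.

## Virtual experiments and readouts

The pipeline is: apply genotype → initialize every pool to its unbound
form → equilibrate → per treatment: apply inhibitors (carrying the
equilibrated state over, new inhibitor species at their dose), simulate,
read endpoints, divide by the vehicle control at the same time. Protein
endpoints (ppERK/ERK, pAKT/AKT: annotated active species over the moiety
total) are read at 30 min; mRNA endpoints at 4 h and 8 h as instantaneous
levels (not time averages). Endpoints with a zero control value are
emitted flagged `undefined_control` rather than dropped. The Actinomycin-D
protocol zeroes synthesis at t = 0 from the same baseline and reports
remaining mRNA normalized to t = 0.

## Validation statistics

Spearman's rho uses midranks for ties; its 95% CI is the Fisher
z-transform interval with SE = 1/√(n−3); the two-tailed p is an exact
permutation enumeration for n ≤ 9 and the t-approximation above that. The
explained-variation measure is R² of ordinary least squares on natural-log
transformed pairs (base-invariant; values must be positive, and offending
rows are named otherwise). Replicates remain separate pairs sharing one
simulated prediction per condition, so with r replicates per condition the
tied predictions impose an attainable-rho ceiling slightly below 1. At
least 4 pairs are required; constant inputs are flagged degenerate rather
than scored.

## The reduced three-pathway network (synthetic test-bed)

The generator builds a miniature of the modeled region: EGF→EGFR→KRAS→
BRAF→MEK→ERK with genuinely double ERK phosphorylation, per-tier
phosphatases, and an ERK→RAF negative feedback; EGFR/ErbB2-driven
PI3K→AKT with PTEN as the counteracting phosphatase; and a WNT arm with
Tankyrase-controlled Axin turnover, the Axin:GSK3β:APC destruction complex
phosphorylating β-Catenin, E-Cadherin sequestration, and β-Catenin:TCF7L2
as the transcriptional output, plus a TGFβ/SMAD arm and constant
TP53/E2F-DP1/RB background feeding the remaining promoter sites. All
totals and rate constants live in `TOY_MANIFEST`.

Parameter choices, made once: kinase and phosphatase activities are
matched (k_cat·[E] ≈ 0.05/s per tier) so untreated steady states sit at
~30–60% pathway activation — room to move in both directions; protein
dynamics relax in minutes, well inside the 30-min protein readout; the AP1
arm runs steep (2× kinase, 4× phosphatase k_cat) and its phospho-form
binds in the low-occupancy/high-weight regime (K_d 85 nM, ω 40) so the
promoter tracks ppERK changes nearly linearly instead of saturating; the
RNAP weight is set so the untreated P(RNAP bound) ≈ 0.5, the point of
maximal dynamic range. Construction is deterministic; the seed only feeds
the pseudo-data noise stream.

Pseudo-experimental tables multiply each simulated readout by lognormal
noise with median 1 and a stated CV (replicating the positivity and
log-transformability of qPCR/western data), with ≥ 2 replicates. What
passing tests on this generator do **not** show: recovery of a trained
full-scale network's quantitative behavior, realistic inter-pathway
crosstalk beyond the wired feedback, biological (as opposed to
multiplicative-noise) replicate structure, or inhibitor
pharmacokinetics.

## Known limitations

* The per-site regulation-factor functional form is the standard
  thermodynamic-occupancy default (competitive, single occupancy,
  activation weights); other derivations would change F_site and are
  pluggable but not implemented.
* The SBML reader covers the subset the writer produces plus conventional
  mass-action files; kinetic laws outside the kon/koff / kcat(/Km)
  local-parameter conventions are rejected with a format error.
* Stochastic simulation, spatial effects, parameter estimation, and
  mechanistic miRNA-mediated mRNA destabilization (represented only by the
  empirical ppERK-ratio term) are out of scope.
* Wnt-arm inhibitor effects on transcription in the reduced network are
  directionally correct but small, a consequence of the buffered
  β-Catenin cycle at the chosen operating point.
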