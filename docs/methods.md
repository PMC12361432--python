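# Methods

## Scope and data model

The package covers the quantitative chain of a receptor-mutant
structure–function study: trace-level normalization of plate-reader kinetics,
flow-cytometry binding ratios, concentration–response summarization,
cross-assay impact statistics, and structural metrics on model ensembles.
Primary containers are a long-format kinetic trace (`KineticTrace`: one well,
one or two emission channels, one or two injection times), a plate map
(well → variant/ligand/concentration/role/replicate/experiment), flow records
(per-sample MFI paired with same-line autofluorescence), and a flat atom table
per structural model with chain roles (receptor/chemokine) and per-atom
confidence carried in the B-factor convention of predicted models.

Residue numbering is 1-based mature-protein numbering throughout, matching
mutant names such as K40A or S32; Ballesteros–Weinstein labels and
transmembrane helix boundaries are supplied as configuration tables, never
computed by alignment. The packaged chemokine sequence follows the printed
one-letter string verbatim; its N-terminal residue is written "P" although the
mature protein carries a cyclized pyroglutamate (from Q1) — the cyclization
has no effect on any sequence-arithmetic result, so the residue is treated as
standard.

## Kinetic normalization

Processing order is fixed: trailing (causal) rolling mean over 10 acquisition
points, division by the mean of the 10 samples immediately preceding the
injection, division by the identically processed buffer/vehicle well, then the
scalar summary. The baseline window width is a convention (the injection-time
mean is otherwise unspecified); 10 points matches the smoothing scale. Edge
handling shrinks the rolling window, ties in the post-injection maximum take
the first occurrence, and all summaries are exactly invariant to rescaling raw
signals by any positive constant (every step is a ratio).

For BRET areas the normalized agonist/buffer ratio has unity subtracted before
trapezoidal integration over the 600 s horizon, so buffer wells score exactly
zero and mutant:WT area ratios are meaningful; the unsubtracted variant is
available behind a flag. Dissociation assays integrate (1 − normalized ratio)
so dissociation is positive. Antagonist-mode traces carry two injections and
the peak is computed on the post-second-injection segment normalized to its
own pre-injection window.

A consequence worth knowing: the pre-injection baseline estimate carries a
relative error of order cv/√10, and dividing the whole 10-minute read by it
converts that error into a correlated offset on the integrand. Integrated over
600 s this dominates the AUC noise, so near-zero responders (e.g. an
arrestin-dead mutant) can yield slightly negative per-experiment AUCRCs. These
are retained as measured; the log-ratio ANOVA refuses non-positive ratios and
the pipeline excludes such variants from inference with an explicit warning
rather than flooring them.

## Binding ratios

Both the surface-level and chemokine-binding definitions are quotients of
log-MFI differences (base-10 logs are stored; the quotient is base-invariant),
which pins WT at exactly 1 and makes the statistics invariant to common
multiplicative rescaling of all fluorescence values. Ratios are computed
within experiment and averaged across experiments on the ratio scale (mean ±
SEM), mirroring the within-experiment WT division used for AUCRCs. Specific
binding is variant MFI minus parental MFI at matched concentrations (direct
subtraction, not a fitted nonspecific line); negative values arising from
noise are retained and flagged so SEMs stay honest.

## Dose–response

AUCRC is the trapezoid of the mean response against log₁₀ concentration over
the tested range, with no extra baseline handling: calcium peaks enter as
(peak ratio − 1) and BRET AUCs are already zero-baselined, so a buffer-level
curve has zero area and the mutant:WT AUCRC ratio equals the efficacy scale
exactly when potency is matched (linearity of the integral). The default
concentration design is six half-log dilutions from 0.3 to ~95 nM bracketing
the 10 nM reference EC₅₀, the layout a practitioner would pick for a ligand of
that potency.

The 4PL model is `floor + (ceiling − floor)/(1 + 10^(hill·(logEC₅₀ − log c)))`
with floor ≥ 0 and hill ∈ [0.3, 5], fitted by least squares from 8 starts on a
log-spaced EC₅₀ grid (best SSE wins, deterministic order). Flat data or a
fitted EC₅₀ outside [min conc/100, max conc·100] yields an honest
`converged=False` rather than an exception. EC₅₀ ratios are geometric means of
per-experiment mutant:WT ratios (potency ratios are log-normal); an arithmetic
mean is available behind a flag. Potency shifts planted beyond the tested
range are extrapolations and recover with visibly larger error than shifts
inside it.

## Impact statistics

Mutation impacts are within-experiment mutant:WT ratios aggregated across
independent experiments; SEMs are computed on the ratio scale and are
descriptive. Inference log₁₀-transforms the ratios: binding uses plain one-way
ANOVA with post-hoc comparisons versus both WT and the parental line;
signaling uses the repeated-measures variant (experiment as the blocking
factor, single pooled residual variance, which requires a balanced design).
Post-hoc two-sided t statistics share the pooled error variance, and families
of raw p-values pass through the Holm–Šídák step-down
(`statsmodels.multipletests`). Under a simulated complete null (12 mutants,
n = 3) the familywise error rate measures ≈ 0.03 over 1000 runs.

The bias index is the absolute difference of log₁₀ impact ratios between the
two signaling pathways — an invented scalar surrogate for the visual
"scalene contour" criterion, declared as such in outputs (0 = proportional
impact, 1 = ten-fold disproportion). The constitutive-activity analysis
reports basal-BRET fold-changes versus WT with Pearson/Spearman correlations
against donor luminescence and acceptor level as expression-confounder
checks, plus an (expression-normalized) surface:total ratio flagging
predominantly intracellular variants below a configurable 0.5 threshold —
also an invented default.

## Structural metrics

Superposition is least-squares rigid (gemmi), default on Cα atoms. The
activation metric is the distance from the Tyr(3.32) hydroxyl oxygen to the
*nearer* of the Asn(6.52) carboxamide heavy atoms (ND2/OD1) — nearest-atom
because carboxamide orientation is often arbitrary in models ("amide flips").
Model ranking uses this distance as the primary key with model-id
tie-breaking; bundle-geometry diagnostics (intracellular TM6 radial offset,
cross-pocket distance, signed TM5 depth) are reported alongside.

Helix-displacement decomposition superposes the inactive structure onto the
active one using all TM Cα except the measured segment (so the moving part
cannot bias the frame), then splits the displacement of the segment's midpoint
Cα into the component along the bundle axis — the principal axis of the frame
Cα cloud, signed positive toward declared intracellular marker residues — and
the perpendicular (outward) remainder. The exact frame/axis convention is a
declared choice; the corresponding checks carry ±1.5 Å tolerance.

Contacts use a 4.5 Å heavy-atom cutoff, optionally restricted to receptor
side-chain atoms; the contact-strength score is (fraction of ensemble models
showing the contact) × (mean number of atom pairs within the cutoff), an
invented operationalization of "strongest direct contacts in multiple
models". Site selection takes the top-k scoring receptor residues inside the
configured TM ranges, ties toward lower residue numbers. Hydrogen bonds are
geometric: N/O donor–acceptor pairs ≤ 3.5 Å in different residues, with the
≥ 120° D–H–A angle applied only when hydrogens are present (predicted models
usually lack them); no energy function. Disulfides are SG–SG pairs < 2.5 Å
paired greedily by distance. Per-atom interaction scores aggregate as sums
over backbone atoms (N, CA, C, O) and side-chain atoms per residue, averaged
across models when several are given.

## Synthetic data: what it emulates and what it does not

The generator is a pure function of (parameters, seed) and encodes one truth
record per variant: binding Bmax scale and Kd, per-pathway EC₅₀ and efficacy
scales, a basal-BRET offset (constitutive activity), and an expression scale;
WT is all-ones by construction and "parental" is a zero-Bmax line.

* Calcium traces: baseline × (1 + A·g(t)), g a difference of exponentials
  (τ_rise 3 s, τ_decay 40 s, normalized to unit peak) with
  A = efficacy · c/(c + EC₅₀) (Hill 1 by default — no cooperativity is
  assumed); multiplicative Gaussian noise per point; 0.5 s sampling with a
  30 s pre-injection window.
* BRET traces: constant donor channel scaled by expression; ratio = basal
  (0.6) + offset ± 0.2·efficacy·occupancy·(1 − e^(−t/60 s)), rising for
  arrestin recruitment and falling for G-protein dissociation.
* Flow MFIs: autofluorescence + saturating specific component + linear
  nonspecific (proteoglycan-like) component present in every line, with
  lognormal noise. At the 300 nM readout the nonspecific term is deliberately
  non-negligible, so a binding-dead variant reads at the parental level, not
  zero — as in real cells.
* Toy ensembles: seven idealized straight helices on a circle (30 residues
  each, numbering echoing the receptor's TM layout) with planted, exactly
  known features: Tyr/Asn atom pairs at controlled separations, strong (3.8 Å)
  and sub-threshold (6.0 Å) receptor–chemokine contacts, a Lys side-chain
  hydrogen-bonding to three chemokine-loop backbone oxygens at 2.9 Å, a
  Cys7–Cys35 disulfide at 2.05 Å, and an inactive reference with the
  tagged helix rigidly slid along (and/or radial to) the bundle axis.

These forms are emulations chosen for closed-form tractability: the kinetic
shapes, the BRET change magnitude, and the toy geometry are not fitted to any
instrument or structure. Consequently, passing tests demonstrate that the
*analysis chain* recovers planted parameters and matches independent oracles —
they say nothing about receptor biology, real detector noise (drift,
crosstalk, saturation), cell-to-cell variability, or realistic protein
geometry. Conversely, every analysis-side convention (windows, cutoffs,
integration, statistics) is exercised exactly as it would run on real
exports.

## Problem sizes and numerics

The demo and recovery runs use the study design: 6 concentrations, triplicate
wells, 3 independent experiments, 3% trace noise, 12 mutants + WT + parental.
BRET plates are sampled at 1 s (calcium at 0.5 s); the demo completes in ~10 s
and the acceptance script in ~30 s on one CPU. Recovery statistics use 40
random truth tables (the medians involved stabilize well below that), with
scales drawn uniformly from [0.1, 2.5]. Oracle-equivalence suites run hundreds
to a thousand randomized instances per primitive at 1e-9 absolute tolerance
where the computation is exact arithmetic, 1e-6 where a numeric superposition
is involved. Concentration matching in tables uses relative (not absolute)
tolerance, since molar quantities live at 1e-10–1e-6.

## Known limitations

No kinetic model fitting (rates/τ) — only peak and area summaries, as in the
underlying assay conventions. No operational-model (Black–Leff) bias factors;
the bias index is a descriptive surrogate. No gating or compensation of raw
cytometry events. No structure prediction, refinement, or neural scoring; the
score-aggregation step consumes externally supplied per-atom tables. The
repeated-measures ANOVA requires balanced designs and will refuse unbalanced
input rather than approximate it.
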