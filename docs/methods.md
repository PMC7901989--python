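# Methods

`ferracet` analyses sealed-bottle cultures of homoacetogenic bacteria
(*Sporomusa* spp., *Acetobacterium woodii*) that reduce insoluble Fe(III)
minerals as a side reaction of acetogenesis, and surveys their genomes for
the multiheme c-type cytochromes (MHCs) and extracellular-electron-transfer
(EET) gene panels that typify dedicated iron reducers.  This note documents
the models, the estimators, the synthetic-data generator, and the numerical
and design choices behind them.

## Electron-balance model

Acetogenic growth on ethanol combines two half-processes:

    2 CH3CH2OH + 2 H2O -> 2 CH3COOH + 4 H2     (ethanol oxidation)
    4 H2 + 2 CO2       -> CH3COOH + 2 H2O      (CO2 reduction)
    2 CH3CH2OH + 2 CO2 -> 3 CH3COOH            (overall)

so complete conversion yields 1.5 mol acetate per mol ethanol.  The electron
ledger assigns 4 e⁻/mol to ethanol oxidation, 8 e⁻/mol sunk per acetate made
from CO2 (4 H2 × 2 e⁻), 2 e⁻/mol carried by H2 and 1 e⁻/mol sunk per
Fe(III)→Fe(II).  The ledger object verifies at construction that each
reaction is element-balanced and that the overall reaction is the exact sum
of the half-processes.

With these coefficients, a mineral-amended culture that makes Δ µmol less
acetate than its mineral-free control has diverted 8Δ µmol of electron
equivalents away from acetogenesis; the *diversion efficiency* is the
fraction of those electrons recovered as Fe(II) (measured Fe(II) µmol × 1
e⁻/Fe over 8Δ).  For a 31 µmol acetate deficit this is 248 µmol diverted;
with 58 µmol Fe(II) the efficiency is 58/248 ≈ 0.234.  The quotient is
returned exactly, never rounded.

Biomass electrons are deliberately not modelled: electrons that are neither
in acetate nor in Fe(II) are left unattributed ("other/unrecovered").

Gas loadings use the ideal-gas law (n[mmol] = P[kPa]·V[mL]/RT, R = 8.314
J·mol⁻¹·K⁻¹, default T = 303.15 K, the 30 °C cultivation temperature).
Mineral loadings are matched on Fe(III) atoms: hematite (Fe2O3, 2
Fe(III)/unit) needs half the molar loading of goethite or HFO (1
Fe(III)/unit) to deliver the same Fe(III) concentration.

## Kinetics estimators

* **Exponential window.**  "Exponential phase" is operationalised as the
  contiguous window of ≥3 observed timepoints maximising the R² of an OLS
  fit of log10(cell density) vs time, enumerated exhaustively over all
  contiguous windows; R² ties (within 1e-9) break toward the longer window,
  then the earlier start.  A user-supplied fixed window overrides
  auto-selection.  Known limitation: on stationary-phase data whose density
  is flat up to counting noise, a short spurious window can occasionally win
  the R² race; when cell counts are very noisy, prefer a fixed window.
* **Fe(II) production rate.**  OLS slope of total Fe(II) (mM) vs time (days)
  restricted to the window, with standard error and R² — a linear slope in
  mM/day, not an exponential fit of Fe(II) itself.
* **Stationary accumulation.**  Mean of the last k (default 2) Fe(II)
  observations.
* **Fraction reduced.**  100 × final Fe(II) / initial Fe(III).
* **Partitioning.**  Sediment-associated Fe = total − supernatant, clamped
  at zero; over-subtractions beyond the 0.05 mM assay tolerance are flagged,
  not fatal.

Negative acetate deficits (treatment above control) are likewise clamped to
zero with a flag, because the real deficits are only a few percent of the
control acetate and replicate noise can invert them.

## Group statistics

Replicate-level metrics are compared by classical one-way ANOVA followed by
all-pairs Tukey HSD: q = |mᵢ − mⱼ| / sqrt(MSE/2 · (1/nᵢ + 1/nⱼ)) with the
studentized-range distribution on N − k df (Tukey–Kramer for unequal n;
group sizes here are normally n = 3).  Stars follow the figure convention
*** p < 0.001, ** p < 0.01 (plus * below alpha); alpha affects annotation
only, never the statistics.

## Heme-motif survey

The heme c attachment site CxxCH (two thioether-forming cysteines plus the
histidine axial ligand) is the primary pattern; CxxxCH, CxxxxCH, CxxCK,
AxxCH and FxxCH are variant patterns ("A/FxxCH" expanded literally into
two).  Matching is exact on anchor residues; wildcards accept any standard
residue plus the ambiguity codes X/B/Z/U, which never satisfy anchors.  A
stop (`*`) terminates its segment.  Coordinates are 1-based; proteins only,
no six-frame translation.

Default counting is non-overlapping greedy — one cysteine cannot ligate two
hemes — with cross-pattern overlaps resolved most-canonical-first
(CxxCH > CxxxCH > CxxxxCH > CxxCK > AxxCH/FxxCH).  `all_positions` counting
is retained for sensitivity analysis and is the form checked against
brute-force position enumeration in the tests.  Classification: 0 none,
1 monoheme, 2–5 multiheme, ≥6 multiheme-high (the high-heme class typical of
dedicated iron-reducer conduits).  Membrane/signal-peptide localisation is
accepted as an optional annotation table, never predicted here.

Assembly statistics: N50 is the length at which descending-sorted contigs
first cover half the assembly; GC excludes N from the denominator.

Gene-panel screening aligns each query locally against every proteome
protein (BLOSUM62; gap cost 11 + L, matching the blastp 11/1 convention)
and converts the best raw score S to a Karlin–Altschul e-value
E = K·m·n·exp(−λS) with the standard gapped-BLOSUM62 parameters λ = 0.267,
K = 0.041, m the query length and n the total proteome length.  Presence
requires e-value < 1e-4 and identity > 30% (strict); by default a query
coverage ≥ 50% requirement is added, because 30% identity over a dozen
residues is meaningless — `no_coverage=True` disables this extension.  An
external blastp backend is available and normalised to the same record.

## Synthetic cultures

The generator emulates the measured study conditions: 20 mL bottles (120 mL
for the dialysis setup), initial density 1.0e6 cells/mL, 9 mM Fe(III) as
HFO, ethanol 20 mM (organotrophic) or 3.2 mmol H2/bottle (lithotrophic),
triplicates, sampling every 2 days to day 14.

Growth is lag → exponential → stationary: density is constant through a lag
(default 2 days — precultures are exponentially growing, so the lag is
short), then rises exponentially at rate µ to the carrying capacity (1e8
cells/mL, 100-fold over inoculum), then is flat.  Substrate is consumed at a
constant rate across the growth phase and is exhausted when growth stops;
donor electrons, acetate and Fe(II) all follow that cumulative budget:

    e(t)       = 4·ΔEtOH(t)  or  2·ΔH2(t)
    acetate(t) = ΔEtOH(t) + e(t)·(1 − f_div)/8       (control: f_div = 0)
    Fe(II)(t)  = f_fe · f_div · e(t), capped at the Fe(III) input

This piecewise form (the two limits of a logistic) was chosen over a smooth
logistic deliberately: it makes the noiseless ground truth *exactly*
recoverable — the auto-selected window is the growth phase, Fe(II) is
exactly linear on it, and the OLS slope equals the configured rate to
machine precision — while preserving the growth-coupled plateau and exact
electron conservation at every timepoint.

Presets are anchored to the measured quantities.  The organotrophic strain
GT1 preset inverts the printed electron budget: f_fe = 58/248 (µmol Fe(II)
per µmol diverted) and f_div = plateau/(f_fe·80 mM e⁻) = 0.155, giving a
2.9 mM plateau, a 31 µmol acetate deficit and 248 µmol diverted electrons
exactly; µ is set so the growth phase lasts plateau/rate days, making
0.47 mM/day the exact noiseless slope.  The lithotrophic presets read the
"~10% of donor electrons" figure as f_div = 0.10 (the printed quantities do
not pin the denominator down; Fe(II) electrons alone would be 0.6% of the
total H2 budget) and set f_fe from the 1.9 mM plateau.  For *S. ovata* and
*A. woodii*, whose rates are not printed numerically, representative values
inside the reported reduced-fraction ranges (13–33% organotrophic, 5–22%
lithotrophic) were fixed once: 0.30/1.7 and 0.20/1.2 mM (organo),
0.15/1.0 and 0.08/0.5 mM (litho).  The dialysis preset scales the final
Fe(II) to 0.2% of the Fe(III) input (mid-range of the observed 0.06–0.3%)
in 120 mL.

Observation noise is additive Gaussian on concentrations (default sd 0 for
ground-truth work; 0.1 mM in calibration runs, matching the reported
replicate scatter of ±0.03–0.12 mM/day on rates) and multiplicative
lognormal on cell counts (counting error is multiplicative; cv
configurable, default 0).  Concentration noise is **not** censored at zero:
blank-subtracted assay readings legitimately go slightly negative, and
left-censoring near-zero observations would bias the windowed rate fit low
by ~σ·φ(0)·(window weight) — about 2.5% at the lithotrophic rate scale.
The soluble fraction is reported as min(0.8·total, total), keeping
soluble ≤ total for every reading.

What the generator does *not* emulate: mechanistic Wood–Ljungdahl
intermediates, magnetite formation dynamics, pH/carbonate chemistry, lag
heterogeneity between replicates, autocorrelated assay drift, or any
stationary-phase Fe(III) reduction decoupled from growth.  Passing the
closure and calibration suites therefore shows the estimators are correct
under growth-coupled, independently-noised observations — not that real
cultures obey the piecewise model.

Synthetic proteomes: decoys are rejection-sampled from the 20-letter
alphabet until they contain zero matches of any pattern; planted proteins
interleave motif instances with spacers drawn from residues that cannot
complete any motif (no C/H/K/A/F), so planted counts are exact and verified
at generation.  Record ids are positional and shuffled; ground truth lives
only in the companion table.

## Problem sizes

Simulation-backed checks use 200 replicate simulations (noise sd 0.1 mM)
for rate calibration and a 10,000-replicate Gaussian null (4 groups × 3
values) for the Tukey family-wise error rate; the motif-scanner oracle runs
1,000 random sequences up to 120 aa.  The full test suite runs in well
under a minute; `scripts/acceptance.py` in a few seconds.

## Degenerate inputs and tie-breaks

Constant cell density → no exponential phase, error.  Zero/negative
densities → error (log fit undefined).  Windows with zero log-density
variance are skipped during selection.  Constant Fe(II) → slope 0, R²
reported as 0.  Zero diverted electrons → diversion efficiency undefined,
error.  Empty protein sequence → empty hit list, not an error.  Empty
proteome in a panel screen → all queries absent.  Duplicate (group, time)
rows, non-numeric cells and missing required columns are schema/parse
errors naming the offender.
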