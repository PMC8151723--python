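# Methods

## Model

A measured mass isotopologue distribution (MID) S̄ₘ of a fragment is modeled
as a linear mixture of component MIDs: component k is the theoretical
isotope pattern of the fragment conditional on carrying exactly k
tracer-derived labeled atoms. Collecting the components as columns of the
correction matrix CM̄̄ gives S̄ₘ = CM̄̄·S̄c, and the corrected MID is the
minimum-norm least-squares solution S̄c = CM̄̄⁺·S̄ₘ. The corrected vector has
exactly n+1 entries, where n is the count of atoms that can acquire label
(`CanAcquireLabel` restricted to the tracer element): a carbon tracer on
serine (C₃H₇NO₃) yields four components, never more.

Component MIDs are computed by polynomial convolution. Each element has an
isotope mass distribution (IMD): a dense vector of natural abundances
indexed by integer mass shift above the lightest principal isotope. The MID
of a formula is the convolution product of its atoms' IMDs; convolution is
exactly polynomial multiplication with terms of equal total mass collected,
and is mathematically equivalent to exhaustively enumerating per-atom
isotope assignments (the `brute_force_mid` test oracle does precisely that,
guarded to ≤ 12 atoms). Powers are computed by binary exponentiation; both
routes agree to < 1e-12.

In column k, k tracer-element atoms carry the labeled-atom IMD

    IMD_EL = P·E·δ(m+1) + (1 − P·E)·IMD_E,

where P is tracer purity and E the atom enrichment at labeled positions —
only the product P·E is identifiable, and both are accepted only as
fractions in [0, 1] (values > 1 are rejected with a message to divide by
100; silent percent-guessing corrupts results). The remaining tracer-element
atoms — including atoms that cannot acquire label, e.g. those contributed by
a derivatization reagent — carry the natural IMD in every column.

High-resolution acquisition means mass shifts from heavy isotopes of listed
elements are resolved from shifts of the tracer element; such elements are
modeled by collapsing their IMD to `[1]` (pure nominal mass). The tracer
element itself can never be listed as resolved. The sentinels `all` and
`none` cover the common cases. This per-element declaration follows the
fragment description rather than an instrument resolving-power model:
resolution is a property the user asserts per element.

## Numerical choices

- **Abundance table.** Natural abundances are pinned in
  `data/isotope_abundances.tsv` (IUPAC/CIAAW representative isotopic
  compositions, Berglund & Wieser 2011). Vector lengths follow the table's
  support — sulfur spans shifts 0–4 with a zero at +3 — not a fixed length.
  Tools pinning a different table edition may differ in corrected values by
  ~1e-3 or less.
- **No truncation during expansion.** Full-support vectors are carried
  through every convolution; weights below 1e-15 are kept. Truncation to a
  finite row count happens once, at matrix assembly, where the row count is
  R = max(measured length, longest column support) and shorter vectors are
  zero-padded. This keeps every column summing to one (when P·E = 1), which
  in turn makes the correction conserve total mass on exactly solvable
  systems.
- **Short measured MIDs.** When the measured MID has fewer bins than the
  theoretical support (the tryptophan example reports 3 bins against a
  12-bin support), the missing bins are assumed zero and a warning reports
  how much theoretical column mass lies in the padded rows. Zero is the
  natural estimate for unreported isotopologue bins; the alternative —
  truncating the matrix — would break column normalization.
- **Input normalization.** Measured MIDs are relative peak areas; sums that
  deviate from 1 by more than 1e-3 are renormalized with a warning rather
  than rejected, tolerating rounded user input (the worked tryptophan input
  sums to 1.000001).
- **Solver.** `numpy.linalg.lstsq` with its default rank tolerance: the
  minimum-norm least-squares solution equals applying the Moore–Penrose
  pseudo-inverse and handles square, over- and under-determined systems
  under one contract. Rank deficiency below n+1 produces a warning, not an
  error.
- **Negative components.** Corrected components can go slightly negative
  through measurement imperfection. They are reported as computed and
  flagged; zeroing them would destroy the unit sum.
- **Determinism.** The correction path contains no randomness; seeds exist
  only in the forward simulator.

Mass-shift bookkeeping is on the nominal/monoisotopic basis (lightest
principal isotope), not average mass. The formula grammar is plain
element+count tokens (`C11H13N2O2`); parentheses, hydrates, charges,
adducts, exact masses and multi-element tracers are out of scope.

## Forward simulator

`midcorrect.simulate` generates fragments over {C, H, N, O, S, Si} with a
carbon tracer by default (2–20 atoms unless asked otherwise, always at least
one tracer atom, a random subset of tracer atoms labelable) and synthesizes
measured MIDs as CM̄̄·w for a known label-count weight vector w, optionally
perturbed by independent multiplicative lognormal noise of a given
coefficient of variation and renormalized. Multiplicative noise was chosen
because MID components are relative peak areas, whose error scales with the
signal. The simulator emulates the linear mixing structure only: it does not
model chromatographic drift, detector saturation, peak-integration error
correlation, or isotope fractionation, so passing recovery tests
demonstrates correctness of the inversion, not robustness to every real
instrument artifact.

Recovery tests run 200 noise-free and 100 noisy (CV 0.5%) simulated
fragments of up to 15 atoms — small enough to keep the suite under a couple
of minutes while exercising square and overdetermined systems — and require
exact recovery (< 1e-8) and mean absolute component error < 0.01
respectively. With P·E < 1 applied consistently in both directions, recovery
matches the pure-tracer case to 1e-8: the purity correction is
self-consistent.

## Design notes and limitations

- The estimator surface (`MIDCorrector`, a scikit-learn transformer) treats
  a batch of measured MIDs as rows; `inverse_transform` is the forward
  model. The functional API (`correct`, `run_correction`) wraps it.
- Batch input files: a new record begins at each `FragmentName:` line. The
  canonical single-record layout freely interleaves blank lines, so blank
  lines cannot delimit records. Lines starting with `#` are comments.
- The 2×2-identity degenerate case (single labelable atom, everything
  resolved) arises only when the tracer element is naturally monoisotopic
  (e.g. phosphorus); for carbon the tracer element's own natural IMD always
  occupies column 0.
- Sum conservation (Σ corrected = Σ measured) is exact only for consistent
  systems; on inconsistent data the residual absorbs the difference. SSE
  against the padded measured vector is reported for diagnosis.
- Correcting very large fragments (tens of labelable atoms) is supported but
  the matrix grows accordingly; dense direct convolution is used throughout,
  which is ample at metabolite scale.
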