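# midcorrect

Natural-abundance correction of mass isotopologue distributions (MIDs) for
stable-isotope tracing experiments.

## The problem

In a stable-isotope tracing experiment, cells are fed a tracer nutrient
enriched in a heavy isotope (e.g. [U-¹³C₆]glucose) and the label that
metabolic pathways pass into downstream metabolites is read out by mass
spectrometry as an MID: the relative abundances of a compound's mass
isotopologues m+0, m+1, m+2, … But heavy isotopes also occur naturally
(¹³C at ~1.07%, ²H, ¹⁵N, ¹⁷O/¹⁸O, …), so a measured MID mixes tracer-derived
label with natural background. `midcorrect` removes that background — along
with the effects of tracer impurity and sub-unity atom enrichment — so the
corrected MID reads as the distribution of *tracer-derived* label counts.
It handles both low-resolution data and high-resolution data in which heavy
isotopes of chosen elements are resolved from those of the tracer element.

It is aimed at metabolomics and fluxomics practitioners who want a headless,
scriptable correction step in a Python pipeline, with a plain-text file
interface for one-off use.

## The model

Write the measured MID as a weighted sum of component MIDs, where component
k is the theoretical isotope pattern of the fragment guaranteed to carry
exactly k tracer-derived labeled atoms:

    S̄ₘ = CM̄̄ · S̄c        ⇒        S̄c = CM̄̄⁺ · S̄ₘ

`CM̄̄` is the correction matrix (column k = component k), `CM̄̄⁺` its
Moore–Penrose inverse, and `S̄c` the corrected MID over label counts
0…n, where n is the number of atoms that can acquire label. Each column is
built by polynomial convolution: the MID of a formula is the product of its
atoms' isotope mass distributions (IMDs) treated as polynomials, e.g.
MID(C₃H₇NO₃) = IMD_C³ ∗ IMD_H⁷ ∗ IMD_N ∗ IMD_O³. A labeled atom's IMD under
tracer purity P and atom enrichment E is

    IMD_EL = P·E·[0, 1, 0, …] + (1 − P·E)·IMD_E

and high-resolution acquisition is modeled by collapsing the IMD of every
resolved non-tracer element to 100% nominal mass, `[1]`. The system is
solved by minimum-norm least squares (equivalent to applying the
pseudo-inverse), which covers square, over- and under-determined cases;
negative corrected components are reported as computed, never clipped, so
the unit sum is preserved.

Natural abundances are pinned in
`src/midcorrect/data/isotope_abundances.tsv` (tab-separated
`element, mass_shift, abundance`; IUPAC/CIAAW representative values), so
results are bit-stable.

## Worked example

Correct the MID of protonated tryptophan measured on a high-resolution
instrument from a sample never exposed to tracer. Input file `trp.txt`:

```
FragmentName: TryptophanProtonated
FragmentFormula: C11H13N2O2
CanAcquireLabel: C11H13N2O2
MIDm: 0.88885 0.106829 0.004322
LabeledElement: C
TracerEnrichment: 1
LabelEnrichment: 1
HighRes: N O H
```

```sh
midcorrect trp.txt
```

prints

```
Fragment: TryptophanProtonated
MIDc: 1.000508 0.001202 -0.001667 -0.000048 0.000006 -0.000000 0.000000 -0.000000 0.000000 -0.000000 0.000000 0.000000
SSE: 6.776128e-30
Warning: measured MID has 3 bins but the theoretical support spans 12; missing bins assumed zero (up to 100.000% of a column's mass lies in the padded rows)
Warning: corrected MID has negative components (reported as computed, not clipped): m+2: -1.667e-03, m+3: -4.786e-05, m+5: -2.273e-07, m+7: -5.195e-11, m+9: -1.863e-15
```

The corrected m+0 component is ~1.0005: essentially all tryptophan carries
zero tracer-derived labels, as expected for an unlabeled sample — the
measured m+1 and m+2 signal was natural ¹³C. The tiny negative components
reflect measurement rounding and are reported verbatim. The same result is
available programmatically:

```python
from midcorrect import MIDCorrector

corr = MIDCorrector("C11H13N2O2", labeled_element="C", high_res="N O H").fit()
result = corr.correct([0.88885, 0.106829, 0.004322], name="TryptophanProtonated")
result.mid_c, result.sse
```

`MIDCorrector` is a scikit-learn transformer: `transform` corrects a matrix
of measured MIDs row-wise and `inverse_transform` runs the forward model.
A forward simulator with known ground truth is available as
`midcorrect-sim --seed N --noise CV --out PATH`.

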