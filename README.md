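# epitope-audit

Antibody-panel auditing for CITE-seq studies of enzymatically digested
tissue.

## The problem

Single-cell studies of tissue-resident immune cells (pancreatic islets in
particular) require enzymatic digestion to obtain cell suspensions, and the
proteases involved can destroy the very surface epitopes that
antibody-based assays — flow cytometry and CITE-seq antibody-derived tags
(ADTs) — rely on. Before committing an antibody panel to sequencing, three
questions have to be answered per antibody clone:

1. **Is the epitope digestion-sensitive?** Stain paired digested/undigested
   cell aliquots, gate on the undigested control, and quantify the relative
   change in percent-positive staining.
2. **What staining concentration is optimal?** Titrate each antibody at
   0.5×, 1× and 2× the vendor-recommended concentration and pick the
   cheapest point that keeps a positive peak with the least nonspecific
   background.
3. **Which ADT counts are real?** After sequencing, remove low-quality
   cells and antibody aggregates, and zero out per-antibody background
   counts below a minimum cut-off.

This package implements those three computations as a tested, reusable
pipeline, together with a synthetic flow-cytometry/ADT generator that
provides ground truth for every rule.

## The core statistic

For one replicate with percent-positive staining `p_u` (undigested) and
`p_d` (digested, scored with the *same* gate fit on the undigested sample):

```
RC = 100 · (p_u − p_d) / p_u
```

RC is at most 100 (complete loss) and unbounded below (staining can
increase). A replicate is **sensitive** when RC ≥ 50, **partially
sensitive** when 25 ≤ RC < 50, and **insensitive** otherwise; replicates
with ≤ 5 % undigested positivity (rare populations, where the ratio
inflates) are instead scored by visibility of a digested positive
population. A clone's category is the strict majority over its included
replicates, with majority-free splits called partially sensitive. Replicates
are included only when a clone was measured in ≥ 2 donors, the undigested
sample shows positive cells, and (for activation-dependent markers) the
CD69 activation control is adequate.

Titration points are scored with two gates — a 99.5 % quantile of the
unstained control (`signal + noise`) and a KDE-valley gate on the stained
sample itself (`signal`) — and the selected concentration minimizes
signal-plus-noise among points that retain a positive peak.

## Worked example

```python
from epitope_audit import (MarkerSimSpec, simulate_digestion_pair,
                           apply_gate_pair, relative_change, classify_replicate)

spec = MarkerSimSpec(marker="CD8a", clone="RPA-T8", cleavage_fraction=0.6)
undigested, digested = simulate_digestion_pair(spec, n_events=20_000, seed=42)
m = apply_gate_pair(undigested, digested, "CD8a")
rc = relative_change(m.pct_pos_undigested, m.pct_pos_digested)
call = classify_replicate(m)
print(f"undigested: {m.pct_pos_undigested:.2f}% positive")
print(f"digested:   {m.pct_pos_digested:.2f}% positive")
print(f"RC = {rc:.1f}  ->  {call.category.value}")
```

prints

```
undigested: 29.19% positive
digested:   12.12% positive
RC = 58.5  ->  sensitive
```

The simulated clone cleaves 60 % of its epitopes during digestion; the
automated KDE-valley gate on the undigested aliquot recovers ~29 % positive
cells (the true positive fraction is 30 %), the shared gate sees the thinned
positive population in the digested aliquot, and the resulting RC ≈ 58.5
(expectation 60 under binomial thinning) crosses the ≥ 50 sensitivity
threshold.

A command-line interface mirrors the library
(`epitope-audit simulate|gate|sensitivity|titrate|adt-qc|report`); for
example `epitope-audit report` reclassifies the bundled published per-clone
table and reprints the titration bookkeeping.

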