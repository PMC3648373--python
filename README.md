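# jitrefine

Post-processing for protein-complex prediction. Clustering algorithms
(CMC, DPClus, IPCA, CPM, MCL, core–attachment methods, …) find dense
subgraphs of a protein–protein interaction network (PPIN), but proteins
only interact while they are in their active form, and complexes assemble
*just in time*: at each time point of a contiguous interval the newly
active subunits dock onto the already-assembled core. `jitrefine` uses a
cyclic gene-expression time course to deduce each protein's active time
points, tests whether a complex could assemble under that just-in-time
model, and refines predicted complexes by removing members that are never
co-active with the rest — typically spurious proteins dragged in by
network topology alone.

## The model

**Activity (3-sigma principle).** For a protein *p* with expression
values *EV₁..EVₙ* over one cycle (multiple cycles are averaged down to
one), let *u* be the mean and *σ²* the population variance. With the
fluctuation weight *F = 1/(1+σ²)*, the activity threshold is the blend

&nbsp;&nbsp;&nbsp;&nbsp;*Active_TH = u·F + (u + 3σ)·(1 − F)*,

and *Active(p) = { i : EVᵢ ≥ Active_TH }*. Flat curves are active
everywhere; the active points of an extremely fluctuating curve may be
uninferrable (threshold above every value), in which case *p* gets the
wildcard time point 0 — "potentially active at any time".

**Formation.** With *APᵢ(C)* the members of complex *C* active at time
point *i*, *C* can form in the interval *[S, S+K]* iff every step's
running union intersects the next *AP* non-emptily and the union over the
interval is all of *C*. The co-active rate *OL(C)* averages the per-step
overlaps *|assembled ∩ AP| / min(|assembled|, |AP|)*.

**Refinement.** Each predicted complex of size ≥ 3 is *split* into
connected sub-clusters of co-active members, one group per time point of
its active time set, then *assembled*: sub-clusters at adjacent time
points merge when their overlap *OV(a,b) = |a∩b| / min(|a|,|b|)* reaches
a threshold *T* (default 0.6); wildcard sub-clusters may merge at any
time point. Surviving sub-clusters of size ≥ 2 become the refined
complexes, deduplicated.

**Evaluation.** A predicted complex matches a known one when the overlap
score *OS = |∩|² / (|Pc|·|Kc|)* is ≥ 0.2 (perfect when OS = 1). From the
match counts follow MKC/MPC, sensitivity *Sn*, specificity *Sp* and the
f-measure (their harmonic mean).

## Worked example

A predicted complex {A,B,C,D,E} over a 4-point cycle, with edges
A–C, A–E, C–E, A–B, B–E, C–D and activities A:{1,2}, B:{2,3,4}, C:{1},
D:{4}, E:{1,2}:

```python
import networkx as nx
from jitrefine import ActivityTable, ComplexCatalog, refine_catalog
from jitrefine.formation import find_formation

activity = ActivityTable(
    {"A": {1, 2}, "B": {2, 3, 4}, "C": {1}, "D": {4}, "E": {1, 2}}, n=4)
network = nx.Graph([("A","C"), ("A","E"), ("C","E"), ("A","B"), ("B","E"), ("C","D")])
catalog = ComplexCatalog([frozenset("ABCDE")])

res = find_formation(frozenset("ABCDE"), activity)
print(res.formable, res.best_interval, round(res.best_overlap, 4))
# True (1, 3) 0.7222

refined = refine_catalog(catalog, network, activity)
print([sorted(c) for c in refined])
# [['A', 'B', 'C', 'E']]
```

The complex can assemble over time points 1–4 ({A,C,E} → +B → … ) with a
mean per-step co-active rate of 13/18 ≈ 0.7222. Refinement keeps the
chain of overlapping sub-clusters and discards D, which is active only at
time 4 and not connected to the members active there.

The same pipeline is available from a shell:

```sh
jitrefine simulate --outdir demo --n-complexes 50 --seed 7
jitrefine refine --network demo/edges.tsv --expression demo/expr.tsv \
    --complexes demo/complexes_contaminated.txt --t 0.6 --out demo/refined.txt
jitrefine evaluate --predicted demo/refined.txt --known demo/complexes_true.txt
```

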