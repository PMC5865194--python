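# antcomp

Competitive-interaction analysis of diverse ground-dwelling ant communities
from bait-card surveys.

## The problem

When tropical forest is disturbed (e.g. selectively logged), ant community
composition changes — but composition alone says little about the
*interactive processes* that structure the community. `antcomp` implements a
full analysis chain for surveys that pair two habitats (primary vs. logged
forest) and record, per site, both leaf-litter occupancy (pooled Winkler-bag
extractions) and 40-minute filmed bait-card sessions in which every
genus–genus encounter is scored behaviourally. It answers: did the
*dominance hierarchy* — who is aggressive over whom at a contested food
resource — stay fixed across habitats, shift with occupancy, or re-wire
idiosyncratically?

It is written for community ecologists working with genus-level interaction
data at baits, and for anyone who needs a tested reference implementation of
dominance-score analysis on observational encounter data.

## The scoring model

Each observed interaction between genera *i* and *j* gets a per-participant
**aggression score**: 0 = submissive, 1 = neutral, 2 = aggressive. An
interaction is *competitive* iff at least one participant was aggressive.
Per habitat *f*, the pairwise mean score

&nbsp;&nbsp;&nbsp;&nbsp;*s̄<sub>ij</sub><sup>f</sup>* = mean score of *i* over all its events against *j*

is computed over the genera that interacted with **more than three** other
genera. The **aggression-score change** is Δ*s<sub>ij</sub>* =
*s̄<sub>ij</sub>*<sup>logged</sup> − *s̄<sub>ij</sub>*<sup>primary</sup>
(defined only where both habitats have ≥ 3 events for the pair), and each
genus's overall competitive shift is the sample-size-weighted mean of its
Δ*s<sub>ij</sub>*. Directed networks (aggressor → submissive, edge weight =
encounter count, drawn width = weight/2 pt) and per-card rates (competitive
interactions · min⁻¹, per-capita counts) complete the picture, and
between-habitat contrasts use site as the independent replicate
(10 sites per habitat, 3 × 9 sampling grids per site; 30 pooled litter
units + 90 camera cards = 120 analysed units per habitat).

A synthetic survey generator with a latent dominance hierarchy *d* (encounter
outcomes follow a logistic contrast, P(*i* beats *j*) =
logistic(β·(*d<sub>i</sub>* − *d<sub>j</sub>*))) makes every stage testable
end-to-end, including recovery of a deliberately *re-wired* hierarchy.

## Worked example

Simulate the *rewired* scenario (logged-forest hierarchy is a random
permutation of the primary one, occupancy changes independently) and run the
full pipeline:

```sh
antcomp run-all --scenario rewired --seed 42 --out demo/
```

or in Python:

```python
from antcomp.pipeline import RunConfig, run_all

rep = run_all(RunConfig(mode="scenario", scenario="rewired", seed=42, out_dir="demo"))
s = rep.stats
print(rep.dataset_summary["n_events"])                          # 9039
print(round(s["rank_occupancy_spearman"]["rho"], 3))            # 0.275
print(round(s["aggression_vs_occupancy_spearman"]["rho"], 3))   # 0.211
print(round(s["rate_contrast"]["p"], 3))                        # 0.525
```

Reading those numbers: 9 039 encounters were generated across 180 bait
cards. The rank occupancy of the 17 focal genera is only weakly correlated
between habitats (ρ = 0.275, composition changed), the per-genus
aggression-score change is uncorrelated with occupancy change (ρ = 0.211,
p = 0.42 — the signature of a re-wired hierarchy rather than an
occupancy-driven one), and the rate of competitive interactions does not
differ between habitats (p = 0.53; the scenario changes *who wins*, not how
often ants fight). `demo/` also contains `occupancy.csv`,
`aggression_{primary,logged}.csv`, `score_change.csv`, GraphML/TSV networks
with their between-habitat diff, figure-shaped summary tables
(`table_*.csv`) and a consolidated `report.json`.

The same stages run on real data from CSV files
(`units.csv`, `presences.csv`, `arrivals.csv`, `interactions.csv`; see
`antcomp run-all --in DIR`, with a YAML column-mapping config for deposited
datasets whose headers differ).

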