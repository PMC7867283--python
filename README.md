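# insectscreen

Consensus ligand- and structure-based virtual screening for prioritizing
multi-target, low-toxicity bioinsecticide candidates.

Natural-product screening campaigns against crop pests such as the cotton
aphid (*Aphis gossypii*) and the fruit fly (*Drosophila melanogaster*)
typically combine a ligand-based activity model with structure-based
docking against several insect enzyme targets — acetylcholinesterase
(AChE), the nicotinic acetylcholine receptor (nAChR), and chitinase (Cht).
`insectscreen` implements that workflow as a tested, reusable library plus
CLI: it is aimed at cheminformaticians who have descriptor matrices,
docking score tables, and toxicity predictions in hand and want a
reproducible, auditable path from those inputs to a ranked multi-target
candidate list.

## The method

**QSAR channel.** Compounds with measured potency are labelled active when
pLC50 ≥ 4.5. A random forest (250 trees, one seed) is trained on a
stratified 80/20 split of a compounds × descriptors matrix and evaluated by
sensitivity, specificity, accuracy, PPV, NPV, the area under the ROC curve,
and the Matthews correlation coefficient

```
MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))
```

Prediction reliability is guarded by a Euclidean applicability domain,
`APD = d̄ + Z·σ` (Z = 0.5), where d̄ and σ summarize the retained training
pairwise distances; queries farther than APD from every training compound
are flagged out-of-domain.

**Docking channel.** Per enzyme, ligand binding energies (MolDock-style,
more negative = stronger) are normalized against the best ligand of the
screened set: `Prob_Dc = E_lig / E_mlig`, defined only when the ligand
binds more strongly than the enzyme's reference insecticide
(`E_lig < E_inib`). Ligand efficiency (score per heavy atom) is carried
along for inspection.

**Consensus.** The channels fuse into

```
Prob_Comb = (Prob_Dc + (1 + ESP)·P_Activity) / (2 + ESP)
```

with ESP the QSAR model's specificity statistic. Selection is strict
(`Prob_Comb > 0.5`); a compound is *multi-target* when selected at every
required enzyme; finally any compound with a predicted toxicity risk
(mutagenic, tumorigenic, reproductive, irritant — even a "low" flag) is
removed.

The package also ships a seeded synthetic-data generator (labelled
libraries with class-separable descriptor blocks, activity-coupled docking
tables, toxicity profiles at a given clean rate) so the entire pipeline is
testable offline, and a small alignment module for the supporting
conservation statistics (percent identity, active-site residue sharing).

## Worked example

The bundle includes the two reference campaigns: 15 aphid candidates
screened at three enzymes and 37 fruit-fly candidates at two, with docking
scores, reported consensus probabilities, and toxicity profiles.

```python
from insectscreen import datasets, pipeline

for species in ("aphis", "drosophila"):
    report = pipeline.screen_with_reported_consensus(
        datasets.load_docking_tables(species),
        datasets.load_consensus_table(species),
        datasets.required_enzymes(species),
        datasets.load_toxicity_profiles(species),
    )
    print(species, len(report.multitarget), len(report.risk_free))
```

prints

```
aphis 15 11
drosophila 37 27
```

— all 15 aphid candidates pass the docking condition and the strict
consensus rule at AChE, nAChR, and Cht, and 11 survive the toxicity filter
(compounds 1800, 1804, 1836, 1840, 1842, 1845, 1910, 1931, 1932, 1933,
1934); for the fruit fly, 37 candidates are multi-target at AChE and nAChR
and 27 are risk-free.

The same screen is available from the shell:

```
insectscreen screen --docking docking.csv --consensus consensus.csv \
    --toxicity toxicity.csv --enzymes ache,nachr,cht -o screen_out
```

and `insectscreen simulate` writes a complete synthetic input set for
experimentation.

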