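# nasfinder

Tissue-specific active sub-network identification and activity ranking for
transcriptomics.

Given a module of differentially expressed genes (a DEG module: co-expressed,
functionally related genes from one contrast), `nasfinder` finds the
sub-networks of an annotated human interactome that connect the module to its
closest upstream regulator molecules — receptors by default — and ranks those
sub-networks by how strongly the experiment activates them. It is aimed at
systems biologists who want pathways scored by *activity* relative to each
other, not merely ranked by enrichment p-value.

## Method

1. **Network preparation.** The reference interactome (an undirected
   gene–gene edge list with molecular-role annotations) is optionally
   expanded with supplementary interactions incident to module genes, and
   pruned to one tissue: genes tissue-enriched (TE) or group-enriched (GE)
   in a *different* tissue are removed unless they carry a TE/GE/TEn class
   in the selected tissue.
2. **Regulator selection.** Breadth-first search from each module gene finds
   the closest nodes of the chosen role (minimal hop distance > 0); the
   union of these, plus role-labelled genes inside the module itself
   (distance 0), are the main regulators.
3. **Path retention.** Every edge *i–j* is weighted with the common linkage
   index CL<sub>ij</sub> = (D<sub>ij</sub> + I<sub>ij</sub>)/(n<sub>i</sub> + n<sub>j</sub>),
   where D<sub>ij</sub> is the adjacency indicator, I<sub>ij</sub> the number
   of shared neighbors and n<sub>k</sub> the degree; non-adjacent pairs score 0.
   For each regulator, the highest-CL-product path of at most 9 edges to each
   module gene is retained; the retained paths are merged into a minimal
   sub-network, optionally extended with every node's 1-neighbors.
4. **Contextual enrichment.** The module genes inside the sub-network form
   the target set *T*, compared against canonical pathways *R* (GMT
   collections, e.g. KEGG/BioCarta/PID/Reactome) by the Sorensen-Dice index
   2|T∩R|/(|T|+|R|) and an upper-tail hypergeometric p-value (ranking only —
   no multiple-testing correction).
5. **Activity scoring.** Each selected sub-network gets a network activity
   score NAS = (MNF × CDR)/NGR, with CDR the overlap between *T* and the
   reference signature, NGR the signature size and MNF the mean min–max
   normalized fold change (signed, over all DEGs of the contrast) of the
   overlap genes. Results are ranked by NAS and same-named pathways are
   merged into consolidated pathways.

The package also ships the benchmarking harness used to compare enrichment
tools (confusion counts at p < 0.05 under top-10/top-100/all windows, the
four standard measures, cross-tool z-score aggregation) and a deterministic
synthetic-data generator that plants a known active pathway in a modular
interactome so the whole pipeline can be validated without any downloads.

## Worked example

```python
from nasfinder import (SyntheticScenario, generate_network, generate_module,
                       analyze_module)

sc = SyntheticScenario(seed=7)                 # 240-gene modular interactome
net, tissues = generate_network(sc)
synth = generate_module(sc, net)               # plants one active cluster
analysis = analyze_module(net, synth.module, synth.collection)

print(f"planted pathway: {synth.planted_name}")
for res in analysis.ranked_selected[:5]:
    print(f"{res.subnetwork.regulator:8s} {res.reference.name:8s} "
          f"dice={res.dice:.2f} p={res.p_value:.2e} NAS={res.nas:.3f}")
```

```
planted pathway: PWY_C4
G0100    PWY_C4   dice=1.00 p=2.26e-10 NAS=0.928
G0103    PWY_C4   dice=1.00 p=2.26e-10 NAS=0.928
G0109    PWY_C4   dice=1.00 p=2.26e-10 NAS=0.928
G0069    PWY_C3   dice=1.00 p=2.26e-10 NAS=0.075
G0080    PWY_C3   dice=1.00 p=2.26e-10 NAS=0.075
```

Three receptors near the planted cluster each recover pathway `PWY_C4` with
perfect Dice overlap and NAS ≈ 0.93: its genes are fully covered and carry
strong, consistently positive fold changes. The structurally identical decoy
clusters are equally well *covered* (same Dice, same p) but score an order of
magnitude lower NAS because their genes are not differentially expressed —
exactly the distinction an activity score adds over enrichment p-values.

The same analysis is available from the shell:

```sh
nasfinder simulate --seed 7 --out-dir sim
nasfinder run --edges sim/edges.tsv --roles sim/roles.tsv \
    --modules sim/module.tsv --gmt sim/pathways.gmt --out-dir out
```

which writes `results.tsv`, `consolidated.tsv`, an `audit.json` with input
hashes and parameters, and one GraphML (or XGMML) file per selected
sub-network. `nasfinder benchmark` scores ranked tool outputs against a
truth table.

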