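# phytonet

Desk-scale systems pharmacology for herbal medicines: from a table of a
herb's phytochemicals to the disease-relevant protein targets they hit,
the organs those targets are expressed in, and the pathways they crowd
into.

Multi-compound herbs act through many weak interactions rather than one
strong one, so the standard workflow in this field is network-based:

1. **ADME screening** — keep compounds that are plausibly drug-like and
   bioavailable: oral bioavailability OB ≥ 15 %, blood–brain-barrier
   score BBB ≥ −0.3, drug-likeness DL ≥ 0.1 (each threshold tunable; a
   literature whitelist can re-admit well-documented compounds that fail).
   BBB scores also classify penetration: < −0.3 non-penetrating,
   −0.3…+0.3 moderate, > +0.3 strong.
2. **Compound–target (C-T) network** — a bipartite graph of screened
   compounds and their fished protein targets; degree centrality is the
   hub statistic.
3. **Disease restriction (C-T-D)** — intersect the target side with a
   disease gene set and prune compounds left without edges.
4. **Tissue localization** — from a gene × tissue expression matrix,
   locate each target in every tissue where its expression strictly
   exceeds its own mean (above-mean rule), or position it in its
   single highest-expression tissue (argmax rule).
5. **Over-representation analysis (ORA)** — for a query gene set of size
   *n* against a background of *N* genes, *M* of which belong to an
   annotation set and *m* to the overlap, the raw P value is the
   hypergeometric upper tail

   P = 1 − Σ_{i=0}^{m−1} C(M,i)·C(N−M,n−i) / C(N,n),

   adjusted across sets by Benjamini–Hochberg; a set is significant when
   p_raw < 0.01 and p_adj ≤ 0.05.

A synthetic-data module generates every input with known ground truth
(engineered pass/fail screening splits, power-law interaction degrees,
planted enriched sets, planted tissue elevation), so the entire pipeline
is testable without any database access. A 32-compound *Acori
Tatarinowii Rhizoma* property table ships as packaged reference data.

## Worked example

```python
import phytonet as pn

table = pn.load_reference_compounds()          # 32 compounds, OB/BBB/DL
filtered, audit = pn.filter_compounds(table)   # default thresholds
print(len(filtered), audit.failed)
# 27 ['M13', 'M16', 'M21', 'M24', 'M29']   (all five fail on DL < 0.1)

wl = {"M13", "M21", "M24", "M29"}              # literature whitelist
filtered, _ = pn.filter_compounds(table, whitelist=wl)
print(len(filtered))
# 31
```

The five excluded compounds all fail the drug-likeness axis alone; the
whitelist re-admits four of them on literature evidence, leaving 31.

A full synthetic run from the shell:

```bash
phytonet synth --seed 7 --outdir data/
phytonet run --config pipeline.yaml   # paths to the data/ files
```

which prints the per-stage summary, e.g.

```
"screen":  {"input_compounds": 105, "passed_thresholds": 30, ...}
"ct_network": {"n_compounds": 29, "n_targets": 165, "n_edges": 268, ...}
```

— 105 generated compounds screen down to 30, one of which has no target
rows, and the surviving 29 span a 194-node network. Every stage is also
a standalone subcommand (`phytonet filter|network|locate|enrich`).

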