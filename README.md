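# pubclass

Tools for analysing plant U-box (PUB) E3 ubiquitin ligase gene families:
rule-based classification of proteins into the ten PUB domain-architecture
classes, tandem-duplicate detection on genome loci, neighbor-joining
phylogenetics with bootstrap support, and ΔΔCt qPCR stress-response calling —
plus seeded synthetic-data generators so the whole pipeline runs and is
testable with no external downloads.

## Who this is for

Groups cataloguing U-box E3 ligases in a plant genome (the package ships the
67-gene barley *HvPUB* catalog as a worked reference) who want a reproducible,
auditable path from domain annotations to class assignments, family trees and
stress-expression calls, instead of ad-hoc spreadsheet rules.

## The rules and models at the core

**Classification.** A protein with no U-box domain is UNCLASSIFIED. Among
U-box proteins, the accessory domain decides the class by precedence
(rarer, more specific domains win): UFD2 → I; cyclophilin → III; TPR+kinase →
VIII; kinase (PKc and/or STK_N) → IV; TPR → VII; WD40 → VI; MIF4G → IX;
DJ-1 → X; ARM/HEAT repeats → II; nothing else → V. Class II splits at the
N-terminal quarter: with the first U-box's midpoint *m* and protein length
*L*, the protein is II-b if *m* ≤ 0.25 *L* (no UND region) and II-a otherwise.
Class IV splits by kinase-domain content (both / PKc only / STK_N only). A
degenerate ARM-like (formerly "GKL") region does **not** qualify for Class II
and such proteins fall to Class V; a config switch restores the superseded
grouping for comparison. Every rule that fires is recorded in a rationale
trace.

**Tandem duplicates.** Within each chromosome, genes are chained whenever the
gap to the previous gene (next start − previous end) is ≤ 100 kb (default);
maximal chains of ≥ 2 genes are reported.

**Phylogenetics.** Uncorrected p-distances (pairwise or complete gap
deletion; Poisson correction −ln(1−p) by flag) feed Saitou–Nei neighbor
joining: join the pair minimising Q(i,j) = (n−2)d(i,j) − Σd(i,·) − Σd(j,·),
branch lengths from the rate-corrected split formula, negative lengths
clamped to zero with the deficit moved to the sister edge. Bootstrap support
is the percentage of column-resampled replicate trees (default 1000)
containing each internal bipartition of the full-data tree.

**Expression.** Technical replicates of Cq are averaged; ΔCt = Cq(target) −
Cq(reference) per (condition, biological replicate); ΔΔCt = ΔCt(treated) −
mean ΔCt(control); fold = 2^(−ΔΔCt). Significance is a two-sided
pooled-variance Student t-test on ΔCt across biological replicates
(\*P < 0.05, \*\*P < 0.01). Calls: induced if fold ≥ 2 (inclusive), strongly
suppressed if fold ≤ 1/3, each gated on significance by default.

## Worked example

```python
import pubclass as pc

records = pc.generate_architectures(seed=1)   # 67 synthetic barley proteins
result = pc.classify_proteome(records)
print(result.summary_frame().to_string(index=False))
print(pc.find_tandem_clusters(pc.load_barley_catalog(), max_gap_bp=100_000))

cq = pc.simulate_cq_table(pc.CqDesign(genes={"HvPUB64": 1.8, "HvPUB18": -2.1}), seed=1)
results, _ = pc.call_stress_response(pc.analyze_expression(cq))
for r in results:
    print(f"{r.gene}: fold={r.fold:.2f} p={r.p_value:.4f}{r.stars} call={r.call}")
```

prints

```
        class  count
            I      1
           II     27
          III      1
           IV     11
            V     21
           VI      3
          VII      2
         VIII      0
           IX      0
            X      1
 UNCLASSIFIED      0
 subclass IIa     19
 subclass IIb      8
subclass IV_1      3
subclass IV_2      5
subclass IV_3      3

[['HvPUB11', 'HvPUB12'], ['HvPUB58', 'HvPUB59']]

HvPUB18: fold=0.23 p=0.0001** call=down
HvPUB64: fold=3.96 p=0.0000** call=up
```

The class table is the barley family structure (1 Class I, 27 Class II of
which 19 II-a, 11 Class IV, 21 Class V, 3 Class VI, 2 Class VII, 1 each of
III and X — 67 in total). The two gene pairs are the tandem duplicates found
on the printed barley loci at the 100 kb threshold (gaps of 62,584 and
53,809 bp). The expression lines show a planted ~3.5-fold induction and
~4-fold suppression recovered with high significance.

## Command line

```
pubclass classify   --domains dom.tsv --format simple_tsv --out assignments.tsv
pubclass phylo      --alignment aln.fasta --bootstrap 1000 --seed 42 --out tree.nwk
pubclass expression --cq cq.csv --reference actin --out calls.tsv
pubclass simulate   architectures|alignment|cq --seed N --out ...
pubclass run        --config run.yaml --outdir out/
```

`pubclass run` emits `assignments.tsv`, `summary.tsv`, `clusters.tsv`,
optionally `tree.nwk` and `calls.tsv`, and a joined `report.tsv` with one row
per gene: gene, class (catalog and assigned), subclass, rationale, EST
library counts (abiotic / biotic / generative / vegetative), tandem-cluster
membership, and the stress call. Every output header carries the seed and a
config hash; a fixed seed makes runs byte-identical.

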