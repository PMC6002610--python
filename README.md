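# eeseq

Analysis toolkit for paired **environmental-enrichment (EE) versus barren
(B)** housing RNA-seq designs — the kind of experiment where littermate
pairs of animals are housed under enriched or barren conditions and brain
gene expression is profiled at short post-stimulation timepoints. It is
aimed at researchers who want the full set-level analysis of such a design
as a reproducible, scriptable pipeline rather than a chain of GUI tools:

* **expression filtering** — genes below 2 TPM in one or both treatment
  groups are removed as noise;
* **TMM-normalised differential expression** with threshold calling — a
  gene is DE when |fold change| ≥ 1.2 *and* p < 0.02 (no FDR correction;
  the double threshold is the conservatism);
* **gene-signature randomisation tests** — the core statistic: for a
  directed signature of x genes (e.g. immediate-early genes expected *up*,
  microglial genes expected *down*), draw s = 10,000 random x-gene subsets
  from all quantified genes and count the subsets q whose median fold
  change the signature beats in its direction; with r = s − q,

  &nbsp;&nbsp;&nbsp;&nbsp;**p = (r + 1) / (s + 1)**,

  so the attainable floor is 1/10001 = 9.99e-05;
* **correlation networks** — sample-sample and gene-gene Pearson graphs at
  fixed thresholds (0.99 all-gene samples, 0.93 DE-gene samples, 0.90
  genes), clustered with a from-scratch **Markov Cluster (MCL)** algorithm
  at inflation 2.2;
* a **synthetic-data generator** that emulates the design (6 litters ×
  {EE, B} × {1 h, 4 h}, negative-binomial counts, shared litter effects, a
  transient IEG induction at 1 h and a persistent microglial depression at
  both timepoints) with full ground truth, so every stage is testable.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Run the whole pipeline on a simulated experiment (2,000 genes, 24 samples;
IEG signature +1 log2 at 1 h only, microglial signature −1 log2 at both
timepoints):

```python
from eeseq import SimConfig, PipelineConfig, run_pipeline

cfg = PipelineConfig(sim=SimConfig(seed=None), s=10_000, seed=11,
                     outdir="out")
rep = run_pipeline(cfg)
print("retained genes:", len(rep.universe))
for name, res in rep.de_results.items():
    print(f"{name}: up={res.n_up} down={res.n_down}")
for name, rows in rep.randomization.items():
    for r in rows:
        print(f"{name}  {r.signature_name:10s} ({r.direction:4s})  "
              f"x={r.x:<3d} q={r.q:<5d} p={r.p_value:.3g}")
```

prints

```
retained genes: 1980
1h_EE_vs_B: up=23 down=46
4h_EE_vs_B: up=10 down=48
all_EE_vs_B: up=18 down=56
1h_EE_vs_B  IEG        (up  )  x=11  q=10000 p=0.0001
1h_EE_vs_B  microglia  (down)  x=49  q=10000 p=0.0001
4h_EE_vs_B  IEG        (up  )  x=11  q=8085  p=0.192
4h_EE_vs_B  microglia  (down)  x=49  q=10000 p=0.0001
all_EE_vs_B  IEG        (up  )  x=11  q=10000 p=0.0001
all_EE_vs_B  microglia  (down)  x=49  q=10000 p=0.0001
```

Reading this: 1,980 of 2,000 genes survive the 2-TPM filter. At 1 h the
11-gene IEG signature beats all 10,000 random subsets (q = s), hitting the
p-value floor 1/10001 ≈ 1e-04 — the injected transient induction is
recovered; by 4 h it is indistinguishable from a random gene set
(p = 0.192). The microglial signature stays at the floor in every
comparison, matching its injected persistent down-regulation. The DE counts
(e.g. 23 up / 46 down at 1 h) reflect the 11 + 52 perturbed genes plus the
expected handful of threshold false positives. `out/` now holds the DE
tables, randomisation results, GraphML networks with MCL cluster labels,
and a `manifest.json` from which the run is byte-exactly reproducible.

The same analysis from the shell:

```sh
eeseq simulate --out sim --seed 3
eeseq run --config pipeline.yaml --out out --seed 11
eeseq test-signature --fold-changes out/de_1h_EE_vs_B.tsv \
      --signatures sim/signatures.gmt --s 10000 --seed 1
eeseq network --matrix sim/tpm.tsv --samples sim/samples.tsv \
      --axis samples --threshold 0.99 --out net.graphml
```

The model-style API is available for the individual pieces:
`DifferentialExpression(counts, samples, ("EE","1h"), ("B","1h")).fit()`
returns a results object with `.table`, `.n_up`/`.n_down` and `.summary()`;
`SignatureRandomizationTest(fold_changes, signature, s=10_000, seed=1).fit()`
returns the x/s/q/r/p record shown above.

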