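# microcca

Salience-weighted **common components analysis** (CCA) for 16S rRNA OTU
count tables, built for anaerobic co-digestion experiments where microbial
communities respond to a substrate-mixture gradient.

Classic single-OTU views of amplicon data either restrict attention to the
most abundant taxa or analyse Archaea and Bacteria separately, and miss the
*joint* response of dominant and sub-dominant organisms. This package
implements an ordination pipeline that keeps all sufficiently prevalent
OTUs and extracts orthogonal *common components*, each grouping the OTUs
that disperse the samples the same way — read as one co-responding
microbial community:

1. **Total-sum scaling** — counts → per-sample relative abundances.
2. **Prevalence partition** — OTUs present in < 2 samples (configurable)
   are *scarce* and set aside; the *ubiquitous* rest proceed.
3. **Pareto scaling** — column centering and division by √(standard
   deviation).
4. **CCA** — for each component, a salience λ_j per OTU is iterated to the
   fixed point λ_j ∝ (x_jᵀt)², Σλ_j = 1, with t the dominant eigenvector of
   W = Σ_j λ_j x_j x_jᵀ; scores t·√μ, loadings Xᵀt, deflation X ← X − ttᵀX.
5. **S-plot selection** — OTUs with |cov(x_j, t)| above one standard
   deviation of the covariance vector are the component's community.
6. **Interpretation** — richness, a 1 %-threshold domain overview, taxonomy
   cladograms (Newick + GraPhlAn-style annotations) shaded by mean clade
   loading, and Pearson correlations of scores against digester performance
   markers (α_app, NH4+, acetate, …).

A synthetic-data generator with planted OTU groups, latent gradients and
coupled markers provides ground truth for parameter-recovery testing. See
`docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from microcca import *
from microcca.synthetic import SyntheticScenario, generate, recovery_metrics

data = generate(SyntheticScenario(seed=1))          # 600 OTUs x 10 samples
abund = total_sum_scale(data.otu_table)
part = prevalence_partition(abund, min_samples=2)
print(f"{len(part.ubiquitous)} ubiquitous / {len(part.scarce)} scarce OTUs")
model = fit_cca(pareto_scale(abund, part.ubiquitous), n_components=2)
print("explained:", np.round(model.explained.to_numpy(), 3))
selection = select_components(model)
print("selected:", {f"CC{c}": len(selection.otus(c)) for c in selection.tables})
report = correlation_report(model, abund, data.taxonomy, data.metadata,
                            data.markers, ubiquitous=part.ubiquitous)
print(report.table[["series", "target", "r", "n"]].head(6).to_string(index=False))
met = recovery_metrics(data.truth, model, selection)
print(f"gradient |r| = {met.score_gradient_r:.3f}, selection F1 = {met.f1:.3f}")
```

prints

```
184 ubiquitous / 416 scarce OTUs
explained: [0.569 0.196]
selected: {'CC1': 90, 'CC2': 49}
series    target         r  n
   CC1 alpha_app  0.993945 10
   CC1       nh4 -0.995509 10
   CC1   acetate -0.029092 10
   CC2 alpha_app  0.073298 10
   CC2       nh4  0.046919 10
   CC2   acetate  0.955192 10
gradient |r| = 0.999, selection F1 = 0.857
```

Of the 600 simulated OTUs, 184 pass the prevalence filter (most of the 440
planted background OTUs are too sparse). CC1 explains 57 % of the scaled
variation and tracks the substrate gradient almost exactly (|r| = 0.999
against the planted gradient); its S-plot selection of 90 OTUs recovers the
planted gradient-responsive guilds with F1 = 0.857. The correlation block
shows the expected sign structure: CC1 correlates positively with the
methanogenic-pathway marker α_app and negatively with NH4+, while CC2 — the
mixture-preference community — correlates with acetate.

## Command line

```bash
microcca simulate --seed 1 --out-dir sim          # synthetic inputs
microcca run --seed 1 --out-dir results           # full pipeline, synthetic mode
microcca run --otu-table otu.tsv --taxonomy tax.tsv \
             --metadata meta.tsv --markers markers.tsv --out-dir results
microcca fit --otu-table otu.tsv --out-dir model  # preprocess + CCA only
microcca report --model-dir model --otu-table otu.tsv --taxonomy tax.tsv \
             --metadata meta.tsv --markers markers.tsv --out-dir results
```

`run` writes scores/loadings/saliences/selection tables, the prevalence
partition, per-sample richness, domain overviews, per-component cladograms
with annotation files, the correlation report and a `manifest.json` with
input checksums and per-stage table sizes. A TOML config file
(`--config run.toml`) can replace the flags; flags override file values.
Exit codes: 0 ok, 1 validation, 2 usage, 3 I/O.

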