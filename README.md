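# tensordx

Integrated multi-tissue differential expression analysis by tensor
decomposition, with standard-deviation-optimized probe selection.

## The problem

Expression studies of systemic disease often profile several tissues from
the same animals — e.g. adipose, muscle and liver from a diabetic rat model
(Goto-Kakizaki) and its control strain (Wistar-Kyoto), sampled at several
time points with replicates under two treatment arms.  The usual practice
analyses each tissue separately and unions the gene lists.  `tensordx`
instead treats the whole experiment as one object: a 6-mode tensor

```
x_ijkmst ∈ R^{N × J × K × M × S × T}
```

for probe *i*, time *j*, replicate *k*, treatment *m*, strain *s* and
tissue *t*, and asks directly for probes whose treatment/strain response is
shared across tissues — a question no per-tissue analysis can pose.

## The method

1. **Normalization.** Every sample fiber is centred and scaled over probes:
   `Σ_i x_ijkmst = 0`, `Σ_i x²_ijkmst = N`.
2. **HOSVD.** The tensor is expanded as
   `x = Σ G(ℓ1…ℓ6) · u_ℓ1,i u_ℓ2,j u_ℓ3,k u_ℓ4,m u_ℓ5,s u_ℓ6,t`,
   where each mode's singular vectors are the left singular vectors of its
   unfolding and `G` is the core tensor.
3. **Mode-vector selection.** For each non-probe mode one singular vector is
   chosen by a biological criterion: *constant* across tissues and
   replicates (tissue-independent, replicate-exchangeable), maximal
   *contrast* between treatments and between strains, time unconstrained.
4. **Probe ranking.** Probe-mode vectors are ranked by `|G|` at the chosen
   non-probe indices; the top vectors carry the tissue-independent,
   treatment-distinct signal.
5. **SD-optimized selection.** Probe *i* gets score
   `Σ_ℓ u²_ℓ,i` over the kept probe vectors, attributed to a scaled χ²
   null `P_i = P[χ²_df > score_i / σ²]`.  The null SD σ is not assumed but
   *optimized*: chosen to make the histogram of null probes' p-values as
   flat as possible.  Benjamini–Hochberg adjustment at 0.01 gives the
   selected set.

The package also implements the conventional alternatives for comparison —
per-tissue Welch *t*, a SAM-like permutation statistic, an empirical-Bayes
moderated *t* (our approximations, verified against the R `limma`
reference), and ComBat batch adjustment (verified against `sva::ComBat`)
for naive integration — plus local hypergeometric gene-set enrichment on
GMT libraries and Venn-style method-overlap reports.

## Worked example

```python
from tensordx import SimulationConfig, generate_dataset, normalize, run_td_pipeline

cfg = SimulationConfig(n_probes=2000, frac_deg=0.1, effect_size=3.0,
                       noise_sd=1.0, seed=7)
tensor, truth = generate_dataset(cfg)        # (2000, 5, 5, 2, 2, 3)
stats, report = run_td_pipeline(normalize(tensor))
print(report["chosen_mode_vectors"])         # {'time': 0, 'replicate': 0,
                                             #  'treatment': 1, 'strain': 1,
                                             #  'tissue': 0}
print(round(report["sigma"], 5), stats.n_selected)   # 0.01174 198
sel = stats.table["selected"].to_numpy()
print((sel & truth.deg_flags).sum())         # 198  (precision 1.00, recall 0.99)
```

The report says the pipeline kept the constant time/replicate/tissue
vectors and the anti-symmetric treatment and strain vectors, calibrated the
null SD to 0.01174, and selected 198 probes — all of them planted DEGs
(198 of the 200 planted are recovered).

The same analysis as a narrative is in `analysis/`; run in order:

```sh
python analysis/01_simulate.py          # write series matrices + truth
python analysis/02_ingest_normalize.py  # parse, assemble, normalize
python analysis/03_td_select.py         # tensor pipeline on planted + null
python analysis/04_baselines.py         # per-tissue t/SAM/moderated-t, ComBat
python analysis/05_enrichment.py        # gene-set enrichment + Venn overlaps
```

Small result tables land in `results/`; bulky intermediates in `scratch/`.
On the planted dataset the integrated pipeline reaches recall 0.99 at
empirical FDR 0, while the best single-tissue method reaches 0.76 at the
same FDR; on the null dataset it selects nothing.

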