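# insuladiv

Does insularity — the joint condition of small population size and
geographic isolation, as on true islands, headwater lakes or mountain
"sky islands" — actually depress genetic diversity (GD) within
populations and inflate divergence among them? `insuladiv` implements a
paired, cross-study inference framework for that question, aimed at
population geneticists and conservation biologists synthesizing
published diversity estimates.

## The approach

Each study contributes populations of one species measured with one or
more GD metrics (mean alleles, allelic richness, heterozygosity,
haplotype diversity, nucleotide diversity, percent polymorphism) and/or
pairwise divergence metrics (F<sub>ST</sub>, G<sub>ST</sub>, Nei's
distance, Jost's D, Rogers' distance). Because metrics live on
incommensurable scales, every metric type is z-scored across all
population-level values of that type. Each study then collapses to one
paired point:

* **within side** — x = mean standardized GD of the non-insular
  populations, y = mean of the insular populations;
* **among side** — x = mean standardized divergence over
  non-insular/non-insular pairs, y = over insular/non-insular pairs
  (insular/insular pairs are too rare to analyse and are excluded).

Both axes are shifted by a common constant so the dataset minimum is
exactly 1, keeping log transforms defined without changing slopes or
crossings. On the paired plot the one-to-one line y = x is the
no-effect reference. The points are fitted to a candidate suite —

| model | form | constraint |
|---|---|---|
| null | y = x | slope 1, intercept 0 |
| semi-null | y = bx | intercept 0 |
| linear | y = a + bx | free |
| log-transformed | y = a + c·log x | within side only |
| exp-transformed | y = a + c·eˣ | |
| broken stick | two-segment linear, breakpoint ψ | iterative linearization |

— all with taxon-group fixed effects (mammals, birds, herps, fish,
invertebrates, plants; sum-to-zero coded) on the within side. Models
are compared by AICc (AIC + 2k(k+1)/(n−k−1)), Akaike weights
w<sub>i</sub> = exp(−Δ<sub>i</sub>/2)/Σ exp(−Δ<sub>j</sub>/2) and
evidence ratios w<sub>i</sub>/w<sub>j</sub>. The winning model's
geometry — its slope, its crossing point x* = a/(1−b) with the
one-to-one line, and where the fitted curve departs from that line —
adjudicates among four hypotheses: **null** (no effect),
**proportional** (a uniform departure), **above-threshold** (departure
only where baseline GD is high) and **below-threshold** (only where it
is low). Individual studies are also labelled against a 95% band
around the one-to-one line.

A synthetic-data module generates literature-like meta-datasets under
each hypothesis regime with known ground truth (including Wright-Fisher
drift and island-model F<sub>ST</sub> presets for realistic parameter
choices), so the whole pipeline is testable end to end without any
download.

## Worked example

Generate a 200-study dataset in which insularity reduces within-study
GD only above a threshold (post-threshold slope 0.4, threshold at the
40th percentile of baseline diversity), and run the full analysis:

```python
import insuladiv as iv

cfg = iv.RunConfig(synth=iv.SynthConfig(
    regime="above_threshold", post_slope=0.4, tau_quantile=0.4,
    n_studies=200, seed=7))
report = iv.run_pipeline(cfg)
res = report.sides["within"]
print(iv.render_comparison_table(res.comparison).to_string(index=False))
```

```
          model                                                       hypothesis delta_aicc weight
   broken_stick                above_threshold / below_threshold (by breakpoint)          —  0.997
log_transformed                                          threshold (by geometry)       11.8  0.003
         linear proportional / above_threshold / below_threshold (by parameters)      100.8 <0.001
      semi_null                                                     proportional      259.4 <0.001
exp_transformed                                          threshold (by geometry)      359.8 <0.001
           null                                                             null      460.4 <0.001
```

The broken-stick model takes essentially all the weight (0.997), its
breakpoint lands at ψ ≈ 2.74 on the shifted standardized scale — the
image of the generating threshold — and the verdict is the generating
hypothesis:

```python
print(res.verdict.hypothesis)        # above_threshold
print(res.fits["broken_stick"].psi)  # 2.738
print(res.bands.counts)              # {'within_band': 181, 'above_band': 0, 'below_band': 19}
```

The band counts say 19 of 200 studies individually fall significantly
below the one-to-one line — the threshold effect concentrates in the
high-diversity studies rather than shifting every study.

The same run is available from the shell:

```sh
insuladiv synth --regime above_threshold --n-studies 200 --seed 7 --outdir data/
insuladiv run --gd data/gd_records.csv --divergence data/divergence_records.csv --outdir out/
```

which writes per-side model-comparison tables, verdict JSON, paired
points with fitted-curve evaluations (plot-ready), study-band labels,
an exclusion log and a run manifest. `insuladiv validate` checks input
tables against the inclusion criteria (≥3 populations, ≥1 insular, ≥2
non-insular per study) and `insuladiv recover` runs the
verdict-recovery Monte Carlo.

To analyse a real harvested dataset, supply two CSVs (per-population GD
records and pairwise divergence records; column names mappable via a
YAML schema config) to `insuladiv run`.

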