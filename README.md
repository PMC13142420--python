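# dmsflow

Config-driven dataflow pipelines for **deep mutational scanning (DMS)**
analysis: from raw FASTQ reads (or count tables) to per-variant
enrichment scores.

DMS experiments measure thousands of protein variant effects in a single
pooled assay: a variant library is put through selection (growth,
binding, FACS sorting into bins, ...) and sequenced at several
conditions; a variant's effect is read out from how its relative
frequency changes.  Analyses differ widely between labs — barcoded vs
direct sequencing, two-condition vs time-series vs bin-sorted designs,
log-ratio vs regression vs custom scoring — so dmsflow provides not a
fixed workflow but a library of composable plugin nodes arranged in a
directed acyclic graph, declared in plain INI files and executed
deterministically from the command line or the Python API.

## What it computes

With pseudocount $\delta$ (default 0.5) and wild-type (wt) normalisation:

* **Log-ratio score** between two conditions, the classic enrichment
  statistic:

  $$s_v = \ln\frac{c_{v,T}+\delta}{c_{v,0}+\delta} -
          \ln\frac{c_{wt,T}+\delta}{c_{wt,0}+\delta},\qquad
    \mathrm{SE}_v = \sqrt{\textstyle\sum_{t\in\{0,T\}}
       \left(\frac{1}{c_{v,t}+\delta}+\frac{1}{c_{wt,t}+\delta}\right)}$$

* **Regression score** for time series: the weighted-least-squares slope
  of $y_{v,t}=\ln(c_{v,t}+\delta)-\ln(c_{wt,t}+\delta)$ on time
  normalised to $x\in[0,1]$, weighted by the count-derived inverse
  variances (taken as known, no residual rescaling), so the slope is the
  total log-enrichment over the experiment.

* **Random-effects replicate combination** (DerSimonian–Laird): a
  method-of-moments between-replicate variance $\sigma^2_s \ge 0$ widens
  the per-replicate variances before inverse-variance averaging; the
  heterogeneity statistic $Q$ and replicate count are reported.

* **FACS bin score** (sort-seq / VAMP-seq style): within-bin variant
  frequencies renormalised across bins and averaged with bin weights
  $w_b$ (default $b/B$, fully customisable):
  $s_v=\sum_b w_b F_{v,b}$.

Supporting plugins cover FASTQ reading with filtering and per-file
counting, CSV/TSV I/O (gzip transparent), file-name tokenisation into
metadata columns, joins (barcode → variant translation), group-by
aggregation, long-to-wide pivoting, a sandboxed row-expression language,
and substitution HGVS variant calling (`c.4A>C`, `p.Lys2Gln`) at the DNA
and protein level.

## Worked example

Generate a synthetic barcoded selection time series (200 variants, 2
replicates, 3 time points, 50,000 reads per file, known true scores) and
run the bundled analysis pipeline:

```sh
dmsflow fixtures selection --out demo --seed 3 --variants 30 --depth 2000
dmsflow validate demo/pipeline.ini
dmsflow run demo/pipeline.ini --workers 2
```

which prints the terminal row counts

```
OK: 14 nodes
write_dna: 30 rows
write_protein: 26 rows
```

— 30 DNA-level variant scores and 26 protein-level scores (synonymous
DNA variants collapse onto the same protein variant) produced by a
*single* pipeline run that fans out after variant calling.  The output
files look like

```
hgvs_dna,score,SE,Q,sigma2_s,n_reps,method
c.110G>A,-0.29451545095942955,0.2212711713424922,0.009207886109422806,0.0,2,random_effects
c.111G>A,-2.0562817221601124,0.4114720295512918,0.045545377632234874,0.0,2,random_effects
```

`score` is the replicate-combined total log-enrichment (wild type ≡ 0 by
normalisation), `SE` its standard error, `sigma2_s` the estimated
between-replicate variance and `Q` the heterogeneity statistic.
`demo/truth.csv` holds the generating true scores for comparison.

Pipelines are ordinary INI files — every node is one section with a
`plugin` key, `input.<k>` connections and typed parameters — so they can
be version-controlled, diffed and edited by hand; any parameter can be
overridden at run time with `--set NODE.PARAM=VALUE`, and
`dmsflow preview PIPELINE NODE --rows N` shows any intermediate table.

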