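# flymeio

Statistics for the quantitative assays of *Drosophila melanogaster*
female-meiosis studies: crossover scoring and Weinstein tetrad analysis,
X-chromosome nondisjunction (NDJ) assays, rule-based germarium RNAi-screen
classification with per-nucleus foci statistics, and a simplified
spectral-count (dNSAF) proximity-enrichment caller. Every pipeline stage
has a matching seeded simulator, so the whole package is testable without
any external data.

## Who it is for

Fly geneticists and analysts who score multi-marker backcrosses, run
`B^s Y` nondisjunction crosses, screen germaria by immunofluorescence, or
triage APEX/BioID-style spectral-count tables, and want the arithmetic
behind those assays as tested, scriptable code instead of spreadsheets
and web calculators.

## The core model

In female meiosis only one of the four chromatids of each tetrad is
recovered. Under the classical no-chromatid-interference assumption each
of the *n* exchanges of a rank-*n* tetrad involves the recovered
chromatid independently with probability ½, so observed chromatid
crossover classes follow

&nbsp;&nbsp;&nbsp;&nbsp;*f*<sub>k</sub> = Σ<sub>n≥k</sub> *E*<sub>n</sub> · C(n,k) / 2<sup>n</sup>,

where *E*<sub>n</sub> is the frequency of rank-*n* tetrads (the Weinstein
E values). `flymeio` estimates **E** two ways: the classical direct
inversion (back-substitution, which can leave the probability simplex)
and a constrained maximum-likelihood fit via EM with the latent tetrad
rank, which always returns a proper distribution and coincides with the
inversion whenever that is non-negative. Percentile-bootstrap intervals
are available for the MLE.

Around that core:

- **Crossover scoring** — per-progeny P/R marker calls → phase switches →
  interval map lengths (cM = 100 × recombinant fraction) and NCO/SCO/DCO/TCO
  class tallies; Fisher's exact test between genotypes per interval.
- **NDJ assay** — adjusted totals (exceptional progeny ×2, because the
  reciprocal exceptional classes die), NDJ percentages, progeny-per-female
  fertility, and a seeded Monte-Carlo test of rate differences under that
  viability model.
- **Germarium screen** — defect labels (SC assembly/maintenance, DSB
  initiation/repair, underdeveloped) assigned when ≥50 % of ≥10 scorable
  germaria show the defect; Mann–Whitney U (exact for small samples) and
  mean (±SD) N summaries for foci counts.
- **Proximity enrichment** — distributed NSAF from unique/shared spectral
  counts, and enrichment calls at log₂FC > 2 and Z > 5 against
  enzyme-only controls (a declared simplified Z statistic; see
  `docs/methods.md`).

## Worked example

Fit the exchange-rank distribution to the packaged control class counts
(NCO 879, SCO 779, DCO 62, TCO 1; N = 1721):

```python
from flymeio import datasets, tetrad_mle, map_length_from_classes

counts = datasets.crossover_classes("control")
fit = tetrad_mle(counts, max_rank=3)
print("E (control):", fit.E_hat.rounded())
print("total map length (cM):", round(map_length_from_classes(counts), 1))
```

prints

```
E (control): [0.0936, 0.7647, 0.1371, 0.0046]
total map length (cM): 52.6
```

i.e. about 9.4 % of tetrads had no exchange (E₀), 76.5 % one exchange,
13.7 % two and 0.5 % three, and the chromatids carried 0.526 crossovers
on average (52.6 cM). The same fit is available from the shell:

```sh
flymeio tetrad --classes classes.tsv --bootstrap 2000 --seed 17 --out out/
```

The NDJ arithmetic works the same way; for the packaged RNAi-like tally
(`ndj_summary(...)`) it prints `{'ndj_percent': 4.9, 'adjusted_total':
1154, 'progeny_per_female': 76.9}` — a 4.9 % X-NDJ rate with roughly
half the control's fertility.

Estimator classes follow scikit-learn conventions (`TetradMLE`,
`EnrichmentCaller`: `fit`, `get_params`, fitted attributes with a
trailing underscore) and compose with sklearn tooling; the module-level
functions are thin wrappers over them.

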