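# podomap

Mapping the environmental limits, prevalence and burden of podoconiosis
from community surveys and gridded environmental covariates.

Podoconiosis (non-filarial elephantiasis) is a disabling lymphoedema
caused by long-term barefoot exposure to irritant volcanic clay soils.
National control programmes need three numbers that raw surveys cannot
give directly: where the environment permits the disease at all, what
the prevalence is everywhere (not just in surveyed communities), and how
many people are affected or at risk.  `podomap` is a tested, reusable
implementation of the two-stage workflow used for such estimates, for
epidemiologists and geostatisticians working with community-level
screening data.

## The models

**Stage 1 — environmental suitability.**  Communities are labelled
endemic/non-endemic from confirmed cases.  Sampling bias is corrected by
thinning positives in over-represented regions and by drawing n = 500
background (pseudo-absence) points from a kernel-density surface of
survey effort; absence + background records are down-weighted so their
summed weight equals that of the presences.  An ensemble of boosted
regression trees (lr 0.005, interaction depth 4) and random forests
(500 trees) is fitted over repeated stratified 80/20 splits; members
with held-out AUC < 0.8 or TSS < 0.7 are discarded; the per-cell mean of
the survivors, thresholded at the cut-off maximising
(sensitivity + specificity + PCC)/3, gives the binary environmental
limits map.

**Stage 2 — binomial geostatistics.**  Within those limits, prevalence
is modelled as

    y_i ~ Binomial(n_i, p_i),   logit p_i = d(x_i)'β + S(x_i) + Z_i,

with S a Gaussian process (exponential covariance, partial sill σ²,
range φ km) and Z the community-level nugget (variance τ²).  Parameters
are estimated by Monte-Carlo maximum likelihood with a Laplace
importance-sampling proposal; prediction draws joint samples of the
latent surface to produce mean/95% CI prevalence maps and the
probability of exceeding a 1% prevalence threshold.  A global
Monte-Carlo variogram envelope checks the fitted spatial structure.

**Burden.**  Cases per cell = prevalence × adult population; population
at risk = adults inside the limits map; both are aggregated to
administrative polygons with exact conservation.

A synthetic-world generator (`podomap.synthdata`) simulates covariate
fields, a known truth surface, clustered surveys with an over-sampled
region, population and admin polygons, so the full pipeline runs and is
validated end-to-end without restricted survey microdata.  See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

The packaged regional totals of two national podoconiosis surveys
(10 regions, 748 community clusters):

```python
>>> from podomap import surveys as sv
>>> s = sv.summarize_regional_totals(sv.load_regional_survey_table())
>>> s.total_screened, s.total_cases
(214729, 882)
>>> round(s.prevalence_pct, 2)
0.41
>>> [round(v, 2) for v in s.ci_exact_pct]
[0.38, 0.44]
```

214 729 people screened, 882 confirmed cases: a pooled prevalence of
0.41% (95% CI 0.38–0.44%) — low overall, which is exactly why the
spatial model matters: the cases concentrate where the environment
permits them.

A full synthetic run from a config file:

```bash
podomap run --config examples/small_world.toml --seed 3
podomap show-report --outdir podomap_run
```

On the bundled example world this prints (abridged):

```json
{
  "survey_summary": {
    "n_clusters": 300,
    "prevalence_pct": 0.36,
    "zero_case_share_pct": 94.3
  },
  "burden_total_cases": 3834.4,
  "population_at_risk": 37844.4
}
```

i.e. on that simulated country, 0.36% of screened adults have the
disease, and multiplying the predicted prevalence surface by the adult
population yields ≈ 3 800 expected cases, with ≈ 38 000 adults living in
environmentally suitable cells.

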