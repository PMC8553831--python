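# evoweb

An eco-evolutionary food-web simulator for studying how the *strangeness*
of invading species disturbs communities and reshapes the evolution of
diet breadth.  It is aimed at theoretical community ecologists who want a
desk-scale, fully scriptable implementation of bioenergetic
consumer-resource dynamics on an evolving body-size trait axis, with the
disturbance/generalism metrics and trend statistics needed to run
invader-strangeness experiments end to end.

## The model

Every species *i* carries three heritable traits: a body mass $m_i$, a
feeding centre $f_i$ and a feeding range $s_i$.  The pair $(f_i, s_i)$
defines a normalised Gaussian feeding kernel over $\log_{10}$ body mass,

$$a_{ij} = m_i^{0.75} \cdot \frac{1}{s_i\sqrt{2\pi}}
  \exp\!\left[-\frac{(\log_{10} f_i - \log_{10} m_j)^2}{2 s_i^2}\right],$$

so specialists (small $s$) buy higher peak attack rates at the price of
breadth.  Biomass densities follow a bioenergetic consumer-resource model
with a Holling type-II functional response

$$g_{ij} = \frac{1}{m_i}\,\frac{a_{ij}}{1 + \sum_k h_i a_{ik} B_k},
\qquad
\frac{dB_i}{dt} = \sum_{j\,\in\,\mathrm{res}} e\, g_{ij} B_i B_j
 - \sum_{j\,\in\,\mathrm{cons}} g_{ji} B_j B_i
 - \sum_{j\neq i} c_{ij} B_i B_j - x_i B_i,$$

a basal resource with chemostat inflow/outflow
$dB_0/dt = n_0 - \sum_j g_{j0}B_jB_0 - l B_0$, allometric handling time
and metabolic loss ($h_i = 0.4\,m_i^{-0.75}$, $x_i = 0.3\,m_i^{-0.25}$ —
see `docs/methods.md` for why the exponents must pair this way), and
interference competition $c_{ij} = c_0 I_{ij}/I_{ii}$ derived from the
closed-form overlap integral $I_{ij}$ of two feeding kernels.

On top of the dynamics, an evolutionary layer introduces one new species
every 100 time units: a **mutant** (probability $1-p$, traits drawn with
SD $z=0.1$ around a parent chosen by individual density $B/m$) or an
**invader** (probability $p=0.2$, traits drawn with SD equal to the
*invader strangeness* $z$ around a uniformly chosen parent).  Species
falling below the extinction threshold $\varepsilon=10^{-8}$ are culled.
Sweeping $z$ and measuring biomass variability, species turnover, feeding
range evolution and specialist/generalist lifespans probes the
generalist-disturbance hypothesis: more variable communities should favour
broader diets.

## Worked example

```python
from evoweb.experiment import desk_config, run_simulation
from evoweb.metrics import compute_metrics

record = run_simulation(desk_config(z=1.5), seed=5)   # horizon 2e5 time units
print(record.status, len(record.ledger), record.final_state.n)
m = compute_metrics(record)
print(m.sd_resource, m.mean_turnover, m.mean_mutant_s, m.lifespan_slope)
```

prints (exactly reproducible with this seed):

```
completed 2001 2
0.3960 0.6368 0.4986 -1.5657
```

Read: the run introduced 2001 species over 2×10⁵ time units and ended with
2 coexisting consumers; the basal-resource biomass fluctuated with SD
0.396 around its mean; on average 64% of the community composition changed
between consecutive 10⁴-step snapshots; viable mutants carried a mean
feeding range of 0.499 (above the 0.3 floor, i.e. moderately generalist);
and the lifespan-vs-feeding-range slope is negative — at this strangeness
level specialists still outlive generalists.

The same machinery is scriptable from a shell:

```bash
evoweb simulate --z 1.5 --horizon 200000 --seed 5 --out runs/z15 --graphml
evoweb sweep --z-min 0.5 --z-max 5 --z-steps 10 --replicates 3 \
             --horizon 200000 --seed 0 --out runs/sweep
evoweb metrics --runs runs/sweep --out runs/metrics.tsv
evoweb report --metrics runs/metrics.tsv --out runs/trends.tsv
```

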