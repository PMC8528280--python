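# oifnet

Directed species-interaction networks, stability indicators and keystone
species from ecological abundance time series.

Community censuses — here, a coastal fish survey sampled roughly every two
weeks for over a decade, but any multispecies count table with an
environmental covariate fits — record *who* was present and *how many*, yet
the quantity ecologists increasingly need is *who drives whom*. `oifnet`
reconstructs that directed interaction structure from the abundance
fluctuations themselves, using information flow as the operational definition
of an interaction, and then reads ecosystem-level state indicators off the
inferred networks: spectral stability, total interaction, effective
diversity, interaction and abundance spectra, link salience and keystone
species, all resolved over temperature ranges and sliding time/temperature
windows.

## The method

For species abundances z-scored over the record, the directed interaction
from species *i* to species *j* is the transfer entropy at first Markov
order,

```
TE_{i→j}(u) = I( x_j(t+1) ; x_i(t+1−u) | x_j(t) )        [bits]
```

with the source–target delay *u* ∈ {0..10} chosen to maximize the lagged
mutual information I(x_i(t−u); x_j(t)) (equivalently, to minimize the
statistical distance d = e^−I). Negative raw estimates are numerical
artifacts and are clamped to zero. Weak links are removed by a threshold —
fixed (0.01 bits), top-20 % ("Pareto core"), or the value whose induced
*effective* diversity best predicts the observed taxonomic diversity. On the
thresholded matrix **W** the package computes

* **TI** = Σᵢⱼ Wᵢⱼ (total interaction),
* **DS** = |Re ξ_max| with **W**v = ξv (dynamic stability; drift of the
  dominant eigenvalue toward zero-crossing is the critical-slowing-down
  signature),
* **α_e** = number of connected species (effective diversity),
* **OTE(i)** = Σⱼ TE_{i→j} (a species' total directed influence),
* **link salience** = the fraction of reference nodes whose shortest-path
  trees (under effective distance 1/W) contain a link; species that dominate
  the most salient links are the keystone candidates,

plus Zipf/exceedance, double-Pareto (broken power law), exponential,
Taylor-law and exponential-temperature-response fits of the abundance and
interaction samples. Estimators are gaussian (default, parameter-free),
box-kernel, and equal-width binned.

A synthetic-community generator with a known directed coupling matrix, the
canonical temperature ranges (≤10, 10–15, 15–20, 20–25, ≥25 °C) and the
canonical window layouts (yearly 24-point windows stepped monthly over a
285-point record → 131 networks; 5 °C windows stepped by 1 °C → 22 networks)
make every stage testable without any data download.

## Worked example

```python
import oifnet as o

tab, truth = o.gen_community(o.SyntheticConfig(seed=42))   # 15 sp x 285 pts
na   = o.normalize(tab)
part = o.partition_by_TR(na)
im   = o.apply_threshold(o.infer_matrix(na), "fixed")      # TE >= 0.01 bits
eig, dom, npos = o.eigen_spectrum(im.W)
print(part.sizes, int((im.W > 0).sum()), round(dom.real, 3),
      round(o.total_interaction(im), 2), o.effective_alpha(im))
print(o.ote_profile(im).ranking[:3])
print(o.keystone_ranking(o.link_salience(im))["ranking"][:3])
```

prints

```
(32, 71, 57, 62, 63) 106 0.716 7.43 15
[('sp5', 1.76), ('sp4', 0.99), ('sp9', 0.83)]
[('sp14', 2), ('sp4', 1), ('sp5', 1)]
```

— the five temperature-range subset sizes, 106 retained links, a dominant
eigenvalue of 0.716 (positive, as expected for a nonnegative interaction
matrix), 7.43 bits of total interaction with all 15 species connected, and
the outgoing-influence and keystone rankings. Species 4, 5 and 9 sit in the
generator's temperature-synchronized competitive block, which is why they top
the OTE ranking.

The same pipeline is scriptable from the shell:

```
oifnet synth --seed 42 --out census.csv
oifnet run --census census.csv        # infer -> sweep -> fits -> salience -> report
```

Each run writes a results bundle (edge lists, GraphML, per-window stability
CSVs, fit reports, keystone tables, a percent-change summary) stamped with
the hash of its archived configuration.

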