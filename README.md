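# foodgap

Food production–consumption gap accounting for regional food
self-sufficiency assessment.

## The problem

Oasis metropolitan areas — compact urban regions whose agriculture is
bounded by water and arable land — depend heavily on long-distance food
trade. How far can such a region feed itself from its own production,
not just in calories but in macronutrients and food diversity?
`foodgap` implements a nine-food-group balance sheet (cereals, tubers,
legumes, vegetables, fruits, meat, eggs, dairy, aquatic products)
answering that question for any region with production statistics,
population pyramids, and per-capita intake tables. It was built around
the Urumqi Metropolitan Area assessment and ships that region's
published 2000–2020 aggregate accounts as reference fixtures.

It is aimed at food-systems and regional-planning researchers who work
from statistical yearbooks and census tables in Python.

## The model

Production side: raw mass per food *j* becomes edible calories and
nutrient masses,

    TCP_j = FP_j · CF_j · CalF_j            TCP = Σ_j TCP_j
    MNP_{j,q} = TCP_j · EP_{j,q} / ECF_q    MNP_q = Σ_j MNP_{j,q}

with CF_j the edible-conversion factor, CalF_j the caloric factor
(kcal/g), EP_{j,q} the energy share of macronutrient *q* in food *j*,
and ECF_q the Atwater-style coefficient (4/4/9 kcal/g for
carbohydrate/protein/fat). Demand side mirrors it over nine age stages
*a* (by sex and urban/rural residence) and a dietary structure FI_{a,j}
(g/person/year):

    TCD_j = Σ_a Pop_a · FI_{a,j} · CalF_j   TCD = Σ_j TCD_j
    MND_{q,j} = TCD_j · NRGP_{q,j} / ECF_q

The self-sufficiency gap at every resolution (total calories, each
macronutrient, each food) is

    Gap = (demand − production) / production × 100 %

with Gap ≤ 0 meaning local production meets demand. Three dietary
structures are distinguished: S0 (historical consumption, 2019–2021
mean), S1 (guideline upper limits), S2 (guideline lower limits). Future
demand applies the same equations to provincial SSP cohort projections
downscaled by a constant per-cohort regional share and averaged over
basic- (2011–2030), near- (2021–2040), and mid-term (2041–2060)
windows, compared against a frozen baseline-year production account.

## Worked example

```sh
python examples/published_gap_statistics.py
```

prints, from the packaged published accounts:

```
2020 total-calorie gap vs guideline upper limit :   7.99 %
2020 carbohydrate gap, actual consumption       :    1.4 %
fruit production fold-change 2020/2000          :   29.5 x
```

The 7.99 % gap means 2020 caloric production (4044.80 B kcal) falls
about 8 % short of what guideline-upper-limit consumption (4368.1
B kcal) would demand; the 1.4 % carbohydrate gap means actual
carbohydrate demand already slightly exceeds local production; fruit
output grew roughly 29-fold over two decades. The other scripts in
`examples/` walk through production accounting, guideline deviations,
scenario projection, and share-model calibration, each printing a short
interpretation.

A thin CLI mirrors the library stages
(`foodgap simulate|produce|demand|gap|project|report`); run
`foodgap --help`.

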