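"""Headline gap statistics from the published UMA accounts.

Feeds the packaged aggregate tables (caloric/macronutrient production and
demand, 2000-2020) through the gap operations: positive gaps mean local
production cannot cover demand.
"""

from foodgap.gap import gap_percent, production_trend_ratio
from foodgap.uma_data import DEMAND_ACCOUNT, PRODUCTION_ACCOUNT, production_by_food_kt

prod_2020 = PRODUCTION_ACCOUNT.set_index("year").loc[2020]
demand = DEMAND_ACCOUNT.set_index(["structure", "year"])

gap_upper = gap_percent(
    demand.loc[("guideline_upper", 2020), "total_bkcal"], prod_2020["total_bkcal"]
)
gap_carb = gap_percent(
    demand.loc[("actual", 2020), "carbohydrate_kt"], prod_2020["carbohydrate_kt"]
)
fruit_fold = production_trend_ratio(
    production_by_food_kt(2020)["fruits"], production_by_food_kt(2000)["fruits"]
)

print(f"2020 total-calorie gap vs guideline upper limit : {gap_upper:6.2f} %")
print(f"2020 carbohydrate gap, actual consumption       : {gap_carb:6.1f} %")
print(f"fruit production fold-change 2020/2000          : {fruit_fold:6.1f} x")
print()
print("The ~8% total gap says 2020 production could not cover demand if")
print("every resident ate at the guideline upper limit; the small positive")
print("carbohydrate gap says actual carbohydrate demand already slightly")
print("exceeds local production.")
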