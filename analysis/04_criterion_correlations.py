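"""Criterion validity: item means vs baseline psychopathology scores.

Within each arm, z-scored per-person item means are correlated with each
baseline criterion (BSI and the three DASS subscales); the per-arm average
absolute correlation and the VAS-Likert difference are bootstrapped at the
participant level.  Writes results/criterion_*.csv.
"""

import pathlib

import pandas as pd

from emascale import apply_inclusion, criterion_correlations, read_study

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"

ds, _ = read_study(OUT / "study.csv", OUT / "criteria.csv")
ds = apply_inclusion(ds)
tab = pd.read_csv(OUT / "stats.csv")
item_means = tab.pivot(index="participant_id", columns="item", values="wp_mean")

for crit in ds.criteria.columns:
    res = criterion_correlations(item_means, ds.criteria[crit], ds.group_of(), B=1000, seed=37)
    res.per_item.to_csv(OUT / f"criterion_{crit}_per_item.csv")
    res.avg_abs.to_csv(OUT / f"criterion_{crit}_avg_abs.csv")
    d = res.difference.loc["vas_minus_likert"]
    print(f"{crit:10s} avg |r|: Likert {res.avg_abs.loc['likert', 'observed']:.3f}  "
          f"VAS {res.avg_abs.loc['vas', 'observed']:.3f}  "
          f"diff {d['median']:+.3f} (90% HDI [{d['hdi_low']:+.3f}, {d['hdi_high']:+.3f}])")
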