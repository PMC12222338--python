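"""Generate the synthetic two-arm EMA study all later steps analyze.

63 Likert and 56 VAS participants, 14 affect items (5 positive / 9
negative), up to 84 beeps, ~1/3 missingness; the Likert arm reads the
same kind of latent affect through seven equal-width thresholds.
Writes results/study.csv, results/criteria.csv, results/truth.yaml.
"""

import pathlib

import yaml

from emascale import SyntheticConfig, generate_study, write_study
from emascale.simulate import config_to_dict

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

cfg = SyntheticConfig(seed=2026)
ds = generate_study(cfg)
write_study(ds, OUT / "study.csv", OUT / "criteria.csv")
with open(OUT / "truth.yaml", "w") as fh:
    yaml.safe_dump(config_to_dict(cfg), fh)

groups = ds.group_of()
print(f"generated {len(ds.records)} records for {len(groups)} participants "
      f"({(groups == 'likert').sum()} Likert / {(groups == 'vas').sum()} VAS)")
print(f"observed beeps per participant: mean {ds.n_obs_beeps().mean():.1f} of 84")
zeros = ds.records.groupby("group")["value_norm"].apply(lambda v: (v == 0).mean())
print(f"fraction of exact-zero responses: Likert {zeros['likert']:.3f}, VAS {zeros['vas']:.3f}")
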