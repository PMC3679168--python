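"""Stage comparisons within a genotype, and the hundred-grain-weight t-test.

First: which hybrid spots appear, disappear, or change abundance between
dry seed and 24 h after imbibition in a simulated experiment? Second: does
the reference hybrid's grain weight differ from its parents'? (Grain weight
is a potential confounder of germination heterosis.)
"""

from collections import Counter

from heterospot import SimulationConfig, simulate_spot_experiment, stage_differential
from heterospot.datasets import load_grain_weight
from heterospot.quant import normalize_volumes
from heterospot.report import TraitSummary, two_group_ttest

table, _ = simulate_spot_experiment(
    SimulationConfig(n_spots=500, dropout_rate=0.1, seed=13)
)
norm = normalize_volumes(table)
ds = norm[norm["stage"] == "DS"]
hai = norm[norm["stage"] == "24HAI"]
changes = stage_differential("H", ds, hai)
print("hybrid spots between stages:", dict(Counter(c.status for c in changes)))

gw = load_grain_weight().set_index("group")
hybrid = TraitSummary("hybrid", *gw.loc["Zong3/87-1", ["mean", "dispersion"]], 3)
for parent in ("Zong3", "87-1"):
    other = TraitSummary(parent, *gw.loc[parent, ["mean", "dispersion"]], 3)
    t, p = two_group_ttest(hybrid, other)
    verdict = "differs" if p < 0.05 else "no significant difference"
    print(
        f"hundred-grain weight, hybrid ({hybrid.mean} g) vs {parent} "
        f"({other.mean} g): t={t:.2f}, p={p:.3f} -> {verdict}"
    )
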