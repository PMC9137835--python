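"""Parameter-recovery check with a planted optimal condition.

Constructs a synthetic dataset in which one chosen rearing condition is
strictly best in all 23 responses, runs the complete pipeline
(generate -> train -> optimize -> select), and verifies the recommendation
returns the planted condition. This is the end-to-end ground-truth test of
the whole analysis.
"""

import larvopt as lv
from larvopt.pipeline import RunConfig, run_all

planted = lv.DesignPoint("ZM", "mixture", 104)
cfg = RunConfig(seed=8,
                planted_optimum=(planted.species, planted.substrate, planted.harvest_days),
                hidden_range=(10, 10), activations=("identity",), restarts=2)
result = run_all(cfg)
print(f"planted:     {planted.label()}")
print(f"recommended: {result.recommended.label()}")
print(f"recovered:   {result.recommended == planted}")
print(f"(enumeration front had {len(result.front_enumeration.members)} members; "
      "under 3% replicate noise neighbours may join the empirical front, but the "
      "distance-to-ideal recommendation still lands on the planted optimum)")
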