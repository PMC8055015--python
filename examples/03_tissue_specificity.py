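"""Detect tissue-specific miSS usage with the dummy-slope regression.

Simulates per-sample counts where one fifth of miSS carry a usage shift
in a single tissue, fits the one-vs-rest slope model per tissue, and
calls tissue-specific miSS from q-values and the delta-phi effect size.
"""

import pandas as pd

from tasscat import simulate, tissue

cfg = simulate.SimConfig(seed=11, tissue_effect_frac=0.2,
                         tissue_effect_size=0.1, zip_a1=1.0, zip_b0=-30.0)
sim = simulate.simulate_counts(cfg, n_miss=60)

rows = []
for miss_id, grp in sim["pairs"].groupby("miss_id"):
    fits = tissue.fit_all_tissues(grp)
    fits["miss_id"] = miss_id
    rows.append(fits)
fits = pd.concat(rows, ignore_index=True)

calls = tissue.call_specific(fits)
hits = calls[calls["specific"]]
truth = set(map(tuple, sim["effects"][["miss_id", "tissue"]].to_numpy()))
found = set(map(tuple, hits[["miss_id", "tissue"]].to_numpy()))

print(f"injected effects: {len(truth)}  called specific: {len(found)} "
      f" (true positives: {len(found & truth)})")
echo = {f for f in found - truth
        if f[0] in {m for m, _ in truth}}
print(f"extra calls on truly affected miSS: {len(echo)} — one-vs-rest "
      "fits see a strong effect in one tissue as a small opposite "
      "deviation of the others")
print("\nexample calls (dphi is the usage deviation of the miSS in that "
      "tissue relative to the tissue average):")
print(hits.nsmallest(5, "q")[["miss_id", "tissue", "a0", "a_t", "dphi",
                              "q", "direction"]].to_string(index=False))
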