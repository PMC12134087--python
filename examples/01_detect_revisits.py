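"""Detect revisited sites in a GPS trajectory with the moving-circle method.

Builds a small synthetic study, runs visit detection at a 250 m radius with
the 12 h minimum-time-away rule, and prints the most-revisited sites.
"""

import numpy as np

from revisit import RecursionConfig, StudyConfig, gen_study, revisitation_table

bundle = gen_study(StudyConfig(n_bulls=1, n_cows=1, duration_days=120, seed=42))
cfg = RecursionConfig(radius=250.0, min_time_away_s=12 * 3600)

sites = revisitation_table(bundle.trajset, cfg, centre_stride=4)
counts = np.array([s.n_visits for s in sites])

print(f"{len(sites)} candidate sites (one per sampled fix)")
print(f"visit counts: mean {counts.mean():.2f}, max {counts.max()}")
top = max(sites, key=lambda s: s.n_visits)
print(f"most revisited site: {top.site_id} at ({top.cx:.0f}, {top.cy:.0f}) "
      f"with {top.n_visits} separate visits")
print("first three visit intervals (UTC):")
for v in top.visits[:3]:
    print(f"  {v.enter_time:%Y-%m-%d %H:%M} -> {v.exit_time:%Y-%m-%d %H:%M}")
# A count of k means the animal entered this 250 m circle on k occasions
# separated by at least 12 h outside it - the raw currency of the analysis.
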