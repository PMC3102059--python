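"""Inflammation outbreak and hysteresis for healthy-control skin.

Builds the positive-LEKTI-feedback model (variant 1) at healthy-control
(HC) parameters, scans steady states over the external stimulus, and
prints the bifurcation pattern with its thresholds.
"""

import numpy as np

from klkbarrier import build_parameters, classify_pattern, scan_mu

params = build_parameters("HC", variant=1, overrides={"alphaK": 0.5, "alphaL": 0.0})
diagram = scan_mu(params, np.linspace(0.0, 60.0, 121))
summary = classify_pattern(diagram)

print(f"pattern:  {summary.pattern}")
print(f"mu_on  =  {summary.mu_on:.2f}   (stimulus where inflammation ignites)")
print(f"mu_off =  {summary.mu_off:.2f}   (stimulus below which it ceases)")
print(f"delta  =  {summary.delta_mu:.2f}   (hysteresis width: persistence)")

# A stimulus between mu_off and mu_on supports two stable states: zero
# inflammation and a high-PAR2* state, so a transient flare persists
# until the stimulus drops below mu_off.
mid = 0.5 * (summary.mu_on + summary.mu_off)
col = diagram.branches[int(np.argmin(np.abs(diagram.mu_grid - mid)))]
print(f"\nat mu ~ {mid:.1f} the model holds {len(col)} steady states:")
for s in col:
    print(f"  [PAR2*] = {s.Pact:7.3f}  ({s.stability})")
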