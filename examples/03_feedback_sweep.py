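"""Map bifurcation patterns over the two feedback strengths.

Sweeps the PAR2*-to-KLK5 (alphaK) and PAR2*-to-LEKTI (alphaL) feedback
strengths over their nominal ranges for healthy-control parameters and
tabulates which bifurcation pattern each cell exhibits.  Runs a coarse
7x7 grid (~10 s); raise the resolution for smoother maps.
"""

from klkbarrier import sweep_feedback_grid

sweep = sweep_feedback_grid("HC", variant=1, resolution=7, mu_max=60.0)

print(sweep["pattern"].value_counts().to_string())
print()
rev = sweep[sweep["pattern"] == "reversible_bistable"]
by_ak = rev.groupby("alphaK")["delta_mu"].mean()
print("mean bistability range by KLK5 feedback strength:")
print(by_ak.round(2).to_string())
# delta_mu grows with alphaK: stronger KLK5 feedback makes inflammation
# more persistent, and at the strongest feedback the pattern becomes
# irreversible (inflammation outlasts any stimulus reduction).
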