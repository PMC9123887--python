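"""Cyclic/environmental covariates and the pre-modelling screens.

Each monitored hour carries moon-cycle fraction, tidal height / 60-min
change / curvature trend, hour of day, civil daylength, daily SST and
chlorophyll.  Before modelling, collinear covariates are removed with a
Spearman screen (|ρ| > 0.7) and the environmental table is checked for
sampling adequacy (KMO > 0.5) ahead of PCA-based clustering.
"""

import whistlegam as wg

_, _, _, records = wg.simulate_study(seed=1)
frame = wg.records_to_frame(records)

candidates = ["moon", "tide", "flow", "dtide", "hour", "daylength",
              "sst", "delta_sst", "chl", "depth", "distance"]
screen = wg.spearman_screen(frame[candidates],
                            priority=["sst", "moon", "tide", "dtide", "hour"])
print("retained after collinearity screen:", screen.retained)
for dropped, partner, rho in screen.dropped:
    print(f"  dropped {dropped!r} (ρ = {rho:+.2f} with retained {partner!r})")

env = frame.groupby("deployment_id")[["sst", "chl", "daylength"]].mean()
overall, per_var = wg.kmo(env)
print(f"\nKMO sampling adequacy of the deployment env table: {overall:.2f}")
print("  (values above 0.5 justify a PCA of these variables)")
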