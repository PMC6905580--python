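"""Simulate ground + thermal surveys over a riverside park and fit the
confidence-weighted logistic models.

The G model sees only the ground-survey records (observer-biased toward
paths); GT adds the thermal-imagery detections.  Coefficients are on the
standardized scale, so their magnitudes are directly comparable.
"""

import sdmfusion as sf

data = sf.simulate_study(seed=1)
obs, cov = data.observations, data.covariates
n_ground_pres = ((obs.y == 1) & (obs.source == "ground")).sum()
print(f"{len(obs)} records: "
      f"{(obs.y == 1).sum()} presences ({n_ground_pres} from ground surveys), "
      f"{(obs.y == 0).sum()} absences at weight 0.90")

ground = obs[obs.source == "ground"]
scaling = sf.compute_reference_scaling(
    cov.set_index("site_id").loc[ground.site_id].reset_index()
)


def z(ids):
    return sf.standardize(cov.set_index("site_id").loc[ids].reset_index(), scaling)


m_g = sf.fit_weighted_logistic(z(ground.site_id), ground.y, ground.weight)
m_gt = sf.fit_weighted_logistic(z(obs.site_id), obs.y, obs.weight)

print(f"\nG model (n={m_g.n_obs}):")
print(m_g.coef_table().round(3).to_string(index=False))
print(f"\nGT model (n={m_gt.n_obs}):")
print(m_gt.coef_table().round(3).to_string(index=False))
print("\nAdding thermal records shrinks every standard error; a negative "
      "dist_water estimate means koalas concentrate near the river.")
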