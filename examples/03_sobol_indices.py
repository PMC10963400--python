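"""Which tissue conductivity drives the EEG topography error?

Estimates first-order, skin-skull second-order and total-effect Sobol
indices of the RDM and MAG for mid-depth tangential sources, using the
Janon pick-freeze estimator on surrogate-evaluated potentials.
"""

from eeguq import default_model, default_priors, generate_montage, generate_source_spaces
from eeguq.forward import assemble_leadfield
from eeguq.gpc import GPCConfig, fit_gpc
from eeguq.sobol import sobol_of_rdm_mag

model = default_model()
montage = generate_montage(model)
priors = default_priors()
sources, _ = generate_source_spaces(model, [(25.0, 8)], "tangential", 1.0, seed=11)

fwd = lambda sigma: assemble_leadfield(model, sigma, sources, montage)  # noqa: E731
surrogate = fit_gpc(fwd, priors, GPCConfig(seed=5))

est = sobol_of_rdm_mag(surrogate, model, montage, sources, priors, n_samples=4096, seed=1, n_boot=50)
t = est.table
for functional in ("rdm", "mag"):
    med = t[t.functional == functional].groupby(["kind", "name"]).raw.median()
    print(f"\nmedian Sobol indices of {functional.upper()} over 8 tangential sources at 25 mm depth:")
    print(med.round(3).to_string())
print("\nThe skull conductivity dominates the topography (RDM) variance;"
      " the skin-skull interaction adds a further share, while gray and"
      " white matter contribute little at this depth.")
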