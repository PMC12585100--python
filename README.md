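# wbsleep

Whole-brain modelling of NREM sleep as a neuromodulatory shift, for
computational neuroscientists studying how cholinergic (ACh) and
noradrenergic (NA) withdrawal reshapes cortical functional connectivity
across wake (W) and sleep stages N1-N3.

The model is a network of Wilson-Cowan excitatory/inhibitory pairs, one
per region of a parcellation, coupled through a structural connectome
`C` and stabilized by homeostatic inhibitory plasticity:

    tau_E dE_i/dt = -E_i + (1 - r_E E_i) S_E(a_EE E_i - a_i_IE I_i
                                             + G_i sum_j C_ji E_j + P + D eps_i)
    tau_I dI_i/dt = -I_i + (1 - r_I I_i) S_I(a_EI E_i)
    tau_ip da_i_IE/dt = I_i (E_i - rho_E)

The plasticity holds each region's mean excitatory activity at
rho_E = 0.18 across the whole parameter range.  Excitatory activity
drives a Balloon-Windkessel hemodynamic model; the simulated BOLD is
band-passed (0.01-0.1 Hz, 2nd-order Bessel, zero-phase) and sampled at
TR = 2 s to produce functional connectivity (FC) matrices.

Neuromodulation enters as regional fields built from mean-1 brain maps,

    G_i = G + deltaG * ACh_i        sigma_i = sigma + delta_sigma * NA_i

(lower ACh tone = higher coupling, lower NA tone = shallower slope), and
each sleep stage is fitted by sweeping (deltaG, delta_sigma) to minimize
the *euccorrelation* between simulated and empirical FC lower triangles,

    euccorr(v1, v2) = ||v1 - v2|| / |rho(v1, v2)|,

which is small only when connectivity strength and pattern both match.
The package also implements Hierarchical Modular Analysis (HMA) — an
eigenmode decomposition splitting FC into global/nodal integration and
segregation components — hemisphere-symmetric map surrogates, homotopic
connectome enhancement, nucleus-cortex FC with confound regression, and
the statistical toolkit (Cohen's D with interpretation bins, paired
t-tests with Benjamini-Hochberg correction, repeated-measures
correlation).  A synthetic-data generator produces connectomes, maps and
multi-subject stage datasets with known ground truth, so the whole
pipeline runs and is tested without any data download.

## Worked example

Generate a 30-region synthetic study, inspect the wake state, and
recover a known N2-like neuromodulatory shift:

```python
import numpy as np
from dataclasses import replace
from wbsleep.synth import make_connectome, make_maps, BASELINE_G, BASELINE_SIGMA
from wbsleep.neural import desk_config
from wbsleep.forward import seed_mean_fc
from wbsleep.fc import lower_triangle_vector
from wbsleep.hma import hma_decompose
from wbsleep.fitting import run_sweep
from wbsleep.neuromodulation import apply_modulation

conn = make_connectome(30, seed=0)
ach, na = make_maps(conn.regions, spatial_correlation=0.3, seed=1)

cfg = desk_config()
g, s = apply_modulation(BASELINE_G, BASELINE_SIGMA, 0.0, 0.0, ach, na)
fc_w = seed_mean_fc(conn, replace(cfg, g=g, sigma_e=s), seeds=range(3))
print(f"wake FC: mean {lower_triangle_vector(fc_w).mean():.3f}")

res = hma_decompose(fc_w)
print(f"HMA: H_in {res.h_in:.3f}  H_se {res.h_se:.3f}  level-2 modules {res.module_counts[1]}")

g, s = apply_modulation(BASELINE_G, BASELINE_SIGMA, 0.2, -0.4, ach, na)
fc_n2 = seed_mean_fc(conn, replace(cfg, g=g, sigma_e=s), seeds=range(10, 13))
sweep = run_sweep(fc_n2, conn, (ach, na), (BASELINE_G, BASELINE_SIGMA),
                  (np.linspace(0, 0.4, 5), np.linspace(-0.8, 0.0, 5)),
                  n_seeds=2, sim_config=cfg, modality="map", keep_optimum_fcs=False)
print(f"N2 sweep optimum: deltaG {sweep.optimum[0]:+.2f}  delta_sigma {sweep.optimum[1]:+.2f}"
      f"  (fit {sweep.fit[sweep.optimum_index].mean():.3f})")
```

Output:

```
wake FC: mean 0.311
HMA: H_in 0.128  H_se 0.248  level-2 modules 2
N2 sweep optimum: deltaG +0.20  delta_sigma -0.40  (fit 0.000)
```

The wake network shows moderate, modular FC; HMA attributes about a
third of the summed component weight to global integration; and the
sweep recovers the ground-truth shift (deltaG = +0.2,
delta_sigma = -0.4) that generated the "empirical" N2 matrix — higher
coupling and shallower slope, the modelled signature of deeper sleep.

A command-line interface mirrors the library
(`wbsleep synth|simulate|sweep|hma|empirical|fit-all|prep-homotopic`);
see `wbsleep --help`.

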