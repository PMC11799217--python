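"""Generate a two-stream scene and recover its TRF kernels by deconvolution.

A noiseless cocktail-party scene with known P1/N1/P2/Nd kernels is
generated, the ridge deconvolution is run jointly over both streams'
envelope-onset regressors plus the event regressors, and the estimated
kernels are compared with the ground truth. The bootstrap then localizes
the P1 peak latency of the recovered kernel.
"""

import numpy as np

from cocktailtrf import RegressorSet, bootstrap_peak_latency, estimate_trf
from cocktailtrf.scene import SceneSpec, gen_scene, gen_true_trf

spec = SceneSpec(n_trials=20, noise_snr_db=None, identity_mixing=True,
                 n_sensors=2, seed=1)
trf_target = gen_true_trf(attention=True)
trf_masker = gen_true_trf(attention=False)
rec, events, truth = gen_scene(spec, trf_target, trf_masker)

regs = RegressorSet(dict(truth.regressors), rec.rate)
est = estimate_trf(rec, regs, lam=1e-6)["mix"]

for name in ("target_onsets", "masker_onsets"):
    k = est.kernel(name)[0]
    gt = truth.source_kernels[name][0]
    r = np.corrcoef(k, gt)[0, 1]
    print(f"{name}: recovery r = {r:.4f}")

# bootstrap the P1 latency over pseudo-subjects (replicated kernel + jitter)
rng = np.random.default_rng(0)
subjects = est.kernel("target_onsets")[0][None, :] + 0.02 * rng.normal(
    size=(17, len(est.lags))
)
lat = bootstrap_peak_latency(subjects, est.lags, window=(0.05, 0.15),
                             n_resamples=5000, rng=rng)
print(f"P1 latency: {lat.mean*1000:.1f} ms (bootstrap SD {lat.sd*1000:.1f} ms)")
# r near 1 shows the deconvolution is exact on noiseless data; the latency
# sits at the generator's 90 ms P1 (sampled on the 128/s lag grid).
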