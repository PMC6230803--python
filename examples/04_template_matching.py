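"""Template matching: sorting more spikes than the clustering cap.

Superparamagnetic clustering cost grows with event count, so at most
``subsample_cap`` spikes (default 20,000) are clustered; every remaining
spike is assigned to the nearest cluster centroid, accepted only within
3 sigma_T of that cluster (sigma_T^2 = summed per-sample waveform variance).
Here 2,550 synthetic spikes from 3 units are sorted with a cap of 2,000 and
the 550 overflow spikes are checked against their true units.
"""

import numpy as np

from autosort import PipelineConfig, SpikeSet, sort_spikes, template_bank

rng = np.random.default_rng(0)
bank = template_bank(24000.0, 3)
n_per = 850
waveforms = np.vstack([bank[u] + rng.normal(0, 0.05, (n_per, 64))
                       for u in range(3)])
truth = np.repeat(np.arange(3), n_per)
perm = rng.permutation(waveforms.shape[0])
waveforms, truth = waveforms[perm], truth[perm]

spikes = SpikeSet(waveforms=waveforms, times=np.arange(2550) * 100,
                  peak_channel=np.zeros(2550, dtype=int), fs=24000.0)
out = sort_spikes(spikes, PipelineConfig(subsample_cap=2000, seed=1))

overflow = np.setdiff1d(np.arange(2550), out.clustered_indices)
print(f"clustered {out.clustered_indices.size} spikes, "
      f"{overflow.size} assigned by template matching")
for t in out.result.templates:
    print(f"  cluster {t.cluster_id}: {int((out.labels == t.cluster_id).sum())} "
          f"spikes, sigma_T={t.sigma_t:.3f}")

mapping = {}
for u in range(3):
    labs = out.labels[out.clustered_indices][truth[out.clustered_indices] == u]
    mapping[u] = np.bincount(labs[labs > 0]).argmax()
correct = sum(out.labels[i] == mapping[truth[i]] for i in overflow)
print(f"overflow spikes assigned to their true unit: "
      f"{correct}/{overflow.size} ({100 * correct / overflow.size:.1f}%)")
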