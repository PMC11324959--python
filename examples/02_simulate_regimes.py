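"""Healthy versus abnormal striatal activity on a reduced network.

Simulates 1 s of a 500-neuron density-matched network under healthy
cortico-striatal drive (I0 = 5 uA/cm^2) and under the reduced drive that
models the pathological state (I0 = 1.5), then prints the three macroscopic
biomarkers: mean per-neuron rate, dominant spectral peak of the mean
membrane potential, and the gamma band fraction ([30, 80] / [0, 300] Hz).
"""

from striatonet import (
    ModelParams,
    band_fraction,
    build_network,
    generate_synthetic_striatum,
    mean_activity,
    power_spectrum,
    simulate,
)

table = generate_synthetic_striatum(500, seed=0)
net = build_network(table, seed=0)
cut = int(200.0 / 0.05)  # discard the settling transient before the FFT

for label, I0 in (("healthy", 5.0), ("abnormal", 1.5)):
    res = simulate(net, ModelParams().with_drive(I0), t_end=1000.0, dt=0.05, seed=1)
    act = mean_activity(res.spikes, net.n, 1000.0)
    spec = power_spectrum(res.mean_V[cut:], 0.05, smooth_width=2.0)
    print(
        f"{label:9s} (I0={I0}): rate {act.time_mean():5.1f} Hz/neuron | "
        f"spectral peak {spec.peak_frequency(f_min=1.0):5.1f} Hz | "
        f"gamma fraction {band_fraction(spec):.2f}"
    )

print(
    "\nLowering the drive collapses the firing rate several-fold and shifts\n"
    "the rhythm out of the gamma band toward low frequencies - the model's\n"
    "signature of disturbed cortico-striatal input."
)
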