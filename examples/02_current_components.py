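"""Separate the IPSC into synchronous and asynchronous components.

Sweeps the asynchronous sensor's decay constant tau_ar and prints the charge
(time-integral of current magnitude) carried by each release pathway.  Slower
Ca2+ clearance (larger tau_ar) lets the asynchronous release rate accumulate,
which grows the asynchronous charge and — because both pathways draw on the
same vesicle pool — shrinks the synchronous charge.
"""

import numpy as np

from sarsyn import ReceptorKernel, SARParams, simulate, split_currents

kernel = ReceptorKernel(tau_syn=5.0, A=10.0, D=0.0)  # quantal amplitude 10 pA
spikes = 10.0 * np.arange(10)

print("tau_ar [ms]   charge_sr [pA*ms]   charge_ar [pA*ms]   async share")
for tau_ar in (8.0, 12.0, 16.0, 22.0, 30.0):
    params = SARParams(tau_sr=1.0, U_sr=0.11, tau_ar=tau_ar, U_ar=0.0035,
                       U_max=0.5, tau_d=60.0, N_F=271, x0=1.0)
    trace = simulate(params, spikes, T=200.0, dt=0.05, mode="deterministic")
    total, I_sr, I_ar = split_currents(trace, kernel)
    q_sr = I_sr.I.sum() * trace.dt
    q_ar = I_ar.I.sum() * trace.dt
    print(f"   {tau_ar:5.1f}       {q_sr:10.0f}         {q_ar:10.0f}"
          f"          {q_ar / (q_sr + q_ar):.2f}")

print("\nThe asynchronous charge rises monotonically with tau_ar while the")
print("synchronous charge falls: vesicle competition between the pathways.")
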