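"""Miniature parameter-recovery study (5 settings; the full one uses 30+).

Draws ground-truth parameter settings, simulates 50 stochastic trials of a
25-spike 100 Hz train each, fits every setting with the two-stage grid
search, and prints estimated-vs-true R^2 per parameter.  The full-size run
is available as `sarsyn recover` or `python scripts/acceptance.py`.
"""

from sarsyn import recovery_experiment

rep = recovery_experiment(n_settings=5, trials=50, n_spikes=25, seed=11)

print("parameter    R^2 (estimated vs true, 5 settings)")
for p in ("U_sr", "tau_d", "tau_ar", "tau_sr", "c_ar", "U_max", "U_ar"):
    label = "U_max*U_ar" if p == "c_ar" else p
    print(f"  {label:10s}  {rep.r2[p]:.3f}")
print(f"\nmean relative log-likelihood deviation (fit vs truth): "
      f"{rep.rel_dev_pct:.2f}%")
print("\nU_sr and tau_d are pinned by the depressing synchronous envelope;")
print("U_max and U_ar are individually free along a ridge, but their product")
print("is recovered. With only 5 settings the R^2 values are rough — run 30+")
print("settings for stable numbers.")
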