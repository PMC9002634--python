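"""Compare the time-efficient two-frame analysis against frame-by-frame
digitization.

Both routes are run over the 88 trials of a synthetic test-retest cohort.
The two digitizations carry independent +-1 mm-scale landmark noise (as two
independent operators would), so their *measured* maximal strains differ;
the printed Pearson r and RMS difference quantify the agreement.
"""

import tendonmetrics as tm

dataset, _ = tm.simulate_cohort(tm.GeneratorConfig(seed=1))
results, _ = tm.analyze_session(dataset, method="both")

agreement = tm.compare_methods(results)
print(f"trials compared      {len(agreement.table)}")
print(f"Pearson r            {agreement.pearson_r:.3f} (p = {agreement.pearson_p:.2e})")
print(f"RMS difference       {agreement.rms:.3f} % strain")
print()
print("An RMS below ~1% strain with r well above 0.8 means the two-frame")
print("shortcut loses essentially nothing relative to digitizing every")
print("ultrasound frame of the contraction.")
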