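"""Per-nucleotide error subtraction with a matched gene control.

A gene-specific control adaptor carries the reference sequence of a
clinical exon, so it experiences the same context-dependent systematic
errors as the patient DNA it flanks. Subtracting the control's per-position
error profile from the sample's suppresses the shared background while
true variants — present only in the sample — stand out.
"""

import numpy as np

import captorkit as ck
from captorkit.align import profile_reads_to_reference
from captorkit.profiling import (profile_correlation, profile_rates,
                                 restrict_to_variants, subtract_profiles)
from captorkit.simulate import simulate_reads_from_reference

rng = np.random.default_rng(6)
exon = "".join("ACGT"[b] for b in rng.integers(0, 4, 500))
model = ck.build_context_error_model(rng_seed=0)
variants = {120: 0.5, 260: 0.4, 410: 0.6}  # position -> allele fraction

control_reads = simulate_reads_from_reference(exon, 500, model, rng_seed=1)
sample_reads = simulate_reads_from_reference(
    exon, 500, model, rng_seed=2, variant_positions=variants)
control = profile_rates(profile_reads_to_reference("ctrl", exon,
                                                   control_reads))
sample = profile_rates(profile_reads_to_reference("samp", exon,
                                                  sample_reads))

corr = profile_correlation(sample, control)
print("sample/control error correlation per class:",
      {k: round(v, 2) for k, v in corr.items()})

report = subtract_profiles(sample, control)
summary = report.summary()
print(f"median total error: {summary['total']['median_before']:.3f} -> "
      f"{summary['total']['median_after']:.3f} after subtraction")
for pos, vaf in variants.items():
    print(f"  variant at {pos} (allele fraction {vaf}): corrected mismatch "
        f"rate {report.corrected_rates['mismatch'][pos]:.2f}")

masked = restrict_to_variants(report, np.array(list(variants)))
ms = masked.summary()
print(f"restricted to variant positions: median mismatch "
      f"{ms['mismatch']['median_before']:.3f} -> "
      f"{ms['mismatch']['median_after']:.3f}")

# Background error collapses by an order of magnitude while the variant
# positions keep rates near their allele fractions: subtraction turns a
# noisy raw profile into one where variants are unambiguous.
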