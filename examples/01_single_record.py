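"""Clean one synthetic 24-h tachogram and compute linear HRV indices.

A raw tachogram carries ectopic beats; the adaptive filter replaces them
by interpolation, then the record is sliced into the four analysis
segments and time- and frequency-domain indices are printed per segment.
"""

from hrvrisk import adaptive_nn_filter, exclusion_check
from hrvrisk.linear_hrv import frequency_indices, power_spectrum, time_domain_indices
from hrvrisk.pipeline import segment_record
from hrvrisk.synthetic_cohort import LR_PROFILE, generate_nn_record

rec = generate_nn_record(LR_PROFILE, duration_s=86400, seed=42)
nn = adaptive_nn_filter(rec.tachogram)
print(f"{len(nn)} beats over {nn.duration_s / 3600:.1f} h, "
      f"{100 * nn.ectopy_fraction:.1f}% beats replaced, "
      f"excluded: {exclusion_check(nn)}")

for label, seg in segment_record(nn).items():
    td = time_domain_indices(seg)
    fi = frequency_indices(power_spectrum(seg))
    print(f"{label:>8}: meanNN={td['meanNN']:7.1f} ms  sdNN={td['sdNN']:6.1f} ms  "
          f"rmssd={td['rmssd']:5.1f} ms  LF/HF={fi['LF/HF']:5.2f}  "
          f"VLF/P={fi['VLF/P']:.2f}")
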