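"""Symbolic-dynamics index families on one 30-min segment.

The NN series is coarse-grained four ways — classical 4-symbol coding,
binary difference coding, 6-level short-term quantization and
SD-scaled difference counting — and the headline index of each family
is printed.
"""

from hrvrisk import adaptive_nn_filter, first_30min
from hrvrisk.symbolic_dynamics import (
    binary_variability_patterns,
    classical_sd_indices,
    encode_classical,
    sdsd,
    stsd,
    word_histogram,
)
from hrvrisk.synthetic_cohort import HR_PROFILE, LR_PROFILE, generate_nn_record

for profile in (LR_PROFILE, HR_PROFILE):
    rec = generate_nn_record(profile, duration_s=3600, seed=7)
    seg = first_30min(adaptive_nn_filter(rec.tachogram))

    sd = classical_sd_indices(word_histogram(encode_classical(seg)))
    bp = binary_variability_patterns(seg)
    st = stsd(seg).aggregates
    out = sdsd(seg)

    print(f"--- {profile.label} ({len(seg)} beats) ---")
    print(f"wpsum02={sd['wpsum02']:.3f}  wpsum13={sd['wpsum13']:.3f}  "
          f"pTH1={sd['pTH1']}")
    print(f"plvar5={bp['plvar5']:.3f}  phvar5={bp['phvar5']:.3f}")
    print(f"m_ST_0V={st['m_ST_0V']:.3f}  m_ST_2V={st['m_ST_2V']:.3f}  "
          f"m_ST_ASC={st['m_ST_ASC']:.3f}")
    print(f"tau1_p001={out['tau1_p001']}")
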