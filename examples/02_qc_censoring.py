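"""Motion-based volume censoring and scan-level quality control.

Computes framewise displacement from six rigid-body parameters, flags
intensity-outlier volumes, censors by both criteria and applies the
120-volume scan-exclusion rule.
"""

import cerebgrad as cg
from cerebgrad.qc import qc_report
from cerebgrad.synth import generate_bold, generate_motion_trace, make_ground_truth

config = cg.CohortConfig(n_subjects=4, n_voxels=80, n_volumes=200, seed=7,
                         spike_rate=0.05)
truth = make_ground_truth(config)

for i in range(config.n_subjects):
    bold = generate_bold(truth, i, config)
    trace = generate_motion_trace(config, i)
    fd = cg.framewise_displacement(trace)           # mm per volume
    frac = cg.outlier_fraction(bold)                # outlier-voxel fraction
    mask = cg.censor_volumes(fd, frac)              # fd > 0.2 mm OR frac > 10%
    rep = qc_report(mask, subject_id=bold.subject_id)
    print(f"{bold.subject_id}: retained {rep['retained']}/{rep['n_volumes']} volumes "
          f"(censored {rep['censored']}), passes QC: {rep['passes_qc']}")

print("\nA volume is censored when volume-to-volume motion exceeds 0.2 mm or "
      "more than 10% of voxels are intensity outliers; scans keeping fewer "
      "than 120 clean volumes (4 min of data) are excluded entirely.")
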