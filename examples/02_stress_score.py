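"""Directional stress scoring of a before/during HRV feature pair.

Six of the seven features move in their stressful direction (HR and
LF/HF up; SDNN, RMSSD, pNN50, HF down; TP unchanged), which lands the
case in the 85.71% bin — the modal score in the study this package
reimplements — and above the 50% binary threshold.
"""

from rtstress import score
from rtstress.types import HRVFeatures

before = HRVFeatures(hr=68, sdnn=42, rmssd=38, pnn50=22,
                     lf=520, hf=430, lf_hf=1.21, tp=1500)
during = HRVFeatures(hr=75, sdnn=35, rmssd=30, pnn50=15,
                     lf=560, hf=350, lf_hf=1.60, tp=1500)

assessment = score.assess(before, during)
for name, moved in assessment.labels.items():
    print(f"  {name:6s} -> {'stressful shift' if moved else 'no'}")
print(f"stress score : {assessment.score:.2f} %")
print(f"stress call  : {'yes' if assessment.stressed else 'no'} "
      "(threshold: score > 50%)")
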