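"""End-to-end synthetic study: cohort, scores, summaries, prediction,
association — every artifact written under out/example_run/.

Rerunning with the same seed reproduces byte-identical CSV outputs.
"""

from rtstress import report
from rtstress.config import load_config

cfg = load_config(seed=17, cohort={"n_patients": 41})
res = report.run_pipeline(cfg, "out/example_run")

print("stress-score distribution (count, % of cases):")
print(res["summary"]["bins"].to_string(index=False))
print()
print(f"cases with any stress : {res['summary']['pct_nonzero']:.2f} %")
print(f"cases above threshold : {res['summary']['pct_above_threshold']:.2f} %")
print()
print("day-by-sex comparison (mean ± sd, Mann-Whitney p):")
print(res["comparisons"]["table"].to_string())
print()
print("stress vs respiratory irregularity (GEE):")
print(res["associations"].to_string(index=False))
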