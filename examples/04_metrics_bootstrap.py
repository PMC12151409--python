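"""Bootstrap the one-class performance metrics of a scored test set.

Reports AUC plus the constrained sensitivity/specificity pairs used in QA
settings (Sens80: best sensitivity at >= 80% specificity, Spec100: best
specificity at 100% sensitivity, etc.), each with a 95% t-interval over 100
stratified bootstrap resamples.
"""

from oart import (
    OartConfig,
    SyntheticSpec,
    bootstrap_metrics,
    oart_sigma_scores,
    run_synthetic_study,
)

split, ensemble, _, _ = run_synthetic_study(SyntheticSpec(seed=4), OartConfig(seed=4))
scores = oart_sigma_scores(split.test.values, ensemble)
report = bootstrap_metrics(scores, split.test.labels, n_bootstrap=100, seed=4)

print(report.to_frame().to_string(index=False))
# Spec80 reads: the fraction of acceptable plans that could be auto-accepted
# without review while still catching >= 80% of unacceptable plans.
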