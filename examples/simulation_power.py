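"""Operating characteristics at one simulation setting.

Estimates the rejection rate of each analysis strategy at a non-null
setting (methylation -> expression -> endpoints all linked) and at the
matching null setting, at a reduced replicate count so the script runs in
seconds. The `ccpromise simulate` CLI subcommand exposes the same loop.
"""

from ccpromise.permutation import PermutationConfig
from ccpromise.simulation import SimulationSetting, run_setting

cfg = PermutationConfig(B0=100, B1=2000)

for label, setting in [
    ("alternative (bm=bx=by=0.5, n=100)", SimulationSetting(0.5, 0.5, 0.5, 100)),
    ("null        (by=0,         n=100)", SimulationSetting(0.5, 0.5, 0.0, 100)),
]:
    res = run_setting(setting, reps=100, alpha=0.01, perm_cfg=cfg, seed=42)
    rates = "  ".join(f"{m}={v:.2f}" for m, v in res.rejection_rate.items())
    print(f"{label}\n  {rates}\n")

print(
    "Each number is the fraction of 100 simulated single-gene datasets the\n"
    "method declared significant at p <= 0.01: power at the alternative\n"
    "setting, type I error at the null setting. The unadjusted minimum-p\n"
    "methods (UXPR, UMPR) inflate the null rate; the score-based combined\n"
    "analysis (CCPR) stays near 0.01 while retaining high power."
)
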