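"""Rank two candidate compounds by their maximal probability of success.

Both compounds must normalise an elevated central (brain) target while
preserving at least 10% of peripheral target activity; benefit must hold in
>= 80% of patients with < 5% at risk of peripheral over-inhibition.  The
compounds differ in brain partitioning (kp,uu uncertainty ranges) and
peripheral potency, so their benefit-risk windows differ in width.
"""

from pops.assemble import run_config
from pops.engine import optimal_dose
from pops.fixtures import make_case1_config

case = make_case1_config(seed=1)
for name, cfg in case.configs.items():
    curve = run_config(cfg)
    dose, best = optimal_dose(curve)
    print(f"\n{name} (M={curve.m} trials x N={curve.n} subjects)")
    print("  dose [mg]:", [f"{d:g}" for d in curve.doses])
    print("  PoPS:     ", [f"{p:.2f}" for p in curve.pops])
    print(f"  maximal PoPS {best:.0%} at {dose:g} mg daily")

print(
    "\nThe compound with the higher maximal PoPS offers the wider window between\n"
    "central efficacy and the peripheral safety ceiling; the dose at the maximum\n"
    "is the best-supported daily dose under all stated uncertainties."
)
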