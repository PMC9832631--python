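"""Antibody dose selection on a tissue-translated protein endpoint.

A monoclonal antibody binds a soluble target (target-mediated drug
disposition); the pharmacology endpoint is suppression of a downstream
protein in the target tissue, translated from serum through an uncertain
plasma-to-tissue distribution coefficient.  Success demands that more than
half the subjects reach the required inhibition (itself uncertain, uniform
70-95%) while more than half stay within the systemic exposure limit.
"""

import numpy as np

from pops.assemble import run_config
from pops.engine import optimal_dose
from pops.fixtures import make_case3_config
from pops.pkpd import Regimen, TMDDParams, tmdd_profile

curve = run_config(make_case3_config(seed=3).configs["base"])
dose, peak = optimal_dose(curve)
print(f"PoPS over Q4W doses (M={curve.m} x N={curve.n}):")
for d, p, s in zip(curve.doses, curve.pops, curve.pass_rate["safety"]):
    print(f"  {d:>7g} mg: PoPS {p:.2f}  (safety pass rate {s:.2f})")
print(f"peak PoPS {peak:.0%} at {dose:g} mg; the top dose collapses on safety alone")

# the underlying mechanistic layer: one TMDD profile with target occupancy
p = TMDDParams(cl=0.012, v1=3.0, q=0.02, v2=3.0, ksyn=0.05, kdeg=0.1,
               kint=0.03, kss=0.5)
prof = tmdd_profile(p, Regimen(dose=600.0, tau=672.0, route="iv_bolus"),
                    np.linspace(0.0, 672.0, 8))
print("\nsingle-dose TMDD profile (600 mg IV, Q4W interval):")
print("  t [h]      :", [f"{t:7.0f}" for t in prof["time"]])
print("  occupancy  :", [f"{o:7.3f}" for o in prof["occupancy"]])
print(
    "\nTarget occupancy stays near-saturated across the interval at this dose,\n"
    "which is why the population endpoint model can use the linear-clearance\n"
    "steady-state exposure."
)
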