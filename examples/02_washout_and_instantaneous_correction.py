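"""Chamber washout and the instantaneous (z-transform) correction.

A 13-liter chamber pulled at 1700 ml/min has a time constant of ~7.6 min, so
the outlet O2 signal smears any metabolic change over tens of minutes.  The
correction F + tau*dF/dt recovers the instantaneous signal.
"""

import numpy as np

from aviphen import respirometry

tau_min = respirometry.time_constant(13.0, 1700.0)
tau_s = tau_min * 60.0
print(f"time constant: {tau_min:.2f} min "
      f"({respirometry.washout_fraction(tau_s, tau_s):.1%} of chamber air "
      "replaced after one tau)")

# a step change in metabolic rate, seen through the chamber
t = np.arange(3600.0)
true_deficit = np.where(t >= 600, 1.0e-3, 0.0)   # O2 fraction units
outlet = np.empty_like(t)
outlet[0] = 0.0
a = np.exp(-1.0 / tau_s)
for i in range(1, t.size):
    outlet[i] = a * outlet[i - 1] + (1 - a) * true_deficit[i - 1]

corrected = respirometry.instantaneous_correct(outlet, tau_s)
i_check = 1200   # 10 min after the step
print(f"10 min after the step: outlet shows {outlet[i_check]/1e-3:.0%} of the "
      f"change, corrected signal {corrected[i_check]/1e-3:.0%}")
# The raw outlet is still far from equilibrium one tau after the step; the
# corrected trace sits on the true value within a few samples.
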