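"""Date-indexed farm reports on a simulated flock.

Every report is computed as of a chosen date, current or past, from the
event ledger: inventories, lambing rate, disposals and a yearly trend.
"""

import datetime as dt

from flockgen import SimParams, simulate_flock
from flockgen.reports import (
    ReportRequest, disposal_report, inventory_report, reproduction_report,
    trend_report,
)

ds, _ = simulate_flock(SimParams(n_founder_sires=8, n_founder_dams=60,
                                 n_generations=3, survival_to_12m=0.85,
                                 n_farms=2, seed=3))

req = ReportRequest(as_of=dt.date(2012, 12, 31))
inv = inventory_report(ds, req)
print("inventory on", req.as_of)
print(inv.table.to_string(index=False))

rep = reproduction_report(ds, req)
print(f"\n2012 season: {rep.metadata['n_lambings']} lambings, "
      f"{rep.metadata['breedable_ewes_at_start']} breedable ewes at year "
      f"start -> lambing rate {rep.metadata['lambing_rate']:.3f}")

disp = disposal_report(ds, req)
print(f"disposals 2012 by reason: {disp.metadata['by_reason']}, "
      f"mortality {disp.metadata['mortality']:.3f}")

trend = trend_report(ds, "TOTAL", [2010, 2011, 2012])
print("\nflock size trend:")
print(trend.table.to_string(index=False))
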