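"""Glycemic-event metrics on a hand-built example: event extraction,
glucose-specific RMSE, and the Matthews correlation coefficient.
"""
import numpy as np

from glyforecast.evaluate import (EventConfusion, extract_events, grmse,
                                  grmse_penalty, mcc, pointwise_metrics)
from glyforecast.datatypes import CgmSeries, regular_grid
import pandas as pd

g = np.array([120, 95, 80, 65, 64, 62, 66, 90, 130, 185, 190, 195, 170, 150.0])
cgm = CgmSeries(regular_grid(pd.Timestamp("2024-03-01"), len(g)), g)

for kind in ("hypo", "hyper"):
    for ev in extract_events(cgm, kind):
        print(f"{kind} event: {ev.start.time()}-{ev.end.time()} "
              f"({ev.n_readings} readings)")

pred = g + np.array([0, 0, 5, 18, 15, 20, 4, 0, 0, -12, -20, -15, 0, 0.0])
m = pointwise_metrics(g, pred)
print(f"RMSE {m['rmse']:.2f}  gRMSE {grmse(g, pred):.2f} mg/dL")
print(f"penalty at (G=64, G_hat=82): {grmse_penalty(np.array([64.0]), np.array([82.0]))[0]:.2f}")

conf = EventConfusion(tp=10, fp=5, fn=5, tn=80)
print(f"MCC for (TP,FP,FN,TN)=(10,5,5,80): {mcc(conf):.3f}")

# gRMSE exceeds RMSE exactly when errors are clinically dangerous: here the
# predictions overestimate during the hypoglycemic run and underestimate the
# hyperglycemic one, so each squared error is inflated by a penalty up to
# 2.5x (low branch) or 2x (high branch).
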