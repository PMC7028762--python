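"""Solve the generator's per-visit latent means so that pipeline mean utility and MCS match the calibration targets; the solution is frozen in psycea.synthetic."""
import numpy as np
from scipy.optimize import fsolve
import pandas as pd
from psycea.qol import SF12_ITEMS, ITEM_COLUMNS, score_sf12, utilities_from_sf12
from psycea.synthetic import SEVERITY_THRESHOLDS

N = 60000
rng = np.random.default_rng(12345)
client_sd, cor, noise_sd = 0.8, 0.3, 0.7
cov = np.array([[1,cor],[cor,1]])*client_sd**2
b = rng.multivariate_normal([0,0], cov, size=N)   # client effects
noise = {item: rng.normal(0, noise_sd, N) for item in ITEM_COLUMNS}

def simulate(mp, mm):
    rows = {"client_id": np.arange(N), "visit": 0}
    df = pd.DataFrame(rows)
    for item in ITEM_COLUMNS:
        levels, domain, best = SF12_ITEMS[item]
        latent = (mp + b[:,0]) if domain=="phys" else (mm + b[:,1])
        s = -latent + noise[item]
        sev = np.ones(N, dtype=int)
        for t in SEVERITY_THRESHOLDS[levels]:
            sev += (s > t)
        resp = sev if best==1 else levels+1-sev
        df[item] = resp
    sc = score_sf12(df)
    ut = utilities_from_sf12(df)
    return float(ut.utility.mean()), float(sc.mcs.mean()), float(sc.pcs.mean())

targets = [(0.6051,35.4),(0.6535,40.3),(0.6602,41.2),(0.6927,44.2)]
sols = []
for (ut_t, mcs_t) in targets:
    def f(x):
        u,m,_ = simulate(x[0],x[1])
        return [u-ut_t, m-mcs_t]
    x = fsolve(f, [0.0,-0.5], xtol=1e-4)
    u,m,p = simulate(*x)
    sols.append(x)
    print(f"target (u={ut_t}, mcs={mcs_t}) -> mu_phys={x[0]:.4f} mu_ment={x[1]:.4f}  got u={u:.4f} mcs={m:.2f} pcs={p:.2f}")
base = sols[0]
print("phys_mean=%.4f ment_mean=%.4f" % (base[0], base[1]))
print("phys_drift=", tuple(round(s[0]-base[0],4) for s in sols[1:]))
print("ment_drift=", tuple(round(s[1]-base[1],4) for s in sols[1:]))
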