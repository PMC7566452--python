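"""Calibrate the SYNTHETIC stand-in species-specific allometric models.

The two generalised models in the bank (jenkins, chojnacky) carry their
published coefficients.  The five species-specific redwood models are
stand-ins: the original coefficient tables are not distributed with this
package, so each stated functional form is calibrated once against the
analytic stem family of :mod:`tlstree.synthetic` (total wood volume from
quadrature, equivalent-area and mean-radius diameters in closed form) with
a wood density of 380 kg/m^3.  The resulting YAML block is printed; it is
pasted into ``src/tlstree/data/allometric_models.yaml`` and never refitted
at run time.

Usage:  python scripts/calibrate_standin_models.py
"""

import math

import numpy as np
import pandas as pd

from tlstree.allometry import fit_power_law
from tlstree.synthetic import cohort_specs, ground_truth

RHO = 380.0  # kg/m^3, basic-density class of coastal redwood wood


def family_sample(seed: int = 20_17, n_extra_cohorts: int = 2) -> pd.DataFrame:
    rows = []
    for c in range(n_extra_cohorts):
        df = cohort_specs(seed=seed + c)
        for sp in df["spec"]:
            gt = ground_truth(sp)
            b13 = sp.buttress_factor(1.3)
            rows.append(
                dict(
                    H=sp.height_m,
                    DBH=2.0 * float(sp.r0(1.3) * b13),  # circle-fit (mean-radius) diameter
                    fDBH=gt.dbh_true_m,  # equivalent-area diameter
                    DTB=2.0 * float(sp.r0(4.25) * sp.buttress_factor(4.25)),
                    V=gt.total_volume_m3,
                    AGB_kg=RHO * gt.total_volume_m3,
                )
            )
    return pd.DataFrame(rows)


def main() -> None:
    df = family_sample()
    print(f"# calibrated on {len(df)} analytic stems, "
          f"DBH {df.DBH.min():.2f}-{df.DBH.max():.2f} m, H {df.H.min():.0f}-{df.H.max():.0f} m")

    out = {}
    # parks: V = a * DBH^b * H^c
    f = fit_power_law(df, "V", ("DBH", "H"), weighting="relative")
    out["parks"] = ("volume_density", f.coefficients, f.rmse_percent)
    # fujimori: V = a * (DBH^2 H)^b  (single combined predictor)
    x = np.log(df.DBH**2 * df.H)
    A = np.column_stack([np.ones(len(x)), x])
    sol, *_ = np.linalg.lstsq(A, np.log(df.V), rcond=None)
    a, b = math.exp(sol[0]), sol[1]
    pred = a * (df.DBH**2 * df.H) ** b
    rmse = 100 * np.sqrt(np.mean((pred - df.V) ** 2)) / df.V.mean()
    out["fujimori"] = ("volume_density", {"a": a, "b_DBH": 2 * b, "b_H": b}, rmse)
    # sillett2015: V = a * DTB^b * fDBH^c
    f = fit_power_law(df, "V", ("DTB", "fDBH"), weighting="relative")
    out["sillett2015"] = ("volume_density", f.coefficients, f.rmse_percent)
    # sillett2019: V = a * DTB^b * H^c
    f = fit_power_law(df, "V", ("DTB", "H"), weighting="relative")
    out["sillett2019"] = ("volume_density", f.coefficients, f.rmse_percent)
    # kizha_han: ln(AGB_kg) = b0 + b1 ln(DBH_cm), CF from log-residual variance
    lx = np.log(df.DBH * 100.0)
    A = np.column_stack([np.ones(len(lx)), lx])
    sol, *_ = np.linalg.lstsq(A, np.log(df.AGB_kg), rcond=None)
    resid = np.log(df.AGB_kg) - A @ sol
    cf = math.exp(float(np.var(resid, ddof=2)) / 2.0)
    out["kizha_han"] = ("log_log", {"b0": float(sol[0]), "b1": float(sol[1])}, cf)

    for mid, (form, coef, extra) in out.items():
        print(f"\n{mid}: form={form}")
        for k, v in coef.items():
            print(f"    {k}: {v:.6g}")
        print(f"    # fit rmse%%/CF: {extra:.4g}")


if __name__ == "__main__":
    main()
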