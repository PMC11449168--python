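#!/usr/bin/env python
"""Derived personality statistics from the fitted posterior, plus the
associates Poisson GLMM on the telemetry-derived counts.

Reads results/fit/ and results/metrics/; writes results/derived/ with the
derived-statistics table, caterpillar/forest plots and the associates-model
summary.
"""

import warnings
from pathlib import Path

import pandas as pd

# refits quickly instead of persisting the full posterior: the fit script
# stores only summaries, and the derived statistics need the draws
from crocsoc import derived_stats as ds
from crocsoc.dhglm import SamplerConfig, fit_dhglm, prepare_model_data
from crocsoc.plots import caterpillar_plot, correlation_forest_plot

IN_SIM = Path("results/simulation")
IN_MET = Path("results/metrics")
OUT = Path("results/derived")
OUT.mkdir(parents=True, exist_ok=True)

panel = pd.read_csv(IN_SIM / "panel.csv")
keep_ids = sorted(panel["individual_id"].unique())[:60]
panel = panel[panel["individual_id"].isin(keep_ids) & (panel["t"] <= 48)]
data = prepare_model_data(panel, transform=False)
cfg = SamplerConfig(chains=2, iterations=3000, warmup=1500, thin=2,
                    ess_threshold=400.0)
with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    draws = fit_dhglm(data, sampler=cfg, seed=2)

rows = []
for beh in ("sociability", "activity", "site_fidelity"):
    r = ds.repeatability(draws, beh)
    cv = ds.coefficient_of_predictability(draws, beh)
    rows.append((r.name, r.mean, r.hpd_low, r.hpd_high, r.significant))
    rows.append((cv.name, cv.mean, cv.hpd_low, cv.hpd_high, cv.significant))
    print(f"{beh:14s} R = {r.mean:.2f} ({r.hpd_low:.2f} to {r.hpd_high:.2f})  "
          f"CV_p = {cv.mean:.2f} ({cv.hpd_low:.2f} to {cv.hpd_high:.2f})")

corr = ds.random_effect_correlations(draws)
for _, row in corr.iterrows():
    star = "*" if row["significant"] else " "
    print(f"{row['kind']:10s} {row['label']:28s} r = {row['mean']:+.2f} "
          f"({row['hpd_low']:+.2f} to {row['hpd_high']:+.2f}){star}")
    rows.append((f"{row['kind']}[{row['label']}]", row["mean"], row["hpd_low"],
                 row["hpd_high"], row["significant"]))
pd.DataFrame(
    rows, columns=["quantity", "mean", "hpd_low", "hpd_high", "significant"]
).to_csv(OUT / "derived_stats.csv", index=False)

realized = ds.realized_phenotypes(draws, "activity")
realized.to_csv(OUT / "realized_activity.csv", index=False)
caterpillar_plot(realized, "realized_phenotype", OUT / "caterpillar_activity.png",
                 title="daily activity phenotypes")
correlation_forest_plot(corr, OUT / "correlation_forest.png")

counts = pd.read_csv(IN_MET / "associate_counts.csv")
if counts.empty or (counts["count"] == 0).all():
    print("associates model skipped: no counts with home ranges")
else:
    res = ds.fit_associates_glmm(counts, iterations=2000, warmup=800, seed=3)
    res.summary.to_csv(OUT / "associates_model.csv", index=False)
    q = res.coefficient("hr_size:type_observed")
    print(f"associates model interaction (hr size x observed): "
          f"{q.mean:+.2f} ({q.hpd_low:+.2f} to {q.hpd_high:+.2f})")
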