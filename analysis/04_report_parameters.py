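"""Natural-scale parameter summaries and posterior predictions.

Produces, from the saved fits:

* a parameter table with posterior means and 89% HPDIs per age class and sex
  for every fitted model (results/parameter_summary.csv);
* daily posterior-mean technique probabilities with raw-frequency overlays
  per group (results/predictions_daily_<spec>.csv);
* a figure of the daily diffusion curves for the best model
  (results/figures/daily_predictions.png).
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from ewalearn.compare import posterior_predict
from ewalearn.cues import CueWindowConfig
from ewalearn.design import build_design
from ewalearn.events import read_event_log
from ewalearn.inference import load_fit, natural_scale

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/synthetic"))
parser.add_argument("--fits", type=Path, default=Path("results/fits"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--window-min", type=float, default=20.0)
parser.add_argument("--plot-spec", default="payoff_bias")
args = parser.parse_args()

log = read_event_log(args.data / "events.csv", args.data / "individuals.csv", args.data / "kin.csv")
design = build_design(log, CueWindowConfig(width_min=args.window_min))
args.out.mkdir(parents=True, exist_ok=True)

summaries = []
for sub in sorted(args.fits.iterdir()):
    if not (sub / "fit.json").exists():
        continue
    samples = load_fit(sub, design)
    for who in ("female", "male", "juvenile", "adult"):
        df = natural_scale(samples, who).reset_index()
        df.insert(0, "class", who)
        df.insert(0, "model", sub.name)
        summaries.append(df)
    daily = posterior_predict(samples, "population-daily", max_draws=200)
    daily.to_csv(args.out / f"predictions_daily_{sub.name}.csv", index=False)
    if sub.name == args.plot_spec:
        fig, axes = plt.subplots(1, design.n_groups, figsize=(6 * design.n_groups, 4), squeeze=False)
        for ax, group in zip(axes[0], design.group_names):
            gdf = daily[daily.group == group]
            for tech in design.techniques:
                t = gdf[gdf.technique == tech].sort_values("date")
                x = range(len(t))
                ax.plot(x, t["mean"], label=f"{tech} (posterior)")
                ax.fill_between(x, t["hpdi_lo"], t["hpdi_hi"], alpha=0.2)
                ax.plot(x, t["raw_freq"], "o--", alpha=0.5, label=f"{tech} (raw)")
            ax.set_title(f"group {group}")
            ax.set_xlabel("experimental day")
            ax.set_ylabel("daily technique probability")
        axes[0, 0].legend(fontsize=7)
        figdir = args.out / "figures"
        figdir.mkdir(exist_ok=True)
        fig.tight_layout()
        fig.savefig(figdir / "daily_predictions.png", dpi=120)
        print(f"figure -> {figdir / 'daily_predictions.png'}")

table = pd.concat(summaries)
table.to_csv(args.out / "parameter_summary.csv", index=False)
wide = table[table.parameter.isin(["lambda", "phi", "gamma"])].pivot_table(
    index=["parameter", "class"], columns="model", values="mean"
)
print(wide.round(3).to_string())
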