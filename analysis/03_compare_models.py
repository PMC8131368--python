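"""WAIC comparison of the fitted learning-strategy models.

Reads the pointwise log-likelihood matrices persisted by 02_fit_models.py and
writes the ranked comparison table (WAIC, SE, dWAIC, weight) to
results/waic_comparison.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from ewalearn.compare import compare_models, compute_waic

parser = argparse.ArgumentParser()
parser.add_argument("--fits", type=Path, default=Path("results/fits"))
parser.add_argument("--out", type=Path, default=Path("results/waic_comparison.csv"))
args = parser.parse_args()

results = []
for sub in sorted(args.fits.iterdir()):
    ll_path = sub / "pointwise_loglik.parquet"
    if ll_path.exists():
        results.append((sub.name, compute_waic(pd.read_parquet(ll_path).to_numpy())))

table = compare_models(results)
table.to_csv(args.out)
print(table.round(2).to_string())
best = table.index[0]
print(f"\nbest-predicting model: {best} (weight {table.loc[best, 'weight']:.2f})")
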