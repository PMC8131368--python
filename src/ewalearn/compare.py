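"""Model comparison (WAIC), HPDI summaries and posterior predictions.

WAIC is reported on the deviance scale, ``-2 (lppd - p_waic)``, with

    lppd   = sum_e log( mean_draws  exp(ll_e) )
    p_waic = sum_e var_draws( ll_e )

and the standard error from the pointwise deviance terms.  Akaike-style
weights over a comparison set are ``exp(-dWAIC/2)`` renormalised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ewalearn.inference import PosteriorSamples


@dataclass
class WAICResult:
    """Deviance-scale WAIC for one fitted model."""

    waic: float
    se: float
    p_waic: float
    n_events: int
    dwaic: float | None = None
    weight: float | None = None


def compute_waic(pointwise_loglik: np.ndarray) -> WAICResult:
    """WAIC from a [draws, events] pointwise log-likelihood matrix."""
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be a draws x events matrix")
    S, E = ll.shape
    if S < 2:
        raise ValueError("p_waic is undefined with a single draw; need >= 2")
    lppd_e = logsumexp(ll, axis=0) - np.log(S)
    p_e = ll.var(axis=0, ddof=1)
    waic_e = -2.0 * (lppd_e - p_e)
    waic = float(waic_e.sum())
    se = float(np.sqrt(E * waic_e.var(ddof=1))) if E > 1 else 0.0
    return WAICResult(waic=waic, se=se, p_waic=float(p_e.sum()), n_events=E)


def compare_models(results: list[tuple[str, WAICResult]]) -> pd.DataFrame:
    """Rank models by WAIC; returns the comparison table sorted ascending.

    All models must have been scored on the same event set.
    """
    if len(results) < 2:
        raise ValueError("model comparison requires >= 2 models")
    n_events = {r.n_events for _, r in results}
    if len(n_events) > 1:
        raise ValueError(f"models scored on different event counts: {sorted(n_events)}")
    rows = sorted(results, key=lambda nr: nr[1].waic)
    best = rows[0][1].waic
    dwaic = np.array([r.waic - best for _, r in rows])
    w = np.exp(-0.5 * dwaic)
    w = w / w.sum()
    for (name, r), d, wt in zip(rows, dwaic, w):
        r.dwaic = float(d)
        r.weight = float(wt)
    return pd.DataFrame(
        {
            "model": [name for name, _ in rows],
            "waic": [r.waic for _, r in rows],
            "se": [r.se for _, r in rows],
            "dwaic": [r.dwaic for _, r in rows],
            "weight": [r.weight for _, r in rows],
        }
    ).set_index("model")


def hpdi(draws: np.ndarray, mass: float = 0.89) -> tuple[float, float]:
    """Narrowest contiguous interval of sorted draws containing ``mass``.

    Ties are broken toward the lowest lower bound.  ``mass`` must lie in
    (0, 1); use e.g. 0.9999 for an effectively full-range interval.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 draws for an HPDI")
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must lie strictly in (0, 1), got {mass}")
    m = int(np.ceil(mass * n))
    m = min(max(m, 1), n)
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns first minimum -> lowest lower bound
    return float(x[i]), float(x[i + m - 1])


# ---------------------------------------------------------------------------
# posterior prediction
# ---------------------------------------------------------------------------

RESOLUTIONS = ("population-daily", "individual-daily", "per-bout")


def posterior_predict(
    samples: PosteriorSamples,
    resolution: str = "population-daily",
    hpdi_mass: float = 0.89,
    max_draws: int | None = None,
) -> pd.DataFrame:
    """One-step-ahead posterior predictions of technique probabilities.

    For every posterior draw the forward model is run along each individual's
    observed sequence (attractions updated with the realised outcomes, cues as
    observed), giving per-bout probabilities of each technique; these are
    aggregated to the requested resolution with posterior mean and HPDI.  Raw
    observed daily technique frequencies are included for overlay.
    """
    if resolution not in RESOLUTIONS:
        raise ValueError(f"unknown resolution {resolution!r}; choose from {RESOLUTIONS}")
    model = samples.model
    design = model.design
    flat = samples.flat()
    if max_draws is not None and len(flat) > max_draws:
        idx = np.linspace(0, len(flat) - 1, max_draws).astype(int)
        flat = flat[idx]
    S = len(flat)
    E, K = design.n_events, design.K
    dates = design.session_date
    groups_of_event = np.array([design.group[a] for a in design.actor])

    if resolution == "per-bout":
        agg_keys = [(int(e),) for e in range(E)]
        key_of_event = np.arange(E)
    elif resolution == "population-daily":
        keys = {}
        key_of_event = np.empty(E, dtype=int)
        for e in range(E):
            k = (design.group_names[groups_of_event[e]], dates[e])
            key_of_event[e] = keys.setdefault(k, len(keys))
        agg_keys = list(keys)
    else:  # individual-daily
        keys = {}
        key_of_event = np.empty(E, dtype=int)
        for e in range(E):
            k = (design.individual_ids[design.actor[e]], dates[e])
            key_of_event[e] = keys.setdefault(k, len(keys))
        agg_keys = list(keys)

    n_keys = len(agg_keys)
    counts = np.bincount(key_of_event, minlength=n_keys).astype(float)
    acc = np.empty((S, n_keys, K))
    for s_idx, th in enumerate(flat):
        probs = model.choice_probs(th)
        for k in range(K):
            acc[s_idx, :, k] = np.bincount(key_of_event, weights=probs[:, k], minlength=n_keys) / counts

    # observed daily/bout technique frequencies for overlay
    raw = np.zeros((n_keys, K))
    for e in range(E):
        raw[key_of_event[e], design.choice[e]] += 1
    raw /= counts[:, None]

    rows = []
    for key_idx, key in enumerate(agg_keys):
        for k, tech in enumerate(design.techniques):
            d = acc[:, key_idx, k]
            lo, hi = hpdi(d, hpdi_mass) if S > 1 else (float(d[0]), float(d[0]))
            row = {
                "technique": tech,
                "mean": float(d.mean()),
                "hpdi_lo": lo,
                "hpdi_hi": hi,
                "raw_freq": float(raw[key_idx, k]),
                "n_bouts": int(counts[key_idx]),
            }
            if resolution == "per-bout":
                e = key[0]
                row.update(
                    event_index=e,
                    actor_id=design.individual_ids[design.actor[e]],
                    date=dates[e],
                    chosen=design.techniques[design.choice[e]],
                )
            elif resolution == "population-daily":
                row.update(group=key[0], date=key[1])
            else:
                row.update(actor_id=key[0], date=key[1])
            rows.append(row)
    return pd.DataFrame(rows)


__all__ = ["RESOLUTIONS", "WAICResult", "compare_models", "compute_waic", "hpdi", "posterior_predict"]
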