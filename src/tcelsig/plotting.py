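"""Plotting helpers: Kaplan-Meier steps and Ts% band charts."""

from __future__ import annotations

import pandas as pd

from tcelsig.scoring import BandConfig


def plot_km(km_tables: dict[str, pd.DataFrame], ax=None, max_time: float | None = None):
    """Step-plot Kaplan-Meier tables from :func:`tcelsig.prognosis.km_estimate`."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, km in km_tables.items():
        times = [0.0] + km["time"].tolist()
        surv = [1.0] + km["survival"].tolist()
        if max_time is not None:
            times.append(max_time)
            surv.append(surv[-1])
        ax.step(times, surv, where="post", label=label)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    return ax


def plot_ts_percent(
    ts: pd.Series, band_config: BandConfig | None = None, ax=None
):
    """Bar chart of per-sample Ts% with the similar-to-healthy-tissue band shaded."""
    import matplotlib.pyplot as plt

    cfg = band_config or BandConfig()
    if ax is None:
        _, ax = plt.subplots()
    ts = ts.sort_values(ascending=False)
    ax.bar(range(len(ts)), ts.to_numpy())
    ax.axhspan(
        cfg.similar_low_frac * cfg.reference_ts,
        cfg.similar_high_frac * cfg.reference_ts,
        alpha=0.2,
        color="green",
        label="similar to healthy tissue",
    )
    ax.set_xticks(range(len(ts)))
    ax.set_xticklabels(ts.index, rotation=90, fontsize=6)
    ax.set_ylabel("Ts%")
    ax.legend()
    return ax
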