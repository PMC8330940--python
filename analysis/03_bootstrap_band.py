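"""Bootstrap the 95% confidence band of the pregnancy-probability curve.

Resamples the cohort with replacement (always re-including the four
confirmed-pregnant whales), refits the mixture per replicate, filters out
label-flipped or non-monotone fits, and takes pointwise 2.5/97.5 percentiles.
Writes the band, the per-whale intervals, and a diagnostic figure.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from whalerepro.bootstrap import BootstrapConfig, attach_cis, bootstrap_band
from whalerepro.life_history import classify_records
from whalerepro.mixture import fit_mixture, pregnancy_probability
from whalerepro.pipeline import make_calls, render_table, table4_records

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--replicates", type=int, default=2000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    OUT.mkdir(exist_ok=True)
    classified = classify_records(table4_records())
    ids = list(classified["whale_id"])
    x = classified["progesterone_ng_g"].to_numpy(float)
    forced = tuple(classified.loc[classified["repro_state"] == "pregnant", "whale_id"])

    fit = fit_mixture(np.log(x))
    cfg = BootstrapConfig(
        n_replicates=args.replicates, seed=args.seed, forced_ids=forced
    )
    band = bootstrap_band(ids, x, cfg)
    pd.DataFrame(
        {"grid_ng_g": band.grid, "lower_2_5": band.lower, "upper_97_5": band.upper}
    ).to_csv(OUT / "probability_band.csv", index=False)

    calls = attach_cis(make_calls(ids, x, fit), band)
    render_table(calls).to_csv(OUT / "pregnancy_calls_with_ci.csv", index=False)

    grid = band.grid
    plt.figure(figsize=(6, 4))
    plt.fill_between(grid, band.lower, band.upper, alpha=0.3, label="95% band")
    plt.plot(grid, pregnancy_probability(grid, fit), "k-", label="point estimate")
    plt.scatter(x, pregnancy_probability(x, fit), s=12, c="tab:red", zorder=3)
    plt.xscale("log")
    plt.xlabel("blubber progesterone (ng/g)")
    plt.ylabel("probability of pregnancy")
    plt.legend()
    plt.tight_layout()
    plt.savefig(OUT / "probability_band.png", dpi=150)

    width = band.upper - band.lower
    mid = (grid >= 5) & (grid <= 10)
    print(
        f"retained {100 * band.retained_fraction:.1f}% of {args.replicates} "
        f"replicates (rejections: {band.rejection_causes})"
    )
    print(
        f"mean band width {width[mid].mean():.2f} at 5-10 ng/g vs "
        f"{width[~mid].mean():.2f} elsewhere — classification is confident at "
        "the extremes and uncertain between the clusters."
    )


if __name__ == "__main__":
    main()
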