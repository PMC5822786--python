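"""Score-level statistics on the simulated cohort.

Pearson correlations between mood subscales and the symptom total (pairwise
deletion for the one subject missing the symptom scale), the rank-sum
comparison of symptom totals between players with and without a concussion
history, the one-year mood stability comparison on complete pairs, and a
scatter of the detected cluster's adjusted mean radii against the coupled
scale.

Writes tables to results/behaviour/ and the scatter to results/behaviour/.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from amyshape.cohort import frame_to_subject_table
from amyshape.pipeline import behavioural_statistics

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()

    records = frame_to_subject_table(
        pd.read_csv(ROOT / "results" / "cohort" / "subjects.csv")
    )
    out = ROOT / "results" / "behaviour"
    out.mkdir(parents=True, exist_ok=True)

    stats = behavioural_statistics(records)
    stats["pearson_r"].round(3).to_csv(out / "correlations_r.csv")
    stats["pearson_p"].round(4).to_csv(out / "correlations_p.csv")
    stats["pearson_n"].to_csv(out / "correlations_n.csv")

    r = stats["pearson_r"]
    print("correlations of mood subscales with the symptom total (PCSS):")
    print(r["pcss_total"].drop("pcss_total").round(3).to_string())

    if "pcss_by_concussion" in stats:
        mw = stats["pcss_by_concussion"]
        print(f"\nPCSS, concussion>=1 (n={mw['n_concussed']}) vs none "
              f"(n={mw['n_nonconcussed']}): U={mw['U']:.1f}, p={mw['p']:.3f}")
        pd.DataFrame([mw]).to_csv(out / "pcss_by_concussion.csv", index=False)

    if "followup_stability" in stats:
        stab = pd.DataFrame(stats["followup_stability"]).T
        stab.round(4).to_csv(out / "followup_stability.csv")
        print("\nbaseline vs one-year follow-up (paired, random-intercept "
              "equivalent):")
        print(stab.round(3).to_string())

    # adjusted-mean-radius scatter for the largest detected cluster
    clusters = pd.read_csv(ROOT / "results" / "analysis" / "clusters.csv")
    if not clusters.empty:
        import numpy as np

        from amyshape import io as aio
        from amyshape.stats import ClusterResult, cluster_adjusted_regression

        top = clusters.sort_values("size", ascending=False).iloc[0]
        shapes = aio.read_radial_shapes(
            ROOT / "results" / "analysis" / f"radii_{top['side']}.csv"
        )
        radii = np.stack([s.radii for s in shapes])
        score = np.array([getattr(r, top["scale"]) for r in records], float)
        age = np.array([r.age for r in records], float)
        etiv = np.array([r.etiv for r in records], float)
        keep = np.isfinite(score)
        cl = cluster_adjusted_regression(
            ClusterResult(indices=np.array(top["indices"].split(), dtype=int),
                          size=int(top["size"])),
            radii[keep], score[keep], age[keep], etiv[keep],
        )
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        ax.scatter(score[keep], cl.adjusted_mean_radii, s=18)
        xs = np.linspace(score[keep].min(), score[keep].max(), 10)
        yhat = cl.adjusted_mean_radii.mean() + cl.beta * (xs - score[keep].mean())
        ax.plot(xs, yhat, lw=1)
        ax.set_xlabel(top["scale"])
        ax.set_ylabel("adjusted mean radius (mm)")
        ax.set_title(
            f"{top['side']} cluster ({top['size']} pts): "
            f"beta={cl.beta:.3f}, t={cl.t:.2f}"
        )
        fig.tight_layout()
        fig.savefig(out / "cluster_adjusted_radii.png", dpi=120)
        print(f"\nscatter written for the {top['side']} {top['scale']} cluster "
              f"(beta={cl.beta:.3f} mm/point)")


if __name__ == "__main__":
    main()
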