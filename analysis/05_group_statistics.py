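"""Group-level statistics over the improvement maps.

Runs the statistical battery on the stored improvement maps: smoothed
mass-univariate one-sample TFCE test, hemispheric paired test and
lateralization index, ROI-averaged one-sample t-tests per group, the
language regression (English baseline), and pairwise language t-tests.
Writes tidy tables under results/.
"""

from pathlib import Path

from speechtrf import io as stio
from speechtrf.pipeline import hemisphere_summary, li_table
from speechtrf.stats import hemispheric_paired_test, mass_univariate_onesample

RESULTS = Path(__file__).resolve().parent.parent / "results"
FEATURE = "lexical_surprisal"


def main() -> None:
    ds = stio.load_group_dataset(RESULTS / f"improvement_{FEATURE}.h5")

    res = mass_univariate_onesample(ds, sigma=1.0, n_perm=2000, seed=0)
    print(
        f"one-sample TFCE over {ds.space.n_sources} sources: "
        f"tmax = {res.tmax:.2f}, p = {res.p_tmax:.4f} "
        f"({res.n_significant} sources with p <= .05)"
    )

    paired = hemispheric_paired_test(ds, sigma=1.0, n_perm=2000, seed=0)
    print(
        f"hemispheric paired TFCE: tmax = {paired.tmax:.2f}, "
        f"p = {paired.p_tmax:.4f}"
    )

    li = li_table(ds)
    li.to_csv(RESULTS / f"{FEATURE}_lateralization.tsv", sep="\t", index=False)
    print(f"lateralization index: mean {li['li'].mean():.3f} (0.5 = symmetric)")

    tables = hemisphere_summary(ds)
    for name, table in tables.items():
        table.to_csv(RESULTS / f"{FEATURE}_{name}.tsv", sep="\t", index=False)
    print("\nROI one-sample t-tests (left hemisphere):")
    print(tables["roi_L"].round(4).to_string(index=False))
    print("\nlanguage regression (left hemisphere, English baseline):")
    print(tables["regression_L"].round(4).to_string(index=False))


if __name__ == "__main__":
    main()
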