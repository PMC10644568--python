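"""Pairwise group differentiation, alone and with combined features.

Runs the two-sample t-tests for every feature and group pair, evaluates the
pairwise independence of the features (R-square of within-group linear
fits), and combines every non-empty feature subset with Fisher's method —
45 combined comparisons in total.

Finding: no single feature separates all three groups; combining all four
separates AN-FA, AN-CA and FA-CA at p = 1.7e-9, 5.6e-13 and 4.5e-3.  The
mechanical pair (k, %R) is the least independent (R-square up to 0.64);
the fibroadenoma group shows the strongest inter-feature correlations.

Writes results/comparison_matrix.csv and results/independence_map.csv.
"""

from pathlib import Path

from etmpheno import comparison_matrix, independence_map, load_cohort_fixture

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cohort = load_cohort_fixture()

    cm = comparison_matrix(cohort)  # published convention: Welch; pooled for %R
    frame = cm.to_frame()
    frame.to_csv(OUT / "comparison_matrix.csv", index=False)
    print(f"comparison matrix: {len(cm)} entries "
          f"({len(frame['modalities'].unique())} subsets x 3 group pairs)")
    allfour = ("Z", "K", "k", "%R")
    for pair in (("AN", "FA"), ("AN", "CA"), ("FA", "CA")):
        p = cm.p(allfour, pair)
        print(f"  all four features, {pair[0]} vs {pair[1]}: "
              f"p = {p:.3g} ({cm.category(allfour, pair)})")

    im = independence_map(cohort)
    imf = im.to_frame()
    imf.to_csv(OUT / "independence_map.csv", index=False)
    print("\nleast independent pair (k, %R): "
          + ", ".join(f"{g}: {im.r2(('k', '%R'), g):.3g}" for g in ("AN", "FA", "CA")))
    print("group with least independent features:",
          imf.groupby("group")["r2"].mean().idxmax())


if __name__ == "__main__":
    main()
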