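"""Replicated validation studies: bias, unbiasedness, and interval coverage.

Three experiments with known ground truth:

1. bias ordering — on a fixed landscape, redraw the inclusion mechanism 200
   times and measure every estimator's bias; the six adjustments should all
   beat the naive mean when the auxiliaries drive both occupancy and
   inclusion (MRP gets 20 replicates; it is far slower than the rest);
2. unbiasedness — the design-based estimator with true inclusion
   probabilities, poststratification under stratum-driven inclusion, and
   the doubly robust estimator with exactly one correct component should
   all be unbiased (the both-wrong doubly robust variant is the negative
   control);
3. coverage caution — when occupancy feeds inclusion directly (a violation
   of the missing-at-random assumption), nominal 95% intervals from the
   adjusted estimators stop covering the truth.

Writes bias_study.csv, unbiasedness.csv and coverage.csv under results/.
"""

from pathlib import Path

from occuadjust import SyntheticConfig, simulate_frame
from occuadjust.studies import bias_study, coverage_study, unbiasedness_checks

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20_240_104


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    frame = simulate_frame(SyntheticConfig(N=4000, seed=SEED))
    bias = bias_study(
        frame, 1,
        methods=("naive", "quasirandomization", "poststratification",
                 "superpopulation", "doubly_robust", "subsampling", "mrp"),
        n_replicates=200, seed=SEED + 1, mrp_replicates=20,
    )
    bias.to_csv(RESULTS / "bias_study.csv", index=False)
    print("bias against known truth over replicate inclusion draws:")
    print(bias.to_string(index=False, float_format="%.5f"))
    naive = bias.set_index("method").loc["naive", "abs_bias"]
    beat = (bias.query("method != 'naive'")["abs_bias"] < naive).sum()
    print(f"-> {beat}/6 adjusted estimators have lower |bias| than naive ({naive:.4f})\n")

    unb = unbiasedness_checks(N=5000, n_replicates=500, seed=SEED + 2)
    unb.to_csv(RESULTS / "unbiasedness.csv", index=False)
    print("unbiasedness checks (|bias| vs 3 x Monte-Carlo SE):")
    for _, r in unb.iterrows():
        verdict = "unbiased" if r["abs_bias"] < 3 * r["mc_se"] else "BIASED"
        print(f"  {r['study']:<30s} |bias| = {r['abs_bias']:.5f} "
              f"(3 SE = {3 * r['mc_se']:.5f}) -> {verdict}")
    print()

    cov = coverage_study(
        SyntheticConfig(N=2000, gamma_y=-1.5),
        methods=("poststratification", "superpopulation"),
        n_worlds=200, B=200, seed=SEED + 3,
    )
    cov.to_csv(RESULTS / "coverage.csv", index=False)
    print("95% interval coverage when occupancy drives inclusion directly "
          "(missing-at-random violated):")
    print(cov.to_string(index=False, float_format="%.3f"))
    print("-> nominal intervals are not to be trusted once the adjustment "
          "variables miss a real driver of inclusion")


if __name__ == "__main__":
    main()
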