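"""Compare BSA and introgression mapping (IM) localization accuracy.

The exploratory design study scores a mapping design by the median genetic
distance between each true QTL and the maximum of its summary statistic
(a_d for BSA, a_p for IM) within the QTL's analysis zone, plus the
fraction of replicates landing within 0.5 cM.  Five equal-effect QTL (one
per arm) and the reference design (600 bred per generation, 10
generations, 20% tails, depth 300) are used here with a small replicate
count for speed.
"""

from sibsam import Scenario, make_synthetic_map, run_scenario

gmap = make_synthetic_map(100, seed=9)
common = dict(N=600, G=10, q=0.2, depth=300, n_qtl_per_arm=1, n_replicates=25)

for mode in ("bsa", "im"):
    df = run_scenario(Scenario(mode=mode, **common), gmap, seed=4)
    pooled = df[df.qtl == "pooled"].iloc[0]
    print(
        f"{mode.upper():3s}: median distance {pooled.median_distance_cm:5.2f} cM, "
        f"0.5 cM hit rate {100 * pooled.hit_rate:4.1f}%"
    )
print()
print("BSA localizes QTL more precisely than IM at the same design, mainly")
print("because IM's repeated selection bottlenecks discard recombinants.")
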