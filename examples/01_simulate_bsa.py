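"""Simulate one bulk-segregant-analysis experiment and look at its signal.

Builds a small synthetic Drosophila-like map (X, 2, 3), places a single QTL
of strength s = 0.3 near the middle of chromosome 3, breeds the mapping
population, and prints where the ancestry-difference (a_d) profile peaks.
a_d is the difference between the high- and low-phenotype pools in the
fraction of ancestry inherited from the high parental strain: near zero at
neutral loci, elevated around a true QTL.
"""

import numpy as np

from sibsam import (
    ExperimentConfig,
    QTL,
    QTLModel,
    make_synthetic_map,
    run_bsa_experiment,
    strength_to_effect,
)

gmap = make_synthetic_map(n_windows_per_chrom=100, seed=7)
config = ExperimentConfig(mode="bsa", N=600, G=10, q=0.10, depth=500)

s = 0.3
qtl_cm = 55.0
model = QTLModel([QTL("3", qtl_cm, strength_to_effect(s))])

result = run_bsa_experiment(config, model, gmap, np.random.default_rng(1))

peak = int(np.argmax(result.ad))
c3 = gmap.chrom("3")
true_flat = gmap.flat_index("3", c3.window_at(qtl_cm))
peak_chrom = gmap.labels[int(np.searchsorted(gmap.offsets, peak, "right")) - 1]
peak_cm = float(np.concatenate([c.cm_mid for c in gmap.chromosomes])[peak])

print(f"simulated QTL: chromosome 3 at {qtl_cm} cM, strength s = {s}")
x_mean = result.ad[gmap.slices()[gmap.chrom_index("X")]].mean()
print(f"max a_d = {result.ad[peak]:.3f} at chromosome {peak_chrom}, {peak_cm:.1f} cM")
print(f"a_d at the true QTL window = {result.ad[true_flat]:.3f}")
print(f"mean a_d on the unlinked X chromosome = {x_mean:+.4f} (expectation ~ 0)")
print()
print("The tall a_d value sits at/near the simulated QTL; unlinked")
print("chromosomes stay near zero because they segregate independently")
print("of the phenotype.")
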