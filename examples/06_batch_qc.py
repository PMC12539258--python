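"""Batch-stability coefficients of variation on a simulated control-pellet
series, plus the per-sample QC rules."""

import tissuequant as tq

counts, means = tq.generate_batch_series(
    n_batches=11,
    base_means={("T", "CD3"): 50.0, ("T", "CD8"): 30.0,
                ("B", "CD20"): 40.0, ("Tumor", "CK"): 80.0},
    sigma=0.15,
    seed=2,
)

frac_cv = tq.celltype_fraction_cv(counts)
print("cell-type fraction CV across 11 batches:")
print((100 * frac_cv).round(1).astype(str) + " %")

report = tq.marker_cv(
    means, relevance={"T": ["CD3", "CD8"], "B": ["CD20"], "Tumor": ["CK"]}
)
print("final per-marker expression CV:")
print((100 * report.per_marker).round(1).astype(str) + " %")
# the marker CVs hover around the generative batch noise (15%); fraction
# CVs are smaller because multinomial sampling is the only noise source

for frac, markers in [(0.3, {}), (0.6, {}), (0.1, {"CD3": False, "CK": False})]:
    rep = tq.sample_qc(frac, markers or None)
    print(f"missing={frac:.0%}, failed markers={sorted(k for k,v in markers.items() if not v)}"
          f" -> {rep.status}")
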