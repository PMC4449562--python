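"""Sweep the two model parameters: max gap I and the t-test cutoff p.

Each combination triggers one full nested cross-validation.  Signal in
this synthetic dataset lives at gaps up to 3, so the I=3 rows should not
trail the I=1 rows.  (A reduced dataset and single-candidate SVM grid
keep the demo quick; drop `svm=` for the full 64-candidate search.)
"""

import apcpred as ap

dataset = ap.generate(ap.PlantSpec(n_pos=100, n_neg=100, seed=7))
table = ap.parameter_sweep(
    dataset,
    I_values=[1, 3],
    p_values=[0.5, 1.0],
    svm=ap.SVMConfig(c_grid=(1.0,), gamma_grid=(2.0,), inner_folds=2),
    seed=11,
)
print(table[["window", "max_gap", "p_cutoff", "auc", "acc", "mcc",
             "n_features_selected_mean"]].to_string(index=False))
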