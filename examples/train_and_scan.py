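"""Train a deployable model, then scan whole antigens for epitope windows.

A final model (selection and tuning on all training rows) slides its
20-residue window along each antigen; embedded epitope-like windows
should outscore the background.  Scan coordinates are 0-based half-open.
"""

import numpy as np

import apcpred as ap
from apcpred.evaluation import predict_peptides

spec = ap.PlantSpec(seed=7)
model = ap.train_final_model(
    ap.generate(spec),
    svm=ap.SVMConfig(c_grid=(1.0,), gamma_grid=(2.0,), inner_folds=2),
    seed=11,
)
print(f"model: C={model.chosen_c:g} gamma={model.chosen_gamma:g} "
      f"{model.n_selected_features}/1600 features")

antigens, offsets = ap.generate_antigens(5, length=120, embedded_epitopes=spec, seed=21)
embedded = {(r.antigen_id, r.start) for r in offsets.itertuples()}
for ant in antigens:
    windows = ap.PeptideDataset(
        [ap.Peptide(id=f"{ant.id}:{s}", sequence=ant.sequence[s : s + 20])
         for s in range(len(ant) - 19)]
    )
    scores = predict_peptides(model, windows)["score"].to_numpy()
    best = int(np.argmax(scores))
    true_start = next(s for a, s in embedded if a == ant.id)
    print(f"{ant.id}: top-scoring window starts at {best} "
          f"(embedded epitope at {true_start}), score={scores[best]:+.2f}, "
          f"median background score={np.median(scores):+.2f}")
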