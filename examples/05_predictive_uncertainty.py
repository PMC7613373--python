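"""Why non-vegetated spectra belong in the training set.

Fits one Gaussian process with and one without the 24-spectrum non-vegetated
library (label 0 g/m^2) and predicts both models on a bare-soil spectrum.
The augmented model answers "no nitrogen here" with confidence, while the
vegetation-only model extrapolates with inflated values and uncertainty.
"""

import numpy as np

from cncmap import gpr
from cncmap.activelearning import LabeledPool, augment_nonvegetated
from cncmap.bands import harmonized_grid, load_sensor_grid
from cncmap.pca import fit_pca, project
from cncmap.rtm import build_training_database
from cncmap.synthetic import make_nonvegetated_library

grid = harmonized_grid(load_sensor_grid())
db = build_training_database(300, grid, seed=1)
pca = fit_pca(db.reflectance, 20)
pool = LabeledPool(project(pca, db.reflectance), db.cnc)

nv = make_nonvegetated_library(24, seed=2)
augmented = augment_nonvegetated(pool, nv, pca)

veg_only = gpr.fit(pool.scores, pool.labels, kernel_mode="isotropic", n_restarts=3, seed=3)
with_nv = gpr.fit(augmented.scores, augmented.labels, kernel_mode="isotropic", n_restarts=3, seed=3)

soil = project(pca, nv[0])[None, :]  # a bare-soil endmember, unseen by veg_only
for name, model in (("vegetation-only", veg_only), ("NV-augmented  ", with_nv)):
    p = gpr.predict(model, soil)
    sd = np.sqrt(p.variance[0])
    cv = 100 * sd / max(p.mean[0], 1e-6)
    print(f"{name} model on bare soil: CNC {p.mean[0]:6.2f} +- {sd:.2f} g/m2  (CV {cv:.0f} %)")
print("-> the zero-labeled non-vegetated spectra anchor the model over "
      "surfaces without canopy, which is what makes full-scene maps sensible.")
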