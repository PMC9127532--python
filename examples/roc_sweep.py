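"""Sweep the gray-similarity threshold th_f and trace a ROC curve.

th_f is the operating parameter of the entanglement test: tiny values
fragment the image (nothing clusters with anything), large values merge
object and background. Each grid value re-runs the full segmentation;
the (false-positive rate, true-positive rate) points are integrated by
the trapezoidal rule. AUC near 1 means the segmenter separates the
classes across the whole operating range.
"""

from qwpso import QwpsoConfig, qwpso_segment, roc_auc
from qwpso.config import RunConfig, config_from_dict
from qwpso.phantoms import PhantomSpec, make_phantom

image, truth = make_phantom(PhantomSpec(shape="dualtail", size=64, noise_sd=10, seed=3))


def family(th_f: float):
    data = RunConfig().to_dict()
    data["cluster"]["th_f"] = float(th_f)
    data["seed"] = 1
    cfg = config_from_dict(data)
    return qwpso_segment(image, cfg.engine_config()).foreground


grid = [2.0, 10.0, 18.0, 26.0, 34.0]
curve, auc = roc_auc(family, truth, grid)
for fpr, tpr in curve:
    print(f"FPR={fpr:.4f}  TPR={tpr:.4f}")
print(f"AUC = {auc:.4f}")
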