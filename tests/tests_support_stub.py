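"""Shared test helper: a classifier whose outputs are preset probabilities."""

import numpy as np

from contourpro import build_classifier


class FixedLogitNet:
    def __init__(self, logits):
        self.logits = logits

    def forward(self, x, train=True):
        return np.array(self.logits[: len(x)], dtype=np.float32)


def model_with_probs(prob_rows):
    model = build_classifier("small_cnn", 128, 2, class_labels=["CON", "ESRD"], seed=0)
    model.net = FixedLogitNet([np.log(np.asarray(r) + 1e-12) for r in prob_rows])
    return model
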