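"""Shared test doubles."""

import numpy as np


class StubCAMModel:
    """Fixed activation maps and scripted class probabilities.

    The scorer returns, for each projected input in a batch, the logits
    whose softmax artifact-probability follows the scripted sequence.
    """

    def __init__(self, maps: np.ndarray, artifact_probs: list[float],
                 input_size: int):
        self.maps = maps
        self.probs = list(artifact_probs)
        self._cursor = 0

        class _Cfg:
            pass
        self.config = _Cfg()
        self.config.input_size = input_size

    def forward_features(self, x):
        return np.zeros((x.shape[0], 2)), np.broadcast_to(
            self.maps[None], (x.shape[0], *self.maps.shape))

    def forward(self, x):
        n = x.shape[0]
        out = np.zeros((n, 2))
        for i in range(n):
            p = self.probs[self._cursor % len(self.probs)]
            self._cursor += 1
            p = min(max(p, 1e-9), 1 - 1e-9)
            out[i, 1] = np.log(p / (1 - p))     # softmax -> exactly p
        return out
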