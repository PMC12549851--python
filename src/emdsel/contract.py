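"""Model contract: the two capabilities a candidate model must expose.

Any probabilistic model can be scored by this package as long as it can
(1) evaluate a pointwise loss on (x, y) records and (2) generate synthetic
(x, y) samples from its own distribution.  Data-generating processes used
in calibration experiments only need the sampling capability.
"""

from __future__ import annotations

from typing import Protocol, Tuple, runtime_checkable

import numpy as np


@runtime_checkable
class CandidateModel(Protocol):
    """Contract for a fitted candidate model.

    ``loss`` evaluates a pointwise loss Q(x_i, y_i) for each record and
    returns one finite real per record (e.g. the negative log likelihood,
    in nats).  ``sample`` draws n synthetic (x, y) records from the model's
    own distribution.
    """

    model_id: str

    def loss(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        ...

    def sample(
        self, n: int, rng: np.random.Generator
    ) -> Tuple[np.ndarray, np.ndarray]:
        ...


@runtime_checkable
class DataGeneratingProcess(Protocol):
    """A process that can generate datasets of requested size."""

    def sample(
        self, n: int, rng: np.random.Generator
    ) -> Tuple[np.ndarray, np.ndarray]:
        ...
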