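"""Shared result container for per-subject risk scores."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ERSVector:
    """Per-subject environmental risk score with provenance.

    ``method`` is one of AENET-M, AENET-I, BART, BKMR, SL; ``fit_id``
    identifies the training fit that produced the weights.
    """

    values: np.ndarray
    method: str
    fit_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ERS values must be finite")

    def __len__(self) -> int:
        return len(self.values)
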