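"""Replicated benchmark runs: generate, detect, score.

Shared by the experiment CLI, the acceptance script and the acceptance
tests, so that every reported number comes from the same code path:
generate a signed LFR network, run the detector, score the crisp
partition against the planted one.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .benchmark import LfrParams, generate_signed_lfr
from .expansion import SrwaConfig, srwa
from .metrics import nmi

__all__ = ["replicate_nmi"]


def replicate_nmi(
    params: LfrParams,
    runs: int,
    rng: np.random.Generator,
    config: SrwaConfig | None = None,
) -> np.ndarray:
    """NMI against the planted partition over ``runs`` seeded networks.

    Per-run generator seeds are drawn from ``rng`` (consume it
    sequentially to keep a whole experiment reproducible from one master
    seed).
    """
    scores = []
    for _ in range(runs):
        child = int(rng.integers(2**31 - 1))
        net, truth = generate_signed_lfr(replace(params, seed=child))
        _, partition = srwa(net, config)
        scores.append(nmi(truth.to_partition(), partition))
    return np.asarray(scores)
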