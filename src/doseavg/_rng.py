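"""Labeled, reproducible random-number substreams.

Every stochastic stage of a study (baseline doses, realization errors,
outcome draws, FMA stage-2 sampling, MCMC) pulls an independent
:class:`numpy.random.Generator` keyed by a master seed plus string labels, so
any stage can be re-run in isolation and results do not depend on the order
in which stages consume randomness.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _label_key(label: str | int) -> int:
    if isinstance(label, (int, np.integer)):
        return int(label) & 0xFFFFFFFF
    return zlib.crc32(str(label).encode("utf-8"))


def substream(master_seed: int, *labels: str | int) -> np.random.Generator:
    """Return a Generator for the substream identified by ``labels``.

    Distinct label tuples yield statistically independent streams; the same
    tuple always yields the same stream for a given master seed.
    """
    seq = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=tuple(_label_key(l) for l in labels)
    )
    return np.random.default_rng(seq)
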