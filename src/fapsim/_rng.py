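"""Keyed random streams for common-random-number (CRN) comparisons.

Every Bernoulli draw in the engine is taken from a stream keyed by
(root seed, purpose, cycle); individual *i* always reads position *i* of the
stream.  Two strategies run with the same root seed therefore see identical
uniforms for the same individual, cycle, and purpose, making strategy
comparisons paired.
"""

from __future__ import annotations

import numpy as np

# Stable purpose labels -> small integers; order is part of the
# reproducibility contract, so append only.
PURPOSES = (
    "symptomatic_detect",
    "progress",
    "polyp_onset",
    "scope_polyp",
    "scope_preclin",
    "perforation_no_polypectomy",
    "idp_perforation",
    "idp_bleeding",
    "recurrence",
    "recurrence_class",
    "aspirin_adherence",
    "aspirin_gi_minor",
    "aspirin_serious_bleed",
    "crc_death",
    "other_death",
    "ipaa_destiny",
    "ipaa_timing",
    "cohort_sex",
    "psa_param_draw",
    "entry_state",
)
_PURPOSE_ID = {name: i for i, name in enumerate(PURPOSES)}


def stream(
    seed: int | tuple[int, ...], purpose: str, cycle: int = 0
) -> np.random.Generator:
    """Deterministic generator for one (seed, purpose, cycle) triple.

    ``seed`` may be a tuple to key additional context into the stream (e.g.
    a strategy tag when common random numbers are disabled).
    """
    entropy = [int(seed)] if np.isscalar(seed) else [int(s) for s in seed]
    return np.random.default_rng(
        np.random.SeedSequence(entropy + [_PURPOSE_ID[purpose], int(cycle)])
    )


def uniforms(
    seed: int | tuple[int, ...], purpose: str, cycle: int, n: int
) -> np.ndarray:
    """n uniforms on [0, 1); position i belongs to individual i."""
    return stream(seed, purpose, cycle).random(n)
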