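"""Small shared helpers: sequence manipulation and deterministic RNG derivation."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                      "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

_IUPAC = frozenset("ACGTRYSWKMBDHVN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMP)[::-1]


def rotations(motif: str) -> set[str]:
    """All cyclic rotations of a short motif."""
    return {motif[i:] + motif[:i] for i in range(len(motif))}


def derive_seed(seed: int, *salt: int) -> int:
    """Derive an independent child seed < 2**31 from a master seed.

    Uses numpy's SeedSequence spawning so sub-streams are statistically
    independent and platform-stable.
    """
    ss = np.random.SeedSequence([int(seed)] + [int(s) for s in salt])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def rng_for(seed: int, *salt: int) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, *salt))
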