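"""Sample barcode design.

Multiplexed runs tag the constant-region read with a short 5' barcode.
To tolerate synthesis/PCR/sequencing errors the codes are designed with a
minimum pairwise Hamming distance (default 3 for 6-nt codes, matching a
per-position synthesis error of ~5% and hence a code-to-code conversion
rate of about 0.05^3 = 1/8000 — the cross-contamination rate used by the
Poisson filter).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .dna import BASES, hamming


@dataclass
class BarcodeSet:
    barcodes: list[str]
    length: int = 6
    min_distance: int = 3

    def __post_init__(self) -> None:
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be distinct")
        if any(len(b) != self.length for b in self.barcodes):
            raise ValueError("all barcodes must have the declared length")
        for i, a in enumerate(self.barcodes):
            for b in self.barcodes[i + 1 :]:
                if hamming(a, b) < self.min_distance:
                    raise ValueError(
                        f"barcodes {a}/{b} closer than min_distance={self.min_distance}"
                    )

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self):
        return iter(self.barcodes)


def design_barcodes(
    k: int, length: int = 6, min_distance: int = 3, seed: int = 0
) -> BarcodeSet:
    """Greedily pick ``k`` codes with pairwise Hamming distance >= min_distance.

    Candidates are the full 4^length code space in a seed-shuffled order;
    a candidate is kept iff it clears the distance bound against every code
    already kept. Raises ``ValueError`` if the space is exhausted before
    ``k`` codes are found. For length 6 / distance 3 at least 64 codes are
    always reachable, comfortably above any per-run sample count.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if length < 1 or not 1 <= min_distance <= length:
        raise ValueError("invalid length/min_distance")
    rng = np.random.default_rng(seed)
    candidates = ["".join(p) for p in product(BASES, repeat=length)]
    rng.shuffle(candidates)
    chosen: list[str] = []
    for cand in candidates:
        if all(hamming(cand, c) >= min_distance for c in chosen):
            chosen.append(cand)
            if len(chosen) == k:
                return BarcodeSet(chosen, length=length, min_distance=min_distance)
    raise ValueError(
        f"cannot design {k} codes of length {length} at distance {min_distance}"
    )
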