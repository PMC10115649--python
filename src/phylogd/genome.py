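"""Abstract genome layout used by the simulator.

Copy-number events operate at chromosome-arm scale: the genome is a set of
equally weighted arm-sized segments (44 autosomal arms by default, 2 per
chromosome 1..22).  SNV loci are points assigned to an arm; they inherit
the arm's allele-specific copy number.  Synthetic 1-based coordinates are
attached so results can be written in SEG-like form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ARM_LENGTH = 50_000_000  # synthetic arm size, bp


@dataclass
class GenomeLayout:
    """Arm-partitioned genome with SNV loci placed on arms."""

    n_arms: int = 44
    arm_of: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    pos: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def n_loci(self) -> int:
        return len(self.arm_of)

    def arm_chrom(self, arm: int) -> str:
        return str(arm // 2 + 1)

    def arm_span(self, arm: int) -> tuple[int, int]:
        """1-based inclusive (start, end) of an arm on its chromosome."""
        offset = (arm % 2) * ARM_LENGTH
        return offset + 1, offset + ARM_LENGTH

    def locus_chrom_pos(self, locus: int) -> tuple[str, int]:
        arm = int(self.arm_of[locus])
        start, _ = self.arm_span(arm)
        return self.arm_chrom(arm), start + int(self.pos[locus])

    @classmethod
    def place_loci(cls, n_loci: int, rng: np.random.Generator, n_arms: int = 44) -> "GenomeLayout":
        """Place loci uniformly over equally weighted arms."""
        arm_of = rng.integers(0, n_arms, size=n_loci)
        pos = rng.integers(0, ARM_LENGTH - 1, size=n_loci)
        return cls(n_arms=n_arms, arm_of=np.asarray(arm_of), pos=np.asarray(pos))
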