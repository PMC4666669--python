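"""Shared call-level data model: genotypes, breakpoints and SV call records."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

#: fixed class order used everywhere probabilities are reported.
SV_CLASSES = ("DEL", "DUP", "INS", "INV")
UNKNOWN_CLASS = "UNK"


@dataclass(slots=True)
class GenotypeCall:
    """A bi-allelic diploid genotype with log10-scaled likelihoods.

    ``gl`` is (L0, L1, L2) for 0, 1 and 2 copies of the alternative allele,
    normalized so the maximum is 0.  ``gt`` is one of ``0/0``, ``0/1``,
    ``1/1`` or ``./.`` (no informative evidence).
    """

    gt: str
    gl: Tuple[float, float, float]
    depth: int
    alt_count: int
    gq: int

    @property
    def n_alt_alleles(self) -> Optional[int]:
        return {"0/0": 0, "0/1": 1, "1/1": 2}.get(self.gt)


@dataclass(slots=True)
class Breakpoint:
    chrom: str
    pos: int                       # 0-based
    support: int = 0


@dataclass(slots=True)
class SVCall:
    """One breakpoint record: a clip-supported position plus its resolved mate.

    Every putative SV yields up to two records, one per breakpoint, each
    pointing at its partner through ``mate`` (emitted as the BE INFO field).
    """

    chrom: str
    pos: int                       # 0-based primary breakpoint
    side: str                      # clip side at the primary breakpoint
    support: int                   # SP: primary clipped reads at pos
    mate: Optional[Breakpoint] = None
    consensus: str = ""
    at: Optional[List[float]] = None          # 14 depth-normalized attributes
    genotypes: Dict[str, GenotypeCall] = field(default_factory=dict)
    wc: str = UNKNOWN_CLASS
    wp: Optional[List[float]] = None
    lrt: Optional[float] = None
    call_id: str = "."

    @property
    def end(self) -> int:
        """0-based END: mate position for intra-chromosomal calls."""
        if self.mate is not None and self.mate.chrom == self.chrom:
            return max(self.pos, self.mate.pos)
        return self.pos

    @property
    def svlen(self) -> int:
        if self.mate is not None and self.mate.chrom == self.chrom:
            return abs(self.mate.pos - self.pos)
        return 0

    @property
    def breakpoints(self) -> List[Tuple[str, int]]:
        bps = [(self.chrom, self.pos)]
        if self.mate is not None:
            bps.append((self.mate.chrom, self.mate.pos))
        return bps
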