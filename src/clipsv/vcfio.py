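"""VCF 4.2 output (and read-back) for SV call records.

INFO keys
---------
END     0-based internal coordinates become 1-based here, once.
SVLEN   breakpoint span for intra-chromosomal calls.
SP      number of primary clipped reads supporting the primary breakpoint.
AT      the 14 depth-normalized pileup attributes, comma-joined.
WC      classified SV type (DEL/DUP/INS/INV/UNK).
WP      per-class classification probabilities, ordered DEL,DUP,INS,INV.
LRT     binomial likelihood-ratio statistic (association mode only).
BE      partner breakpoint as chrom,pos(1-based),support.

FORMAT is GT:GL:DP:SP per sample.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import pysam

from .variants import Breakpoint, GenotypeCall, SVCall, SV_CLASSES, UNKNOWN_CLASS

_INFO_HEADER = [
    '##INFO=<ID=END,Number=1,Type=Integer,Description="1-based end of the variant (mate breakpoint for intra-chromosomal calls)">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Distance between the paired breakpoints">',
    '##INFO=<ID=SP,Number=1,Type=Integer,Description="Primary clipped reads supporting the breakpoint">',
    '##INFO=<ID=AT,Number=14,Type=Float,Description="Depth-normalized pileup attributes used for SV-type classification">',
    '##INFO=<ID=WC,Number=1,Type=String,Description="Classified SV type">',
    '##INFO=<ID=WP,Number=.,Type=Float,Description="Classification probability per SV type (DEL,DUP,INS,INV)">',
    '##INFO=<ID=LRT,Number=1,Type=Float,Description="Binomial likelihood-ratio statistic between target and background cohorts">',
    '##INFO=<ID=BE,Number=3,Type=String,Description="Partner breakpoint: chrom,pos,support">',
    '##INFO=<ID=SIDE,Number=1,Type=String,Description="Clip side of the primary breakpoint (left/right)">',
    '##INFO=<ID=CONSENSUS,Number=1,Type=String,Description="Soft-clip consensus sequence">',
]
_FORMAT_HEADER = [
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GL,Number=G,Type=Float,Description="Log10 genotype likelihoods">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Reads overlapping the breakpoint">',
    '##FORMAT=<ID=SP,Number=1,Type=Integer,Description="Reads supporting the alternative allele">',
]
_ALT_HEADER = [
    f'##ALT=<ID={c},Description="{c} structural variant">' for c in SV_CLASSES
] + ['##ALT=<ID=SV,Description="Unclassified structural variant">']


def _fmt(x: float) -> str:
    """Minimal exact decimal representation so round-trips are lossless."""
    s = repr(float(x))
    return s


def _format_genotype(g: Optional[GenotypeCall]) -> str:
    if g is None:
        return "./.:.:.:."
    gl = ",".join(_fmt(v) for v in g.gl)
    return f"{g.gt}:{gl}:{g.depth}:{g.alt_count}"


def write_vcf(calls: List[SVCall], samples: List[str], reference_name: str,
              out: str, contigs: Optional[Dict[str, int]] = None) -> None:
    """Write calls (sorted by chrom, pos) as VCF 4.2.

    Raises ``ValueError`` when the call list is out of order or two records
    share (chrom, pos, side).
    """
    seen = set()
    prev = None
    for c in calls:
        key = (c.chrom, c.pos, c.side)
        if key in seen:
            raise ValueError(f"duplicate call record at {c.chrom}:{c.pos} ({c.side})")
        seen.add(key)
        if prev is not None and prev[0] == c.chrom and prev[1] > c.pos:
            raise ValueError(f"calls not sorted at {c.chrom}:{c.pos}")
        prev = (c.chrom, c.pos)

    if contigs is None:
        contigs = {}
        for c in calls:
            contigs.setdefault(c.chrom, 0)
            if c.mate is not None:
                contigs.setdefault(c.mate.chrom, 0)

    lines = ["##fileformat=VCFv4.2", f"##reference={reference_name}",
             "##source=clipsv"]
    for name, length in contigs.items():
        if length:
            lines.append(f"##contig=<ID={name},length={length}>")
        else:
            lines.append(f"##contig=<ID={name}>")
    lines += _INFO_HEADER + _FORMAT_HEADER + _ALT_HEADER
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        header_cols += ["FORMAT"] + list(samples)
    lines.append("\t".join(header_cols))

    for c in calls:
        info = [f"END={c.end + 1}", f"SVLEN={c.svlen}", f"SP={c.support}"]
        if c.at is not None:
            info.append("AT=" + ",".join(_fmt(v) for v in c.at))
        info.append(f"WC={c.wc}")
        if c.wp is not None:
            info.append("WP=" + ",".join(_fmt(v) for v in c.wp))
        if c.lrt is not None:
            info.append(f"LRT={_fmt(c.lrt)}")
        if c.mate is not None:
            info.append(f"BE={c.mate.chrom},{c.mate.pos + 1},{c.mate.support}")
        info.append(f"SIDE={c.side}")
        if c.consensus:
            info.append(f"CONSENSUS={c.consensus}")
        alt = f"<{c.wc}>" if c.wc != UNKNOWN_CLASS else "<SV>"
        row = [c.chrom, str(c.pos + 1), c.call_id, "N", alt, ".", "PASS",
               ";".join(info)]
        if samples:
            row.append("GT:GL:DP:SP")
            row += [_format_genotype(c.genotypes.get(s)) for s in samples]
        lines.append("\t".join(row))

    with open(out, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_reference_name(path: str) -> str:
    """The ##reference header value, falling back to the VCF path itself."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("##reference="):
                return line.rstrip("\n").split("=", 1)[1]
            if not line.startswith("##"):
                break
    return path


def read_contigs(path: str) -> Dict[str, int]:
    with pysam.VariantFile(path) as vf:
        return {name: (ctg.length or 0)
                for name, ctg in vf.header.contigs.items()}


def read_vcf(path: str) -> List[SVCall]:
    """Read a clipsv VCF back into :class:`SVCall` records (via pysam)."""
    calls: List[SVCall] = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            info = rec.info
            mate = None
            if "BE" in info:
                bchrom, bpos, bsup = info["BE"]
                mate = Breakpoint(bchrom, int(bpos) - 1, int(bsup))
            genotypes: Dict[str, GenotypeCall] = {}
            for s in samples:
                fmt = rec.samples[s]
                gt = fmt.get("GT")
                if gt is None or gt == (None, None):
                    continue
                gl = fmt.get("GL")
                genotypes[s] = GenotypeCall(
                    gt="/".join(str(a) for a in gt),
                    gl=tuple(float(v) for v in gl) if gl is not None else (0.0, 0.0, 0.0),
                    depth=int(fmt.get("DP") or 0),
                    alt_count=int(fmt.get("SP") or 0),
                    gq=0,
                )
            at = [float(v) for v in info["AT"]] if "AT" in info else None
            wp = [float(v) for v in info["WP"]] if "WP" in info else None
            calls.append(SVCall(
                chrom=rec.chrom,
                pos=rec.pos - 1,
                side=str(info.get("SIDE", "left")),
                support=int(info.get("SP", 0)),
                mate=mate,
                consensus=str(info.get("CONSENSUS", "") or ""),
                at=at,
                genotypes=genotypes,
                wc=str(info.get("WC", UNKNOWN_CLASS)),
                wp=wp,
                lrt=float(info["LRT"]) if "LRT" in info else None,
                call_id=rec.id or ".",
            ))
    return calls
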