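"""Interval mapping between assemblies via UCSC chain alignments.

A chain is a gapped pairwise alignment between a *target* (source) and a
*query* (destination) sequence, expressed as runs of aligned bases separated
by gaps on either side.  Coordinates are 0-based half-open; the target strand
is always "+", while minus-strand query coordinates count from the reverse
complement and are converted back to plus-strand coordinates on output, as in
the UCSC liftOver tool.  An interval maps through the single highest-scoring
chain overlapping it; the result spans the first to the last mapped base, and
the mapping is rejected when the fraction of source bases that are aligned
falls below ``min_match``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import GenomeLayout, Peak, PeakSet, ValidationError

DEFAULT_MIN_MATCH = 0.95


@dataclass(frozen=True)
class ChainBlock:
    size: int      # aligned bases
    dt: int = 0    # unaligned bases on the target after the block
    dq: int = 0    # unaligned bases on the query after the block


@dataclass(frozen=True)
class ChainAlignment:
    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: tuple[ChainBlock, ...]
    chain_id: str = ""

    def __post_init__(self):
        if self.t_strand != "+":
            raise ValidationError(f"chain {self.chain_id}: target strand must be '+'")
        if self.q_strand not in ("+", "-"):
            raise ValidationError(f"chain {self.chain_id}: bad query strand {self.q_strand!r}")
        sizes = sum(b.size for b in self.blocks)
        if any(b.size <= 0 for b in self.blocks):
            raise ValidationError(f"chain {self.chain_id}: non-positive block size")
        t_span = sizes + sum(b.dt for b in self.blocks)
        q_span = sizes + sum(b.dq for b in self.blocks)
        if t_span != self.t_end - self.t_start:
            raise ValidationError(
                f"chain {self.chain_id}: target span {t_span} != header "
                f"{self.t_end - self.t_start}"
            )
        if q_span != self.q_end - self.q_start:
            raise ValidationError(
                f"chain {self.chain_id}: query span {q_span} != header "
                f"{self.q_end - self.q_start}"
            )


@dataclass
class MappedInterval:
    """Result of lifting one source interval."""

    source: tuple[str, int, int]
    mapped: tuple[str, int, int] | None
    mapped_fraction: float
    chain_id: str = ""
    reason: str = ""

    @property
    def ok(self) -> bool:
        return self.mapped is not None


def parse_chain(text: str) -> list[ChainAlignment]:
    """Parse UCSC chain-format text into validated ChainAlignment records."""
    chains: list[ChainAlignment] = []
    lines = iter(text.splitlines())
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0] != "chain":
            raise ValidationError(f"expected 'chain' header, got {line!r}")
        if len(fields) < 12:
            raise ValidationError(f"short chain header: {line!r}")
        (score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end) = fields[1:12]
        chain_id = fields[12] if len(fields) > 12 else ""
        blocks: list[ChainBlock] = []
        for bline in lines:
            bline = bline.strip()
            if not bline:
                break
            parts = bline.split()
            if len(parts) == 1:
                blocks.append(ChainBlock(int(parts[0])))
                break
            blocks.append(ChainBlock(int(parts[0]), int(parts[1]), int(parts[2])))
        if not blocks:
            raise ValidationError(f"chain {chain_id}: no alignment blocks")
        chains.append(
            ChainAlignment(
                score=float(score),
                t_name=t_name, t_size=int(t_size), t_strand=t_strand,
                t_start=int(t_start), t_end=int(t_end),
                q_name=q_name, q_size=int(q_size), q_strand=q_strand,
                q_start=int(q_start), q_end=int(q_end),
                blocks=tuple(blocks), chain_id=chain_id,
            )
        )
    return chains


def read_chain(path) -> list[ChainAlignment]:
    with open(path) as fh:
        return parse_chain(fh.read())


def write_chain(chains: list[ChainAlignment], path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score:g} {c.t_name} {c.t_size} {c.t_strand} {c.t_start} "
                f"{c.t_end} {c.q_name} {c.q_size} {c.q_strand} {c.q_start} {c.q_end} "
                f"{c.chain_id}\n"
            )
            for b in c.blocks[:-1]:
                fh.write(f"{b.size} {b.dt} {b.dq}\n")
            fh.write(f"{c.blocks[-1].size}\n\n")


def _map_through_chain(chain: ChainAlignment, start: int, end: int):
    """Map [start, end) on the target through one chain.

    Returns (q_lo, q_hi in strand space, mapped_bases).
    """
    t = chain.t_start
    q = chain.q_start
    q_lo, q_hi, mapped = None, None, 0
    for b in chain.blocks:
        o_s, o_e = max(start, t), min(end, t + b.size)
        if o_s < o_e:
            qs = q + (o_s - t)
            qe = q + (o_e - t)
            q_lo = qs if q_lo is None else min(q_lo, qs)
            q_hi = qe if q_hi is None else max(q_hi, qe)
            mapped += o_e - o_s
        t += b.size + b.dt
        q += b.size + b.dq
        if t >= end:
            break
    return q_lo, q_hi, mapped


def map_interval(chains: list[ChainAlignment], chrom: str, start: int, end: int,
                 min_match: float = DEFAULT_MIN_MATCH) -> MappedInterval:
    """Lift one 0-based half-open interval through the best overlapping chain."""
    if not (0 < min_match <= 1):
        raise ValidationError(f"min_match must be in (0, 1], got {min_match}")
    if end <= start:
        raise ValidationError(f"invalid interval [{start}, {end})")
    source = (chrom, start, end)
    candidates = [
        c for c in chains
        if c.t_name == chrom and c.t_start < end and start < c.t_end
    ]
    if not candidates:
        return MappedInterval(source, None, 0.0, reason="no chain overlaps interval")
    best = max(candidates, key=lambda c: c.score)
    q_lo, q_hi, mapped = _map_through_chain(best, start, end)
    frac = mapped / (end - start)
    if mapped == 0:
        return MappedInterval(source, None, 0.0, best.chain_id,
                              reason="interval falls entirely in a chain gap")
    if frac < min_match:
        return MappedInterval(source, None, frac, best.chain_id,
                              reason=f"mapped fraction {frac:.3f} < {min_match}")
    if best.q_strand == "-":
        q_lo, q_hi = best.q_size - q_hi, best.q_size - q_lo
    return MappedInterval(source, (best.q_name, q_lo, q_hi), frac, best.chain_id)


def map_peakset(chains: list[ChainAlignment], peaks: PeakSet,
                min_match: float = DEFAULT_MIN_MATCH,
                target_layout: GenomeLayout | None = None):
    """Lift every peak; returns (mapped PeakSet, per-peak MappedInterval report).

    The destination layout defaults to the query sequences named in the
    chains, with their declared sizes.
    """
    if target_layout is None:
        sizes: dict[str, int] = {}
        for c in chains:
            sizes.setdefault(c.q_name, c.q_size)
        target_layout = GenomeLayout(tuple(sizes.items()))
    report = []
    mapped_peaks = []
    for p in peaks:
        m = map_interval(chains, p.chrom, p.start, p.end, min_match)
        report.append(m)
        if m.ok:
            chrom, s, e = m.mapped
            mapped_peaks.append(
                Peak(chrom, s, e, statistic=p.statistic, comparisons=p.comparisons,
                     max_score=p.max_score)
            )
    return PeakSet(mapped_peaks, target_layout), report


def invert_chain(chain: ChainAlignment) -> ChainAlignment:
    """Swap target and query roles of a plus-strand chain.

    Only '+/+' chains are invertible in place; a minus-strand query would need
    its block order reversed onto the opposite strand.
    """
    if chain.q_strand != "+":
        raise ValidationError("only plus-strand chains can be inverted directly")
    blocks = tuple(ChainBlock(b.size, b.dq, b.dt) for b in chain.blocks)
    return ChainAlignment(
        score=chain.score,
        t_name=chain.q_name, t_size=chain.q_size, t_strand="+",
        t_start=chain.q_start, t_end=chain.q_end,
        q_name=chain.t_name, q_size=chain.t_size, q_strand="+",
        q_start=chain.t_start, q_end=chain.t_end,
        blocks=blocks, chain_id=chain.chain_id + "_inv" if chain.chain_id else "",
    )
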