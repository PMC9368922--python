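"""Fragment assembly and chromosome-aberration scoring.

After repair, every chromosome is partitioned at its break positions into
segments; logged junctions (proper or improper) glue segment ends together.
Following the junctions yields the post-repair fragment sequences — linear
chains terminated by telomeres or open ends, or circular products (rings).
Aberrations are read off the fragments and off the graph of breaks linked by
improper junctions:

* simple exchange — a connected component of exactly 2 breaks on 2 distinct
  chromosomes (the dicentric/translocation-forming interchanges);
* complex exchange — a component of more than 2 breaks on ≥ 2 chromosomes;
* intrachanges — components confined to one chromosome (ring/inversion
  formers), reported separately;
* dicentric — a fragment carrying ≥ 2 centromeres; ring — a circular
  fragment (centric if it contains a centromere); translocation — a linear
  fragment joining ≥ 2 chromosomes with exactly one centromere; inversion —
  a fragment containing material of one chromosome in both orientations;
  deletion — an acentric fragment.  Categories are not mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

from .geometry import Karyotype
from .damage import DSBRecord
from .repair import RejoinEvent


@dataclass(frozen=True)
class Segment:
    """Half-open genomic interval [start_bp, end_bp) of one chromosome."""

    chromosome: str
    start_bp: int
    end_bp: int
    has_centromere: bool

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class FragmentSequence:
    """Ordered, oriented segments of one post-repair product."""

    segments: list[tuple[Segment, int]]     # (segment, +1 | -1)
    topology: str                           # "linear" | "circular"
    n_junctions: int
    n_open_ends: int = 0

    @property
    def n_centromeres(self) -> int:
        return sum(s.has_centromere for s, _ in self.segments)

    @property
    def chromosomes(self) -> set:
        return {s.chromosome for s, _ in self.segments}

    @property
    def length_bp(self) -> int:
        return sum(s.length_bp for s, _ in self.segments)


@dataclass(frozen=True)
class ExchangeEvent:
    """Connected component of breaks linked by improper junctions."""

    dsb_ids: frozenset
    chromosomes: frozenset
    kind: str                    # "simple" | "complex"


@dataclass
class AberrationTally:
    """Per-history category counts (categories are not exclusive)."""

    intact: int = 0
    properly_repaired: int = 0
    deletions: int = 0
    translocations: int = 0
    dicentrics: int = 0
    rings: int = 0
    centric_rings: int = 0
    inversions: int = 0
    simple_exchanges: int = 0
    complex_exchanges: int = 0
    simple_intrachanges: int = 0
    complex_intrachanges: int = 0
    unrepaired_breaks: int = 0

    @property
    def total_exchanges(self) -> int:
        return self.simple_exchanges + self.complex_exchanges

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        d["total_exchanges"] = self.total_exchanges
        return d


class InconsistentLogError(ValueError):
    """An end appears in more than one junction."""


def _pairing_from_events(events: list[RejoinEvent]) -> dict[int, int]:
    pairing: dict[int, int] = {}
    for ev in events:
        for e in (ev.end_a, ev.end_b):
            if e in pairing:
                raise InconsistentLogError(
                    f"free end {e} is closed by more than one junction")
        pairing[ev.end_a] = ev.end_b
        pairing[ev.end_b] = ev.end_a
    return pairing


def assemble_fragments(karyotype: Karyotype, dsbs: list[DSBRecord],
                       events: list[RejoinEvent]) -> list[FragmentSequence]:
    """Partition the genome at the break positions and chain the junctions.

    Every segment appears in exactly one fragment; traversal that returns to
    its starting junction yields a circular fragment; open (unrepaired) ends
    and telomeres terminate linear fragments.
    """
    pairing = _pairing_from_events(events)

    # per-chromosome breakpoints
    by_chrom: dict[str, list[DSBRecord]] = {}
    for d in dsbs:
        by_chrom.setdefault(d.chromosome, []).append(d)

    segments: list[Segment] = []
    port_to_end: dict[int, int] = {}
    end_to_port: dict[int, int] = {}
    for chrom in karyotype.chromosomes:
        breaks = sorted(by_chrom.get(chrom.id, []), key=lambda d: d.genomic_bp)
        cuts = [d.genomic_bp for d in breaks]
        if len(set(cuts)) != len(cuts):
            raise ValueError(
                f"coincident breakpoints on {chrom.id} are not supported")
        bounds = [0] + cuts + [chrom.length_bp]
        for i in range(len(bounds) - 1):
            start, end = bounds[i], bounds[i + 1]
            seg_idx = len(segments)
            segments.append(Segment(
                chrom.id, start, end,
                has_centromere=start <= chrom.centromere_bp < end))
            if i > 0:                      # left port carries a break end
                e = 2 * breaks[i - 1].id + 1    # downstream end
                port_to_end[2 * seg_idx] = e
                end_to_port[e] = 2 * seg_idx
            if i < len(bounds) - 2:        # right port carries a break end
                e = 2 * breaks[i].id            # upstream end
                port_to_end[2 * seg_idx + 1] = e
                end_to_port[e] = 2 * seg_idx + 1

    def next_port(port: int) -> int | None:
        """Port reached through the junction leaving ``port``; None if free."""
        end = port_to_end.get(port)
        if end is None or end not in pairing:
            return None
        return end_to_port[pairing[end]]

    visited = [False] * len(segments)
    fragments: list[FragmentSequence] = []

    def traverse(entry_port: int) -> FragmentSequence:
        seq: list[tuple[Segment, int]] = []
        n_junc = 0
        n_open = 0
        port = entry_port
        entry_end = port_to_end.get(entry_port)
        if entry_end is not None and entry_end not in pairing:
            n_open += 1                    # starting at an open break end
        while True:
            seg = port // 2
            visited[seg] = True
            orient = 1 if port % 2 == 0 else -1
            seq.append((segments[seg], orient))
            exit_port = port ^ 1
            nxt = next_port(exit_port)
            if nxt is None:
                if port_to_end.get(exit_port) is not None:
                    n_open += 1
                return FragmentSequence(seq, "linear", n_junc, n_open)
            n_junc += 1
            if nxt == entry_port:          # closed the ring
                return FragmentSequence(seq, "circular", n_junc, 0)
            port = nxt

    # linear fragments start at free ports (telomeres or open ends)
    for seg_idx in range(len(segments)):
        for port in (2 * seg_idx, 2 * seg_idx + 1):
            if visited[seg_idx]:
                break
            end = port_to_end.get(port)
            if end is None or end not in pairing:
                fragments.append(traverse(port))
    # what remains is circular
    for seg_idx in range(len(segments)):
        if not visited[seg_idx]:
            fragments.append(traverse(2 * seg_idx))
    return fragments


class _UnionFind:
    def __init__(self):
        self.parent: dict[int, int] = {}

    def find(self, x: int) -> int:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


def group_exchanges(dsbs: list[DSBRecord], events: list[RejoinEvent]
                    ) -> tuple[list[ExchangeEvent], list[ExchangeEvent]]:
    """Connected components of breaks linked by improper junctions.

    Returns (exchanges, intrachanges): components spanning ≥ 2 chromosomes
    are exchanges (simple iff exactly 2 breaks); single-chromosome
    components are intrachanges and never count as exchanges.
    """
    chrom_of = {d.id: d.chromosome for d in dsbs}
    uf = _UnionFind()
    for ev in events:
        if ev.kind == "improper":
            uf.union(ev.end_a // 2, ev.end_b // 2)
    comps: dict[int, set[int]] = {}
    for ev in events:
        if ev.kind == "improper":
            for d in (ev.end_a // 2, ev.end_b // 2):
                comps.setdefault(uf.find(d), set()).add(d)
    exchanges: list[ExchangeEvent] = []
    intrachanges: list[ExchangeEvent] = []
    for members in comps.values():
        chroms = frozenset(chrom_of[d] for d in members)
        kind = "simple" if len(members) == 2 else "complex"
        event = ExchangeEvent(frozenset(members), chroms, kind)
        (exchanges if len(chroms) >= 2 else intrachanges).append(event)
    return exchanges, intrachanges


def _is_restored(frag: FragmentSequence, karyotype: Karyotype) -> bool:
    """Complete single chromosome reassembled in original order."""
    if frag.topology != "linear" or len(frag.segments) < 2:
        return False
    if len(frag.chromosomes) != 1:
        return False
    segs = frag.segments
    orients = {o for _, o in segs}
    if len(orients) != 1:
        return False
    if next(iter(orients)) == -1:
        segs = [(s, o) for s, o in reversed(segs)]
    chrom_id = segs[0][0].chromosome
    length = next(c.length_bp for c in karyotype.chromosomes
                  if c.id == chrom_id)
    if segs[0][0].start_bp != 0 or segs[-1][0].end_bp != length:
        return False
    return all(segs[i][0].end_bp == segs[i + 1][0].start_bp
               for i in range(len(segs) - 1))


def classify_aberrations(fragments: list[FragmentSequence],
                         exchanges: list[ExchangeEvent],
                         karyotype: Karyotype,
                         intrachanges: list[ExchangeEvent] = (),
                         n_unrepaired_breaks: int = 0,
                         min_fragment_bp: int = 0) -> AberrationTally:
    """Score the per-history aberration tally.

    ``min_fragment_bp`` optionally drops fragments below a detection limit
    (off by default: everything is counted).
    """
    t = AberrationTally(unrepaired_breaks=n_unrepaired_breaks)
    for frag in fragments:
        if frag.length_bp < min_fragment_bp:
            continue
        cent = frag.n_centromeres
        if frag.topology == "circular":
            t.rings += 1
            if cent >= 1:
                t.centric_rings += 1
        if cent >= 2:
            t.dicentrics += 1
        if cent == 0:
            t.deletions += 1
        if len(frag.segments) == 1 and frag.n_junctions == 0 \
                and _covers_whole_chromosome(frag, karyotype):
            t.intact += 1
        elif _is_restored(frag, karyotype):
            t.properly_repaired += 1
        if frag.topology == "linear" and len(frag.chromosomes) >= 2 \
                and cent == 1:
            t.translocations += 1
        # same-chromosome material present in both orientations
        per_chrom: dict[str, set[int]] = {}
        for seg, orient in frag.segments:
            per_chrom.setdefault(seg.chromosome, set()).add(orient)
        if any(len(v) == 2 for v in per_chrom.values()):
            t.inversions += 1
    for ex in exchanges:
        if ex.kind == "simple":
            t.simple_exchanges += 1
        else:
            t.complex_exchanges += 1
    for ex in intrachanges:
        if ex.kind == "simple":
            t.simple_intrachanges += 1
        else:
            t.complex_intrachanges += 1
    return t


def _covers_whole_chromosome(frag: FragmentSequence,
                             karyotype: Karyotype) -> bool:
    seg = frag.segments[0][0]
    length = next(c.length_bp for c in karyotype.chromosomes
                  if c.id == seg.chromosome)
    return seg.start_bp == 0 and seg.end_bp == length


def analyze_history(karyotype: Karyotype, dsbs: list[DSBRecord],
                    events: list[RejoinEvent], min_fragment_bp: int = 0
                    ) -> tuple[list[FragmentSequence], list[ExchangeEvent],
                               AberrationTally]:
    """Assemble, group and classify one history in one call."""
    fragments = assemble_fragments(karyotype, dsbs, events)
    exchanges, intrachanges = group_exchanges(dsbs, events)
    tally = classify_aberrations(
        fragments, exchanges, karyotype, intrachanges,
        n_unrepaired_breaks=len(dsbs) - len(events),
        min_fragment_bp=min_fragment_bp)
    return fragments, exchanges, tally
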