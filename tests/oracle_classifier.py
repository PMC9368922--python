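"""Independent brute-force aberration classifier for cross-checking.

Works at single-base resolution on toy chromosomes: each chromosome is an
explicit list of unit-length beads.  Breaks cut the bead list; junctions are
applied one at a time by physically concatenating (and if needed reversing)
the pieces, forming a circle when a junction joins the two termini of one
piece.  Classification then scans the final bead lists.  The mechanics are
deliberately different from the package's port-graph traversal.

End numbering matches the package: break i has upstream end 2i (lower-bp
side) and downstream end 2i+1.
"""

from dataclasses import dataclass


@dataclass
class _Piece:
    beads: list            # [(chrom_id, bead_index, orientation ±1), ...]
    left_end: object       # end id, or ("tel", chrom, side)
    right_end: object
    n_junctions: int = 0
    circular: bool = False

    def reverse(self):
        self.beads = [(c, i, -o) for c, i, o in reversed(self.beads)]
        self.left_end, self.right_end = self.right_end, self.left_end


def oracle_classify(chromosomes, breaks, events):
    """chromosomes: [(id, length, centromere)], lengths small integers.
    breaks: [(chrom_id, bp)] indexed by break id.
    events: [(end_a, end_b, kind)].
    Returns a tally dict.
    """
    pieces = []
    for cid, length, cen in chromosomes:
        cuts = sorted([bp for c, bp in breaks if c == cid])
        assert all(0 < bp < length for bp in cuts)
        ids_sorted = sorted([i for i, (c, _) in enumerate(breaks) if c == cid],
                            key=lambda i: breaks[i][1])
        bounds = [0] + cuts + [length]
        for k in range(len(bounds) - 1):
            beads = [(cid, u, 1) for u in range(bounds[k], bounds[k + 1])]
            left = ("tel", cid, "p") if k == 0 \
                else 2 * ids_sorted[k - 1] + 1
            right = ("tel", cid, "q") if k == len(bounds) - 2 \
                else 2 * ids_sorted[k]
            pieces.append(_Piece(beads, left, right))

    def find(end):
        for p in pieces:
            if p.circular:
                continue
            if p.left_end == end or p.right_end == end:
                return p
        raise AssertionError(f"end {end} not found on any open terminus")

    for a, b, _kind in events:
        pa = find(a)
        pb = find(b)
        if pa is pb:
            # joining the two termini of one piece closes a ring
            assert {pa.left_end, pa.right_end} == {a, b}
            pa.circular = True
            pa.n_junctions += 1
            continue
        if pa.right_end != a:
            pa.reverse()
        if pb.left_end != b:
            pb.reverse()
        pa.beads = pa.beads + pb.beads
        pa.right_end = pb.right_end
        pa.n_junctions += pb.n_junctions + 1
        pieces.remove(pb)

    cen_of = {cid: cen for cid, _, cen in chromosomes}
    len_of = {cid: length for cid, length, _ in chromosomes}

    tally = dict(intact=0, properly_repaired=0, deletions=0, translocations=0,
                 dicentrics=0, rings=0, centric_rings=0, inversions=0,
                 simple_exchanges=0, complex_exchanges=0,
                 simple_intrachanges=0, complex_intrachanges=0,
                 unrepaired_breaks=len(breaks) - len(events))
    total_beads = 0
    total_cents = 0
    for p in pieces:
        total_beads += len(p.beads)
        cents = sum(1 for c, u, _ in p.beads if u == cen_of[c])
        total_cents += cents
        chroms = {c for c, _, _ in p.beads}
        if p.circular:
            tally["rings"] += 1
            if cents >= 1:
                tally["centric_rings"] += 1
        if cents >= 2:
            tally["dicentrics"] += 1
        if cents == 0:
            tally["deletions"] += 1
        if not p.circular and len(chroms) >= 2 and cents == 1:
            tally["translocations"] += 1
        for c in chroms:
            if len({o for cc, _, o in p.beads if cc == c}) == 2:
                tally["inversions"] += 1
                break
        if len(chroms) == 1 and not p.circular:
            c = next(iter(chroms))
            units = [(u, o) for _, u, o in p.beads]
            if len(units) == len_of[c]:
                fwd = units == [(u, 1) for u in range(len_of[c])]
                rev = units == [(u, -1) for u in reversed(range(len_of[c]))]
                if fwd or rev:
                    if p.n_junctions == 0:
                        tally["intact"] += 1
                    else:
                        tally["properly_repaired"] += 1

    assert total_beads == sum(len_of.values()), "bead conservation broken"
    assert total_cents == len(chromosomes), "centromere conservation broken"

    # exchange components: BFS over breaks linked by improper junctions
    adj = {}
    touched = set()
    for a, b, kind in events:
        if kind == "improper":
            i, j = a // 2, b // 2
            adj.setdefault(i, set()).add(j)
            adj.setdefault(j, set()).add(i)
            touched |= {i, j}
    seen = set()
    for start in sorted(touched):
        if start in seen:
            continue
        comp = set()
        stack = [start]
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj.get(x, ()))
        seen |= comp
        comp_chroms = {breaks[i][0] for i in comp}
        if len(comp_chroms) >= 2:
            key = "simple_exchanges" if len(comp) == 2 else "complex_exchanges"
        else:
            key = "simple_intrachanges" if len(comp) == 2 \
                else "complex_intrachanges"
        tally[key] += 1
    return tally
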