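"""Classify post-repair fragments into chromosome aberrations.

Constructs the two classic two-break interchanges by hand on a toy
karyotype — the asymmetric pairing that forms a dicentric plus an acentric
fragment, and the symmetric pairing that forms reciprocal translocations —
and scores them.
"""

import numpy as np

import casim

toy = casim.Karyotype((
    casim.Chromosome("A", 12_000_000, 5_000_000),
    casim.Chromosome("B", 10_000_000, 4_000_000),
))


def interchange(pairs, label):
    dsbs = [
        casim.DSBRecord(0, "A", 0, 0, 7_000_000, np.zeros(3), 1e3, "complex"),
        casim.DSBRecord(1, "B", 1, 0, 6_000_000, np.zeros(3), 1e3, "complex"),
    ]
    events = [casim.RejoinEvent(10.0 + k, a, b,
                                "proper" if a ^ 1 == b else "improper")
              for k, (a, b) in enumerate(pairs)]
    frags, exchanges, tally = casim.analyze_history(toy, dsbs, events)
    print(f"{label}:")
    for f in frags:
        parts = " + ".join(
            f"{s.chromosome}[{s.start_bp // 10**6}-{s.end_bp // 10**6} Mb]"
            f"{'(-)' if o < 0 else ''}" for s, o in f.segments)
        print(f"  {f.topology} fragment, {f.n_centromeres} centromere(s): "
              f"{parts}")
    print(f"  -> dicentrics {tally.dicentrics}, translocations "
          f"{tally.translocations}, deletions {tally.deletions}, "
          f"simple exchanges {tally.simple_exchanges}\n")


# end ids: break i has upstream end 2i, downstream end 2i+1
interchange([(0, 2), (1, 3)], "asymmetric interchange (centric+centric)")
interchange([(0, 3), (1, 2)], "symmetric interchange (reciprocal)")
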