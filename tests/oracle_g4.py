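"""Independent brute-force quadruplex enumerator used as a test oracle.

Tries every combination of four equal-length G-run placements and filters by
the candidate constraints (ordering, loop bounds, span, no N inside the
span).  Written first and kept deliberately naive and separate from the
package's windowed enumeration so the two can disagree.
"""

from itertools import combinations

from compoundg4.g4_engine import G4Candidate, G4Params


def brute_force_candidates(seq: str, params: G4Params) -> set[G4Candidate]:
    seq = seq.upper()
    n = len(seq)
    found: set[G4Candidate] = set()
    for g in range(params.min_tetrads, params.max_tetrads + 1):
        starts = [i for i in range(n - g + 1) if seq[i : i + g] == "G" * g]
        for i, s1 in enumerate(starts):
            pool = [s for s in starts[i + 1 :] if s + g <= s1 + params.max_span]
            for s2, s3, s4 in combinations(pool, 3):
                loops = (s2 - s1 - g, s3 - s2 - g, s4 - s3 - g)
                if any(
                    l < params.min_loop or l > params.max_loop for l in loops
                ):
                    continue
                if "N" in seq[s1 : s4 + g]:
                    continue
                found.add(
                    G4Candidate(run_starts=(s1, s2, s3, s4), tetrads=g, loops=loops)
                )
    return found
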