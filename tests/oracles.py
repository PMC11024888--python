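"""Independent brute-force oracles kept separate from the code under test."""

import itertools

from gslprof.structures import AcylChain, LongChainBase


def brute_force_ceramides(lcb_names, carbons, max_db, hydroxyls):
    """Exhaustively scan all (LCB, acyl) tuples and apply the constraints
    directly; deliberately naive so it cannot share bugs with the
    enumerator."""
    pairs = []
    for lcb_name in sorted(lcb_names):
        lcb = LongChainBase.parse(lcb_name)
        for acyl_c, acyl_db, acyl_oh in itertools.product(
            range(2, 60), range(0, 10), (0, 1)
        ):
            if not carbons[0] <= lcb.carbons + acyl_c <= carbons[1]:
                continue
            if lcb.double_bonds + acyl_db > max_db:
                continue
            if not hydroxyls[0] <= lcb.hydroxyls + acyl_oh <= hydroxyls[1]:
                continue
            pairs.append((lcb.name, AcylChain(acyl_c, acyl_db, acyl_oh).name))
    return pairs
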