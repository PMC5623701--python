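"""Brute-force motif-scanning oracle shared by the motif tests."""

MOTIF1 = ("EPELLVAHAxYTRY[LM]GDLSGxGQVLKK[VI]xxAQ[RK]ALKLPS[TS]"
          "GExxxGL[QA]F[YF]")


def brute_force_scan(pattern, sequence):
    """Sliding-window matcher, independent of the regex implementation."""
    hits = []
    L = len(pattern)
    for start in range(len(sequence) - L + 1):
        ok = True
        for el, c in zip(pattern.elements, sequence[start:start + L]):
            if el is None:
                if c == "-":
                    ok = False
                    break
            elif c not in el:
                ok = False
                break
        if not ok:
            continue
        hits.append(start + 1)
    return hits
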