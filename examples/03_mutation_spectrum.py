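"""Substitution spectrum and the doubled Ts/Tv ratio.

Builds the 12-class substitution spectrum from the published class counts
of both mutation classes and prints the doubled (2xTs/Tv) and conventional
ratios.
"""

from corepromoter import substitution_spectrum, ts_tv
from corepromoter.variants import VariantKey

CLASS_COUNTS = {
    "G>A": (88, 15), "C>T": (78, 7), "A>G": (17, 4), "T>C": (9, 2),
    "C>A": (93, 7), "G>C": (21, 4), "C>G": (21, 1), "A>C": (13, 2),
    "G>T": (63, 2), "T>G": (5, 3), "A>T": (13, 1), "T>A": (11, 3),
}

for name, col in (("somatic", 0), ("germline", 1)):
    keys, pos = [], 1
    for cls, counts in CLASS_COUNTS.items():
        ref, alt = cls.split(">")
        for _ in range(counts[col]):
            keys.append(VariantKey("chr1", pos, ref, alt))
            pos += 1
    spec = substitution_spectrum(keys)
    conventional = ts_tv(spec.ts_total, spec.tv_total, doubled=False)
    print(f"{name}: Ts={spec.ts_total} Tv={spec.tv_total} "
          f"2xTs/Tv={spec.ts_tv_ratio:.2f} (conventional {conventional:.2f})")
# The doubled convention is what makes 192 transitions / 240 transversions
# print as 1.60; population-genetics Ts/Tv values are usually conventional,
# so both are reported.
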