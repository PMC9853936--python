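"""Substitution spectrum and the doubled transition/transversion statistic.

Single-base substitutions are tallied into the 12 reference-strand classes
(no pyrimidine folding: G>A and C>T are reported separately).  The headline
ratio follows a doubled convention, ``2 x Ts / Tv``; the conventional
``Ts / Tv`` is available via a flag for comparison with population values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Sequence

import pandas as pd

from .variants import CohortVariant, VariantKey, classify_type

__all__ = [
    "SPECTRUM_CLASSES",
    "TRANSITIONS",
    "SpectrumSummary",
    "substitution_spectrum",
    "ts_tv",
    "spectrum_table",
]

#: The 12 single-base classes in reporting order: transitions first.
TRANSITIONS = ("G>A", "C>T", "A>G", "T>C")
TRANSVERSIONS = ("C>A", "G>C", "C>G", "A>C", "G>T", "T>G", "A>T", "T>A")
SPECTRUM_CLASSES = TRANSITIONS + TRANSVERSIONS


class UndefinedRatioError(ZeroDivisionError):
    """Ts/Tv is undefined when no transversions were observed."""


@dataclass
class SpectrumSummary:
    class_counts: Dict[str, int]
    ts_total: int
    tv_total: int
    ts_tv_ratio: float

    def to_dict(self) -> Dict[str, object]:
        return {
            "class_counts": dict(self.class_counts),
            "ts_total": self.ts_total,
            "tv_total": self.tv_total,
            "ts_tv_ratio": self.ts_tv_ratio,
        }


def ts_tv(ts_total: int, tv_total: int, doubled: bool = True) -> float:
    """The (doubled by default) transition/transversion ratio.

    ``doubled=True`` returns ``2 * ts / tv``; ``doubled=False`` the
    conventional ``ts / tv``.  Zero transversions raise rather than
    returning infinity.
    """
    if tv_total == 0:
        raise UndefinedRatioError("Ts/Tv undefined with zero transversions")
    factor = 2 if doubled else 1
    return factor * ts_total / tv_total


def substitution_spectrum(
    mutations: Iterable[CohortVariant | VariantKey], doubled: bool = True
) -> SpectrumSummary:
    """Tally single-base substitutions into the 12 ref>alt classes.

    Indels and multi-base substitutions (MNVs) are ignored here; MNVs still
    count as substitutions in type totals elsewhere.  When no transversion
    was observed the ratio is reported as NaN (the strict accessor
    :func:`ts_tv` raises instead).
    """
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for m in mutations:
        key = m.key if isinstance(m, CohortVariant) else m
        if classify_type(key) != "substitution" or len(key.ref) != 1:
            continue
        counts[f"{key.ref}>{key.alt}"] += 1
    ts = sum(counts[c] for c in TRANSITIONS)
    tv = sum(counts[c] for c in TRANSVERSIONS)
    ratio = ts_tv(ts, tv, doubled=doubled) if tv else float("nan")
    return SpectrumSummary(counts, ts, tv, ratio)


def spectrum_table(
    somatic: SpectrumSummary, germline: SpectrumSummary
) -> pd.DataFrame:
    """Two-column table of class counts plus totals and the ratio row."""
    rows = []
    for c in TRANSITIONS:
        rows.append(("transition", c, somatic.class_counts[c], germline.class_counts[c]))
    rows.append(("transition", "Total", somatic.ts_total, germline.ts_total))
    for c in TRANSVERSIONS:
        rows.append(
            ("transversion", c, somatic.class_counts[c], germline.class_counts[c])
        )
    rows.append(("transversion", "Total", somatic.tv_total, germline.tv_total))
    rows.append(
        ("ratio", "Ts/Tv ratio",
         round(somatic.ts_tv_ratio, 2), round(germline.ts_tv_ratio, 2))
    )
    return pd.DataFrame(
        rows, columns=["group", "class", "somatic_count", "germline_count"]
    )
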