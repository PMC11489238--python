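"""Ordinal evidence grades for in vitro endpoints.

The four-level scale none < medium < strong < very strong is shared by the
protein-marker matrix (graded on percent-of-control condition means) and the
transcriptomics matrix (graded on overlap p-values). "At least X" filters
compare on this order.
"""

from __future__ import annotations

from enum import IntEnum


class EvidenceGrade(IntEnum):
    NONE = 0
    MEDIUM = 1
    STRONG = 2
    VERY_STRONG = 3

    @property
    def symbol(self) -> str:
        """The +/++/+++ notation used in report tables."""
        return {0: "", 1: "+", 2: "++", 3: "+++"}[int(self)]

    @classmethod
    def parse(cls, value) -> "EvidenceGrade":
        if isinstance(value, cls):
            return value
        if isinstance(value, int):
            return cls(value)
        s = str(value).strip().lower().replace(" ", "_")
        by_symbol = {"": cls.NONE, "+": cls.MEDIUM, "++": cls.STRONG, "+++": cls.VERY_STRONG}
        if s in by_symbol:
            return by_symbol[s]
        return cls[s.upper()]


#: Thresholds swept by the concordance engine ("at least medium", "at least
#: strong", "very strong only").
SWEEP_THRESHOLDS = (EvidenceGrade.MEDIUM, EvidenceGrade.STRONG, EvidenceGrade.VERY_STRONG)
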