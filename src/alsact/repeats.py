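"""Repeat-expansion genotype interpretation for the two ALS expansion loci.

Interprets repeat-count calls (e.g. from a short-read repeat genotyper such
as ExpansionHunter; the calls are inputs here) at:

* *C9orf72* — the GGGGCC hexanucleotide repeat; more than 30 repeat units
  on the larger allele is pathogenic.
* *ATXN2* — the CAG trinucleotide repeat; an intermediate expansion of
  29–33 units inclusive is an established ALS risk factor and is treated as
  pathogenic for reporting.  Full SCA2-range expansions (>33) are flagged
  separately but are not counted as ALS-actionable.
"""

from __future__ import annotations

import pandas as pd

#: C9orf72 counts strictly above this are pathogenic.
C9ORF72_PATHOGENIC_ABOVE = 30

#: Closed interval of ATXN2 intermediate (ALS risk) repeat counts.
ATXN2_RISK_RANGE = (29, 33)

REPEAT_LOCI = ("C9orf72", "ATXN2")


def interpret_repeat(gene: str, repeat_count: int) -> bool:
    """True when the repeat count at ``gene`` is pathogenic for ALS.

    The count is the larger allele's repeat number.
    """
    if repeat_count < 0:
        raise ValueError(f"repeat_count must be non-negative, got {repeat_count}")
    if gene == "C9orf72":
        return repeat_count > C9ORF72_PATHOGENIC_ABOVE
    if gene == "ATXN2":
        lo, hi = ATXN2_RISK_RANGE
        return lo <= repeat_count <= hi
    raise ValueError(f"unknown repeat locus: {gene!r} (expected one of {REPEAT_LOCI})")


def interpret_frame(repeats: pd.DataFrame) -> pd.DataFrame:
    """Interpret a frame of calls (columns ``person_id, gene, repeat_count``).

    Returns a copy with ``pathogenic`` and, for ATXN2 full expansions in the
    SCA2 range, an ``sca2_range`` flag.
    """
    bad = set(repeats["gene"]) - set(REPEAT_LOCI)
    if bad:
        raise ValueError(f"unknown repeat loci: {sorted(bad)}")
    out = repeats.copy()
    count = out["repeat_count"].to_numpy(int)
    if (count < 0).any():
        raise ValueError("repeat_count must be non-negative")
    is_c9 = (out["gene"] == "C9orf72").to_numpy()
    lo, hi = ATXN2_RISK_RANGE
    out["pathogenic"] = (is_c9 & (count > C9ORF72_PATHOGENIC_ABOVE)) | (
        ~is_c9 & (count >= lo) & (count <= hi)
    )
    out["sca2_range"] = ~is_c9 & (count > hi)
    return out
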